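"""Synthetic two-condition barley trait tables with known quantile structure.

Each accession is observed once under saline and once under non-saline
irrigation.  Yield follows a location-scale model in the (population-)
centered traits,

    y = b0 + b' (x - mu) + (1 + g' (x - mu)) * sigma * eps,

per condition, with the non-saline condition's coefficients shifted by a
delta vector and the two conditions' errors drawn from a Gaussian copula
with correlation ``rho``.  Under this model the true conditional-quantile
coefficients are available in closed form,

    slope_j(p)  = b_j + g_j * sigma * Finv(p),
    intercept(p) = b0 + sigma * Finv(p),

with Finv the inverse CDF of the noise family, which is what downstream
recovery and coverage tests check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm
from scipy.stats import t as student_t

__all__ = [
    "TRAIT_NAMES",
    "TRAIT_COLUMNS",
    "SALINE",
    "NON_SALINE",
    "SyntheticConfig",
    "generate_trait_table",
    "true_quantile_coefficients",
]

SALINE = "saline"
NON_SALINE = "non_saline"

# the five covariates retained by the trait models (in fitting order)
TRAIT_NAMES = [
    "plant_height_cm",
    "flowering_time_d",
    "ripening_period_d",
    "ear_number",
    "grain_number",
]

TRAIT_COLUMNS = [
    "accession_id",
    "condition",
    "plant_height_cm",
    "flowering_time_d",
    "ripening_period_d",
    "ear_number",
    "grain_number",
    "thousand_grain_mass_g",
    "dry_mass_g_m2",
    "harvest_index",
    "yield_g_m2",
]

_DEFAULT_MEANS = {
    "plant_height_cm": 70.0,
    "flowering_time_d": 65.0,
    "ripening_period_d": 40.0,
    "ear_number": 3.0,
    "grain_number": 11.0,
}

_DEFAULT_SDS = {
    "plant_height_cm": 10.0,
    "flowering_time_d": 7.0,
    "ripening_period_d": 5.0,
    "ear_number": 1.0,
    "grain_number": 3.0,
}

# saline-condition coefficients (intercept + one slope per trait, g/m2 per
# trait unit) and the non-saline shift; magnitudes follow two-row spring
# barley field data
_DEFAULT_BETA_SALINE = {
    "intercept": 110.0,
    "plant_height_cm": 0.35,
    "flowering_time_d": -1.13,
    "ripening_period_d": -0.90,
    "ear_number": 10.3,
    "grain_number": 6.77,
}

_DEFAULT_BETA_DELTA = {
    "intercept": 27.75,
    "plant_height_cm": -0.66,
    "flowering_time_d": -0.27,
    "ripening_period_d": 1.23,
    "ear_number": -0.54,
    "grain_number": 0.99,
}

# mild heteroscedasticity concentrated on grain number and flowering time
_DEFAULT_GAMMA = {
    "plant_height_cm": 0.0,
    "flowering_time_d": -0.008,
    "ripening_period_d": 0.0,
    "ear_number": 0.0,
    "grain_number": 0.03,
}

_PLANTS_PER_M2 = 75.0  # stand density used to derive thousand-grain mass


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic field trial.

    Trait distributions are independent truncated normals on positive
    support.  ``beta_saline`` holds intercept + per-trait slopes for the
    saline condition; ``beta_delta`` is added for the non-saline condition.
    ``gamma`` scales the noise linearly in the centered traits (the scale
    factor 1 + gamma'(x - mu) must stay positive; offending trait draws are
    resampled).  ``rho`` correlates the two conditions' errors.
    """

    n_accessions: int = 404
    seed: int = 0
    trait_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    beta_saline: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_SALINE))
    beta_delta: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_DELTA))
    gamma: dict = field(default_factory=lambda: dict(_DEFAULT_GAMMA))
    sigma: float = 30.0
    rho: float = 0.5
    noise_family: str = "gaussian"  # or "student_t"
    student_df: float = 5.0
    max_resamples: int = 1000

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise ValueError("n_accessions must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.noise_family not in ("gaussian", "student_t"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        for t in TRAIT_NAMES:
            if self.trait_sds[t] <= 0:
                raise ValueError(f"trait sd for {t!r} must be positive")

    def noise_ppf(self, p):
        if self.noise_family == "gaussian":
            return norm.ppf(p)
        return student_t.ppf(p, self.student_df)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gamma_vector(config: SyntheticConfig) -> np.ndarray:
    return np.array([config.gamma.get(t, 0.0) for t in TRAIT_NAMES])


def _beta_vector(config: SyntheticConfig, condition: str) -> tuple[float, np.ndarray]:
    b0 = config.beta_saline["intercept"]
    b = np.array([config.beta_saline[t] for t in TRAIT_NAMES])
    if condition == NON_SALINE:
        b0 += config.beta_delta.get("intercept", 0.0)
        b = b + np.array([config.beta_delta.get(t, 0.0) for t in TRAIT_NAMES])
    elif condition != SALINE:
        raise ValueError(f"unknown condition {condition!r}")
    return b0, b


def _draw_traits(config: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Independent positive-support truncated-normal trait draws, resampled
    until the noise scale 1 + gamma'(x - mu) is positive for every row."""
    mu = np.array([config.trait_means[t] for t in TRAIT_NAMES])
    sd = np.array([config.trait_sds[t] for t in TRAIT_NAMES])
    g = _gamma_vector(config)

    def draw(m: int) -> np.ndarray:
        cols = []
        for j in range(len(TRAIT_NAMES)):
            a = (0.0 - mu[j]) / sd[j]
            u = rng.random(m)
            cols.append(truncnorm.ppf(u, a, np.inf, loc=mu[j], scale=sd[j]))
        return np.column_stack(cols)

    X = draw(n)
    bad = 1.0 + (X - mu) @ g <= 0.0
    # heavy rejection would truncate the trait law and break the analytic
    # quantile coefficients, so a steep gamma is a configuration error
    if bad.mean() > 0.25:
        raise ValueError(
            f"noise scale 1 + gamma'(x - mu) non-positive for "
            f"{bad.mean():.0%} of trait draws; gamma={config.gamma} is too "
            "steep for the configured trait spread"
        )
    for _ in range(config.max_resamples):
        if not bad.any():
            return X
        X[bad] = draw(int(bad.sum()))
        bad = 1.0 + (X - mu) @ g <= 0.0
    raise ValueError(
        "noise scale 1 + gamma'(x - mu) stayed non-positive after "
        f"{config.max_resamples} resamples; gamma={config.gamma} is too steep "
        "for the configured trait spread"
    )


def _draw_error_pairs(config: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """(eps_saline, eps_non_saline) from a Gaussian copula with corr rho."""
    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    L = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
    z = rng.standard_normal((n, 2)) @ L.T
    if config.noise_family == "gaussian":
        return z
    return student_t.ppf(norm.cdf(z), config.student_df)


def generate_trait_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the accession x condition trait table (2 * n_accessions rows).

    Traits are drawn independently per condition; yields follow the
    location-scale model with cross-condition error correlation ``rho``.
    Accessions whose draw would produce a negative yield have their error
    pair redrawn (bounded retries), so the tails are very mildly truncated
    relative to the nominal noise family.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions
    mu = np.array([config.trait_means[t] for t in TRAIT_NAMES])
    g = _gamma_vector(config)

    traits = {SALINE: _draw_traits(config, rng, n), NON_SALINE: _draw_traits(config, rng, n)}
    eps = _draw_error_pairs(config, rng, n)

    def yields_from(eps_pair: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for col, cond in enumerate((SALINE, NON_SALINE)):
            b0, b = _beta_vector(config, cond)
            Xc = traits[cond] - mu
            scale = 1.0 + Xc @ g
            out[cond] = b0 + Xc @ b + scale * config.sigma * eps_pair[:, col]
        return out

    y = yields_from(eps)
    neg = (y[SALINE] < 0.0) | (y[NON_SALINE] < 0.0)
    for _ in range(config.max_resamples):
        if not neg.any():
            break
        redraw = _draw_error_pairs(config, rng, int(neg.sum()))
        eps[neg] = redraw
        y = yields_from(eps)
        neg = (y[SALINE] < 0.0) | (y[NON_SALINE] < 0.0)
    else:
        raise ValueError("could not draw non-negative yields; model mean too close to 0")

    harvest_index = 0.2 + 0.4 * rng.beta(2.0, 2.0, size=(n, 2))

    frames = []
    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    for col, cond in enumerate((SALINE, NON_SALINE)):
        T = traits[cond]
        yy = y[cond]
        hi = harvest_index[:, col]
        grains_per_m2 = T[:, 3] * T[:, 4] * _PLANTS_PER_M2
        frames.append(
            pd.DataFrame(
                {
                    "accession_id": ids,
                    "condition": cond,
                    "plant_height_cm": T[:, 0],
                    "flowering_time_d": T[:, 1],
                    "ripening_period_d": T[:, 2],
                    "ear_number": T[:, 3],
                    "grain_number": T[:, 4],
                    "thousand_grain_mass_g": 1000.0 * yy / grains_per_m2,
                    "dry_mass_g_m2": yy / hi,
                    "harvest_index": hi,
                    "yield_g_m2": yy,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table[TRAIT_COLUMNS]


def true_quantile_coefficients(config: SyntheticConfig, p: float, condition: str = SALINE) -> pd.Series:
    """Analytic conditional-quantile coefficients of the generator.

    For covariates centered at the population trait means, the level-p
    conditional quantile of yield is linear with slope
    ``b_j + gamma_j * sigma * Finv(p)`` and intercept
    ``b0 + sigma * Finv(p)``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {p}")
    b0, b = _beta_vector(config, condition)
    g = _gamma_vector(config)
    q = config.noise_ppf(p)
    vals = np.concatenate([[b0 + config.sigma * q], b + g * config.sigma * q])
    return pd.Series(vals, index=["intercept", *TRAIT_NAMES])
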