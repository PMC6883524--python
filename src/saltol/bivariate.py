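"""Covariate-conditional directional quantile envelopes and SWP curves.

For each direction s on the unit circle, the projected yield s'y is
modelled as a cubic spline in a single plant trait x using the
truncated-power basis

    s'y = b0 + b1 x + b2 x^2 + b3 x^3 + sum_j d_j (x - k_j)^3_+ + eps,

fitted at each quantile level by pinball-loss regression.  Evaluating the
fitted directional quantiles at a covariate value x0 gives halfspace
offsets whose intersection is the predicted envelope D-hat(p | x0).  The
bivariate median of the predicted median envelope (level p*, the largest
non-empty level in (1/3, 1/2]) provides point predictions (y_s_hat,
y_c_hat), from which the stress-weighted performance curve

    SWP-hat(x0) = y_s_hat / sqrt(y_c_hat)

is computed, with lower/upper bands taken from the inner (p = 0.25) and
outer (p = 0.1) predicted envelopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depth import (
    DirectionSet,
    QuantileEnvelope,
    envelope_from_offsets,
)
from .quantreg import DesignMatrix, RankDeficientDesignError, fit_quantile_regression

__all__ = [
    "SplineSpec",
    "spline_basis",
    "BivariateQuantileRegressor",
    "fit_directional_model",
    "swp_curve",
]

P_STAR_GRID_STEP = 0.005
INNER_LEVEL = 0.25
OUTER_LEVEL = 0.1


@dataclass(frozen=True)
class SplineSpec:
    """Truncated-power cubic spline specification (degree fixed at 3)."""

    knots: tuple

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if len(k) < 1 or np.any(np.diff(k) <= 0):
            raise ValueError("knots must be non-empty and strictly increasing")

    @property
    def n_basis(self) -> int:
        return 4 + len(self.knots)

    @classmethod
    def from_quantiles(cls, x, probs=(0.25, 0.5, 0.75)) -> "SplineSpec":
        """Default placement: knots at interior empirical quantiles of x."""
        k = np.quantile(np.asarray(x, dtype=float), probs)
        if np.any(np.diff(k) <= 0):
            k = np.unique(k)
            if len(k) < 1:
                raise ValueError("cannot place knots on a degenerate covariate")
        return cls(tuple(float(v) for v in k))


def spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """[1, x, x^2, x^3, (x-k_1)^3_+, ..., (x-k_K)^3_+]; shape (n, 4+K)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    cols = [np.ones_like(x), x, x**2, x**3]
    for k in spec.knots:
        cols.append(np.clip(x - k, 0.0, None) ** 3)
    return np.column_stack(cols)


class BivariateQuantileRegressor:
    """Directional spline quantile model of bivariate yields on one trait.

    Parameters
    ----------
    n_directions : number of unit directions (equally spaced).
    levels : quantile levels to pre-fit.  None fits the inner/outer band
        levels plus the p*-search grid over (1/3, 1/2].
    knots : explicit knot locations, or None for the 0.25/0.5/0.75
        empirical quantiles of the covariate (K = 3).
    p_star_step : grid step of the p* search levels.
    band_method : "inner_outer_minmax" (lower band = min SWP over inner-
        envelope vertices, upper = max over outer-envelope vertices) or
        "per_envelope" (min/max over each envelope separately, widest).
    allow_extrapolation : permit prediction outside the observed covariate
        range (flagged by a warning).

    Column convention: component 0 of Y = saline yield, component 1 =
    non-saline yield.
    """

    def __init__(
        self,
        n_directions: int = 32,
        levels=None,
        knots=None,
        p_star_step: float = P_STAR_GRID_STEP,
        band_method: str = "inner_outer_minmax",
        allow_extrapolation: bool = False,
    ):
        self.n_directions = n_directions
        self.levels = levels
        self.knots = knots
        self.p_star_step = p_star_step
        self.band_method = band_method
        self.allow_extrapolation = allow_extrapolation

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_directions": self.n_directions,
            "levels": self.levels,
            "knots": self.knots,
            "p_star_step": self.p_star_step,
            "band_method": self.band_method,
            "allow_extrapolation": self.allow_extrapolation,
        }

    def set_params(self, **params) -> "BivariateQuantileRegressor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------

    def _level_grid(self) -> np.ndarray:
        if self.levels is not None:
            lv = np.asarray(self.levels, dtype=float)
            if np.any((lv <= 0) | (lv >= 1)):
                raise ValueError("levels must lie in (0, 1)")
            return np.unique(lv)
        pstar_grid = np.arange(0.5, 1.0 / 3.0, -self.p_star_step)
        return np.unique(np.concatenate([[OUTER_LEVEL, INNER_LEVEL, 1.0 / 3.0], pstar_grid]))

    def fit(self, x, Y) -> "BivariateQuantileRegressor":
        """Fit per-(direction, level) spline quantile regressions.

        x : covariate vector (n,) or (n, 1); Y : (n, 2) yields
        (saline, non-saline).
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError(f"Y must be n x 2, got {Y.shape}")
        if len(x) != len(Y):
            raise ValueError("x and Y lengths differ")
        spec = (
            SplineSpec(tuple(np.asarray(self.knots, dtype=float)))
            if self.knots is not None
            else SplineSpec.from_quantiles(x)
        )
        lo, hi = float(x.min()), float(x.max())
        if np.any(np.asarray(spec.knots) <= lo) or np.any(np.asarray(spec.knots) >= hi):
            raise ValueError(
                f"knots {spec.knots} must lie strictly inside the covariate "
                f"range ({lo}, {hi})"
            )
        B = spline_basis(x, spec)
        if len(x) < spec.n_basis + 1:
            raise ValueError("need n >= basis dimension + 1 observations")
        names = ["intercept", "x", "x^2", "x^3"] + [
            f"(x-k{j + 1})^3+" for j in range(len(spec.knots))
        ]
        design = DesignMatrix(B, names)

        directions = DirectionSet.uniform(self.n_directions)
        levels = self._level_grid()
        coefs = np.empty((directions.M, len(levels), spec.n_basis))
        for k in range(directions.M):
            proj = Y @ directions.vectors[k]
            for li, p in enumerate(levels):
                fit = fit_quantile_regression(design, proj, float(p))
                coefs[k, li] = fit.coefficients

        self.spline_spec_ = spec
        self.directions_ = directions
        self.levels_ = levels
        self.coef_ = coefs
        self.x_range_ = (lo, hi)
        self.n_features_in_ = 1
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def _check_range(self, x0: float) -> None:
        lo, hi = self.x_range_
        if not lo <= x0 <= hi:
            if not self.allow_extrapolation:
                raise ValueError(
                    f"x0={x0} outside the observed covariate range [{lo}, {hi}]; "
                    "set allow_extrapolation=True to override"
                )
            warnings.warn(
                f"extrapolating the directional model to x0={x0} outside "
                f"[{lo}, {hi}]",
                UserWarning,
                stacklevel=3,
            )

    def _level_index(self, p: float) -> int:
        idx = np.where(np.isclose(self.levels_, p, atol=1e-9))[0]
        if len(idx) == 0:
            raise ValueError(f"level {p} was not fitted; fitted levels: {self.levels_}")
        return int(idx[0])

    def predicted_offsets(self, x0: float, p: float) -> np.ndarray:
        """Q-hat(p, s_k | x0) for every direction."""
        self._check_fitted()
        self._check_range(float(x0))
        b = spline_basis([float(x0)], self.spline_spec_)[0]
        return self.coef_[:, self._level_index(p), :] @ b

    def predict_envelope(self, x0: float, p: float) -> QuantileEnvelope:
        """Predicted directional quantile envelope D-hat(p | x0)."""
        q = self.predicted_offsets(x0, p)
        return envelope_from_offsets(q, self.directions_, p)

    def predict_p_star(self, x0: float) -> tuple[float, QuantileEnvelope, bool]:
        """Largest fitted level in (1/3, 1/2] with non-empty predicted envelope."""
        self._check_fitted()
        search = sorted(
            (p for p in self.levels_ if 1.0 / 3.0 < p <= 0.5 + 1e-12), reverse=True
        )
        for p in search:
            env = self.predict_envelope(x0, float(p))
            if not env.is_empty:
                return float(p), env, False
        base = self.predict_envelope(x0, 1.0 / 3.0)
        if base.is_empty:
            raise RuntimeError(
                f"predicted envelope empty at p = 1/3 for x0={x0}; the fitted "
                "directional quantiles are inconsistent at this covariate value"
            )
        return 1.0 / 3.0, base, True

    def predict(self, x) -> np.ndarray:
        """Bivariate-median prediction (y_s_hat, y_c_hat) per covariate value."""
        x = np.atleast_1d(np.asarray(x, dtype=float)).ravel()
        out = np.empty((len(x), 2))
        for i, x0 in enumerate(x):
            _, env, _ = self.predict_p_star(float(x0))
            out[i] = env.vertices.mean(axis=0)
        return out

    # -- SWP curve ---------------------------------------------------------

    def swp_curve(self, x_grid) -> pd.DataFrame:
        """SWP point predictions with envelope-based lower/upper bands.

        Per grid point: p* and its envelope give the bivariate median
        (y_s_hat, y_c_hat) and swp_hat = y_s_hat / sqrt(y_c_hat); the band
        is built from SWP evaluated at the vertices of the inner (0.25)
        and outer (0.1) predicted envelopes.
        """
        self._check_fitted()
        if self.band_method not in ("inner_outer_minmax", "per_envelope"):
            raise ValueError(f"unknown band_method {self.band_method!r}")
        rows = []
        for x0 in np.atleast_1d(np.asarray(x_grid, dtype=float)).ravel():
            p_star, env_med, at_bound = self.predict_p_star(float(x0))
            ys_hat, yc_hat = env_med.vertices.mean(axis=0)
            if yc_hat <= 0:
                raise ValueError(
                    f"predicted non-saline yield non-positive at x0={x0}"
                )
            swp_hat = ys_hat / np.sqrt(yc_hat)

            def vertex_swp(env: QuantileEnvelope, x0=x0) -> np.ndarray:
                if env.is_empty:
                    raise ValueError(
                        f"band envelope (p={env.p}) empty at grid point x0={x0}"
                    )
                v = env.vertices
                if np.any(v[:, 1] <= 0):
                    raise ValueError(
                        f"band envelope vertex with non-positive non-saline "
                        f"yield at grid point x0={x0}"
                    )
                return v[:, 0] / np.sqrt(v[:, 1])

            inner = vertex_swp(self.predict_envelope(float(x0), INNER_LEVEL))
            outer = vertex_swp(self.predict_envelope(float(x0), OUTER_LEVEL))
            if self.band_method == "inner_outer_minmax":
                lower, upper = float(inner.min()), float(outer.max())
            else:
                lower = float(min(inner.min(), outer.min()))
                upper = float(max(inner.max(), outer.max()))
            lower = min(lower, swp_hat)
            upper = max(upper, swp_hat)
            rows.append(
                {
                    "x": float(x0),
                    "y_s_hat": float(ys_hat),
                    "y_c_hat": float(yc_hat),
                    "swp_hat": float(swp_hat),
                    "band_lower": lower,
                    "band_upper": upper,
                    "p_star": p_star,
                    "p_star_at_bound": at_bound,
                }
            )
        return pd.DataFrame(rows)


def fit_directional_model(
    Y,
    x,
    levels=None,
    n_directions: int = 32,
    knots=None,
    **kwargs,
) -> BivariateQuantileRegressor:
    """Functional wrapper over :class:`BivariateQuantileRegressor`."""
    model = BivariateQuantileRegressor(
        n_directions=n_directions, levels=levels, knots=knots, **kwargs
    )
    return model.fit(x, Y)


def swp_curve(Y, x, x_grid, n_directions: int = 32, knots=None, **kwargs) -> pd.DataFrame:
    """Fit the directional model and evaluate the SWP curve on a grid."""
    model = fit_directional_model(
        Y, x, levels=None, n_directions=n_directions, knots=knots, **kwargs
    )
    return model.swp_curve(x_grid)
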