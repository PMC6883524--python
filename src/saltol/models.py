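"""Trait regression analyses: yield-on-traits with a condition dummy, and
the stress-weighted performance (SWP) index on saline-condition traits.

Two univariate quantile analyses are built here.  The yield model pools
both irrigation conditions,

    y = b0 + sum_j b_j x_j + a0 D + sum_j a_j D x_j + eps,

with D = 1 for non-saline and 0 for saline rows, so main effects are the
saline-condition effects and interactions are the non-saline shifts.  The
SWP model regresses SWP = y_s / sqrt(y_c) on the saline-condition traits.
Both are fitted over a grid of quantile levels with rank-score confidence
intervals, next to an ordinary-least-squares comparison fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quantreg
from .quantreg import DesignMatrix, OLSResult, rankscore_ci, fit_ols
from .simulate import NON_SALINE, SALINE, TRAIT_NAMES

__all__ = [
    "DEFAULT_QUANTILE_GRID",
    "CoefficientProfile",
    "build_condition_design",
    "coefficient_profiles",
    "profiles_to_frame",
    "compute_swp",
    "swp_trait_model",
]

DEFAULT_QUANTILE_GRID = tuple(round(0.1 * i, 10) for i in range(1, 10))


@dataclass
class CoefficientProfile:
    """One covariate's quantile-coefficient trajectory with CIs."""

    covariate: str
    quantiles: np.ndarray
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles, dtype=float)
        if not (np.all(np.diff(q) > 0) and q.min() > 0 and q.max() < 1):
            raise ValueError("quantile grid must be strictly increasing within (0,1)")
        if np.any(self.ci_lower > self.ci_upper):
            raise ValueError("interval bounds out of order")

    @property
    def significant(self) -> np.ndarray:
        return (self.ci_lower > 0.0) | (self.ci_upper < 0.0)


def _paired_table(table: pd.DataFrame) -> pd.DataFrame:
    """Drop accessions not observed under both conditions (with a warning)."""
    counts = table.groupby("accession_id")["condition"].nunique()
    unpaired = counts.index[counts < 2]
    if len(unpaired):
        warnings.warn(
            f"excluding {len(unpaired)} accession(s) missing one condition: "
            f"{sorted(unpaired)[:5]}{'...' if len(unpaired) > 5 else ''}",
            UserWarning,
            stacklevel=3,
        )
        table = table[~table["accession_id"].isin(unpaired)]
    return table


def build_condition_design(
    table: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[DesignMatrix, np.ndarray]:
    """Design for the pooled two-condition yield model.

    Columns: intercept, covariates centered to pooled mean 0, condition
    dummy D (1 = non-saline), and D x covariate interactions.  Covariates
    default to the five traits retained after dropping harvest index,
    thousand grain mass and dry mass (partial expressions of yield).
    """
    if covariates is None:
        covariates = list(TRAIT_NAMES)
    if not covariates:
        raise ValueError("empty covariate list")
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise ValueError(f"covariates not in table: {missing}")
    conds = set(table["condition"].unique())
    if not {SALINE, NON_SALINE} <= conds:
        raise ValueError(f"need both conditions present, got {sorted(conds)}")
    table = _paired_table(table)

    Z = table[covariates].to_numpy(dtype=float)
    offsets = Z.mean(axis=0)  # pooled centering across both conditions
    Zc = Z - offsets
    D = (table["condition"] == NON_SALINE).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table)), Zc, D, D[:, None] * Zc])
    names = (
        ["intercept", *covariates, "condition", *[f"condition:{c}" for c in covariates]]
    )
    design = DesignMatrix(X, names, {c: float(m) for c, m in zip(covariates, offsets)})
    y = table["yield_g_m2"].to_numpy(dtype=float)
    return design, y


def coefficient_profiles(
    X: DesignMatrix,
    y: np.ndarray,
    quantiles=DEFAULT_QUANTILE_GRID,
    alpha: float = 0.05,
    ci_variant: str = "nid",
) -> list[CoefficientProfile]:
    """One rank-score-CI quantile fit per grid level, stacked per covariate."""
    q = np.asarray(quantiles, dtype=float)
    if not (np.all(q > 0) & np.all(q < 1)):
        raise ValueError("quantile grid must lie within (0, 1)")
    fits = [rankscore_ci(X, y, float(p), alpha=alpha, variant=ci_variant) for p in q]
    profiles = []
    for j, name in enumerate(X.names):
        profiles.append(
            CoefficientProfile(
                covariate=name,
                quantiles=q,
                estimate=np.array([f.coefficients[j] for f in fits]),
                ci_lower=np.array([f.ci_lower[j] for f in fits]),
                ci_upper=np.array([f.ci_upper[j] for f in fits]),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[CoefficientProfile]) -> pd.DataFrame:
    """Tidy (covariate, quantile, estimate, lower, upper, significant) table."""
    rows = []
    for pr in profiles:
        for i, p in enumerate(pr.quantiles):
            rows.append(
                {
                    "covariate": pr.covariate,
                    "quantile": float(p),
                    "estimate": pr.estimate[i],
                    "ci_lower": pr.ci_lower[i],
                    "ci_upper": pr.ci_upper[i],
                    "significant": bool(pr.significant[i]),
                }
            )
    return pd.DataFrame(rows)


def compute_swp(table: pd.DataFrame) -> pd.DataFrame:
    """Stress-weighted performance SWP = y_s / sqrt(y_c), one row per accession.

    y_s is yield under saline and y_c under non-saline (control) irrigation;
    SWP rewards accessions that maintain saline yield without simply being
    low-yielding overall.  Units g^(1/2)/m.
    """
    table = _paired_table(table)
    wide = table.pivot(index="accession_id", columns="condition", values="yield_g_m2")
    if SALINE not in wide or NON_SALINE not in wide:
        raise ValueError("need both conditions to compute SWP")
    y_s = wide[SALINE]
    y_c = wide[NON_SALINE]
    bad_c = y_c[y_c <= 0]
    if len(bad_c):
        raise ValueError(
            f"non-saline yield must be positive; offending accessions: "
            f"{sorted(bad_c.index)[:10]}"
        )
    bad_s = y_s[y_s < 0]
    if len(bad_s):
        raise ValueError(
            f"saline yield must be non-negative; offending accessions: "
            f"{sorted(bad_s.index)[:10]}"
        )
    out = pd.DataFrame(
        {
            "accession_id": wide.index,
            "y_s": y_s.to_numpy(dtype=float),
            "y_c": y_c.to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    out["swp"] = out["y_s"] / np.sqrt(out["y_c"])
    return out


def swp_trait_model(
    table: pd.DataFrame,
    quantiles=DEFAULT_QUANTILE_GRID,
    alpha: float = 0.05,
    covariates: list[str] | None = None,
    ci_variant: str = "nid",
) -> tuple[list[CoefficientProfile], OLSResult]:
    """Quantile profiles (plus the OLS comparison) of SWP on saline traits.

    Covariates are the saline-condition trait values, centered to mean 0;
    the response is SWP (n = number of paired accessions).
    """
    if covariates is None:
        covariates = list(TRAIT_NAMES)
    swp = compute_swp(table)
    saline = (
        table[table["condition"] == SALINE]
        .set_index("accession_id")
        .loc[swp["accession_id"]]
    )
    Z = saline[covariates].to_numpy(dtype=float)
    design = quantreg.center_covariates(
        DesignMatrix.from_covariates(Z, list(covariates))
    )
    y = swp["swp"].to_numpy(dtype=float)
    profiles = coefficient_profiles(design, y, quantiles, alpha, ci_variant)
    ols = fit_ols(design, y)
    return profiles, ols
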