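"""Selection of high-salt-tolerant, high-yielding accessions.

An accession is salt tolerant when its saline yield lies strictly above
the fitted no-intercept conditional quantile line of saline yield on
non-saline yield at level p1, and high yielding when its saline yield lies
strictly above the marginal empirical quantile at level p2.  The "top"
category is the intersection of the two.  Defaults p1 = 0.85, p2 = 0.90.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantreg import DesignMatrix, fit_quantile_regression

__all__ = ["select_top_accessions", "marginal_quantile"]


def marginal_quantile(values, p: float) -> float:
    """Inf-based (type-1) empirical quantile: inf{t : F(t) >= p}."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty sample")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"quantile level must be in (0, 1], got {p}")
    idx = max(int(np.ceil(len(v) * p)) - 1, 0)
    return float(v[idx])


def select_top_accessions(
    swp_table: pd.DataFrame,
    p1: float = 0.85,
    p2: float = 0.9,
    orientation: str = "saline_on_nonsaline",
    intercept: bool = False,
) -> pd.DataFrame:
    """Classify accessions by the conditional/marginal quantile intersection.

    Parameters
    ----------
    swp_table : DataFrame with accession_id, y_s, y_c columns.
    p1 : conditional-quantile level of the fitted line.
    p2 : marginal-quantile level of the yield threshold.
    orientation : "saline_on_nonsaline" (default; response = saline yield,
        matching the marginal threshold also being on saline yield) or
        "nonsaline_on_saline".
    intercept : include an intercept in the conditional line (the default
        model is the through-the-origin form y = a x + eps).

    Returns the input rows plus ``above_conditional``, ``above_marginal``
    and ``category`` in {"top", "tolerant_only", "other"}.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("p1 and p2 must lie in (0, 1)")
    if len(swp_table) < 3:
        raise ValueError("need at least 3 accessions")
    if orientation == "saline_on_nonsaline":
        resp, cov = "y_s", "y_c"
    elif orientation == "nonsaline_on_saline":
        resp, cov = "y_c", "y_s"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    y = swp_table[resp].to_numpy(dtype=float)
    x = swp_table[cov].to_numpy(dtype=float)
    if np.allclose(x, 0.0):
        raise ValueError("conditioning yield is identically zero")

    if intercept:
        design = DesignMatrix.from_covariates(x[:, None], [cov])
        fit = fit_quantile_regression(design, y, p1)
        fitted = fit.coefficients[0] + fit.coefficients[1] * x
    else:
        # no-intercept design: bypass the unit-column convention
        d = DesignMatrix.__new__(DesignMatrix)
        d.X, d.names, d.offsets = x[:, None], [cov], {}
        fit = fit_quantile_regression(d, y, p1)
        fitted = fit.coefficients[0] * x

    above_cond = y > fitted + 1e-12
    thr = marginal_quantile(y, p2)
    above_marg = y > thr + 1e-12

    out = swp_table.copy()
    out["above_conditional"] = above_cond
    out["above_marginal"] = above_marg
    out["category"] = np.where(
        above_cond & above_marg, "top", np.where(above_cond, "tolerant_only", "other")
    )
    out.attrs["conditional_slope"] = float(fit.coefficients[-1])
    out.attrs["marginal_threshold"] = thr
    out.attrs["p1"], out.attrs["p2"] = p1, p2
    return out
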