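"""Linear quantile regression by pinball-loss linear programming.

The conditional quantile model is ``Q_y(p | x) = x' beta(p)``; the
coefficient vector solves

    min_beta  sum_i rho_p(y_i - x_i' beta),

with the check (pinball) loss ``rho_p(u) = u (p - 1[u < 0])``.  The
minimisation is carried out exactly as a linear program (residuals split
into positive and negative parts, solved with the HiGHS dual simplex so a
vertex of the feasible polytope is returned).

Confidence intervals invert regression rank-score tests: a candidate value
``xi`` for one coefficient is acceptable when the rank-score statistic of
H0: beta_j = xi is inside the normal acceptance region.  Both the iid and
the non-iid ("nid", locally weighted) score variants are available; the nid
variant is the default because field data of this kind are heteroscedastic.
A paired (row-level) bootstrap is the fallback when the inversion cannot
bracket the acceptance boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.stats import norm, t as student_t

__all__ = [
    "DesignMatrix",
    "QuantileFitResult",
    "OLSResult",
    "PinballQuantileRegressor",
    "pinball_loss",
    "fit_quantile_regression",
    "rankscore_ci",
    "fit_ols",
    "vif",
    "center_covariates",
]

_RESID_TOL = 1e-9


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient; names the dependent columns."""


@dataclass
class DesignMatrix:
    """An n x (1+k) design whose first column is the unit vector.

    ``offsets`` records the centering constant subtracted from each
    covariate column so fitted intercepts can be mapped back to the raw
    covariate scale.
    """

    X: np.ndarray
    names: list[str]
    offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        if len(self.names) != self.X.shape[1]:
            raise ValueError("one name per design column required")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the unit vector")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_covariates(cls, Z: np.ndarray, names: list[str] | None = None) -> "DesignMatrix":
        """Prepend an intercept column to a raw covariate block."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] == 1 and Z.shape[1] > 1 and names is not None and len(names) == 1:
            Z = Z.T
        if names is None:
            names = [f"x{j + 1}" for j in range(Z.shape[1])]
        X = np.column_stack([np.ones(Z.shape[0]), Z])
        return cls(X, ["intercept", *names])


@dataclass
class QuantileFitResult:
    """Coefficients of one quantile fit, with optional rank-score CIs."""

    p: float
    coefficients: np.ndarray
    names: list[str]
    objective: float
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    alpha: float | None = None
    method_tag: str | None = None

    @property
    def significant(self) -> np.ndarray:
        """True where the 1-alpha interval excludes zero (strictly)."""
        if self.ci_lower is None:
            raise ValueError("no confidence intervals attached to this fit")
        return (self.ci_lower > 0.0) | (self.ci_upper < 0.0)


@dataclass
class OLSResult:
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    names: list[str]
    residual_df: int


def pinball_loss(u, p: float):
    """Check loss rho_p(u) = u (p - 1[u < 0]); vectorised over ``u``."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {p}")
    u = np.asarray(u, dtype=float)
    return np.where(u >= 0, p * u, (p - 1.0) * u)


def _as_design(X, names=None) -> DesignMatrix:
    if isinstance(X, DesignMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.allclose(X[:, 0], 1.0):
        if names is None:
            names = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
        return DesignMatrix(X, list(names))
    return DesignMatrix.from_covariates(X, names)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise RankDeficientDesignError(
            f"more columns ({X.shape[1]}) than rows ({X.shape[0]})"
        )
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # pivoted QR flags which columns are linearly dependent on earlier ones
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[r:])
        raise RankDeficientDesignError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"dependent columns: {bad}"
        )


def _solve_pinball_lp(X: np.ndarray, y: np.ndarray, p: float, return_dual: bool = False):
    """Exact pinball minimiser via the bounded dual LP.

    The dual of the pinball program is  max y'a  s.t.  X'a = (1-p) X'1,
    0 <= a <= 1; the equality-constraint marginals recover beta exactly and
    ``a`` holds the regression rank scores.  Solved with the HiGHS dual
    simplex, so the reported solution is a vertex (basic) solution.
    """
    n, k = X.shape
    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=(1.0 - p) * X.sum(axis=0),
        bounds=(0.0, 1.0),
        method="highs-ds",
    )
    if res.status != 0:
        raise RuntimeError(
            f"quantile-regression LP did not solve (status {res.status}: {res.message}); "
            "this indicates an internal failure for a full-rank design"
        )
    beta = -np.asarray(res.eqlin.marginals)
    objective = float(np.sum(pinball_loss(y - X @ beta, p)))
    if return_dual:
        return beta, objective, np.asarray(res.x)
    return beta, objective


def fit_quantile_regression(X, y, p: float, names=None) -> QuantileFitResult:
    """Fit ``Q_y(p|x) = x' beta(p)`` by exact LP minimisation of the pinball sum.

    The returned solution is a vertex of the LP polytope; at most
    ``n * p`` residuals are negative and at most ``n * (1-p)`` positive.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {p}")
    d = _as_design(X, names)
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != d.n:
        raise ValueError(f"response length {y.shape[0]} != design rows {d.n}")
    _check_rank(d.X, d.names)
    beta, obj = _solve_pinball_lp(d.X, y, p)
    return QuantileFitResult(p=p, coefficients=beta, names=list(d.names), objective=obj)


# ---------------------------------------------------------------------------
# rank-score confidence intervals


def _hall_sheather_bandwidth(n: int, p: float, alpha: float) -> float:
    z = norm.ppf(1.0 - alpha / 2.0)
    zp = norm.ppf(p)
    num = 1.5 * norm.pdf(zp) ** 2
    den = 2.0 * zp**2 + 1.0
    return n ** (-1.0 / 3.0) * z ** (2.0 / 3.0) * (num / den) ** (1.0 / 3.0)


def _nid_weights(X: np.ndarray, y: np.ndarray, p: float, alpha: float) -> np.ndarray:
    """Local conditional-density weights (difference-quotient estimate)."""
    n = X.shape[0]
    h = _hall_sheather_bandwidth(n, p, alpha)
    h = min(h, min(p, 1.0 - p) * 0.95)  # keep p +/- h inside (0, 1)
    b_hi, _ = _solve_pinball_lp(X, y, p + h)
    b_lo, _ = _solve_pinball_lp(X, y, p - h)
    dq = X @ (b_hi - b_lo)
    eps = np.finfo(float).eps ** (2.0 / 3.0)
    f = 2.0 * h / np.maximum(dq, eps)
    return np.clip(f, 0.0, None)


def _rankscore_T(Z: np.ndarray, x_tilde: np.ndarray, y_shift: np.ndarray, p: float) -> float:
    """Rank-score statistic for H0 at the current shifted response.

    The scores a_i - (1 - p) come from the dual solution of the restricted
    fit (a_i in [0, 1]), which equals p - 1[r_i < 0] off the fitted
    hyperplane and interpolates for the basic (zero-residual) rows.
    """
    _, _, a = _solve_pinball_lp(Z, y_shift, p, return_dual=True)
    b = a - (1.0 - p)
    denom = np.sqrt(p * (1.0 - p) * float(x_tilde @ x_tilde))
    return float(x_tilde @ b) / denom


def _pairs_bootstrap_ci(
    X: np.ndarray,
    y: np.ndarray,
    p: float,
    j: int,
    alpha: float,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    n = X.shape[0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb, yb = X[idx], y[idx]
        if np.linalg.matrix_rank(Xb) < Xb.shape[1]:
            stats[b] = np.nan
            continue
        beta_b, _ = _solve_pinball_lp(Xb, yb, p)
        stats[b] = beta_b[j]
    stats = stats[~np.isnan(stats)]
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def rankscore_ci(
    X,
    y,
    p: float,
    alpha: float = 0.05,
    variant: str = "nid",
    names=None,
    n_boot: int = 1000,
    random_state: int | None = 0,
    max_bracket_expansions: int = 4,
    coef_indices=None,
    bisect_rtol: float = 1e-2,
) -> QuantileFitResult:
    """Quantile fit plus per-coefficient rank-score test-inversion intervals.

    For each coefficient the interval is the set of candidate values ``xi``
    at which the rank-score test of H0: beta_j = xi fails to reject at
    level ``alpha``.  The acceptance boundary is located by bisection on
    the (monotone in ``xi``) standardised score, bracketed at +/- 10
    classical standard errors around the point estimate; intervals that
    cannot be bracketed fall back to a paired bootstrap and tag the result.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if variant not in ("nid", "iid"):
        raise ValueError(f"unknown rank-score variant {variant!r}")
    d = _as_design(X, names)
    y = np.asarray(y, dtype=float).ravel()
    _check_rank(d.X, d.names)
    fit = fit_quantile_regression(d, y, p)
    n, k = d.X.shape

    # classical OLS standard errors only define the bracketing window
    ols = fit_ols(d, y)
    z_crit = norm.ppf(1.0 - alpha / 2.0)

    if variant == "nid":
        w = _nid_weights(d.X, y, p, alpha)
    else:
        w = np.ones(n)

    lo = np.full(k, np.nan)
    hi = np.full(k, np.nan)
    tag = f"rankscore_{variant}"
    rng = np.random.default_rng(random_state)
    indices = range(k) if coef_indices is None else list(coef_indices)

    for j in indices:
        Z = np.delete(d.X, j, axis=1)
        xj = d.X[:, j]
        # (weighted) projection of the tested column off the nuisance block
        WZ = Z * w[:, None]
        coef, *_ = np.linalg.lstsq(WZ.T @ Z, WZ.T @ xj, rcond=None)
        x_tilde = xj - Z @ coef

        def T(xi: float) -> float:
            return _rankscore_T(Z, x_tilde, y - xi * xj, p)

        bhat = fit.coefficients[j]
        se = max(ols.std_errors[j], 1e-12)
        half = 10.0 * se
        ok = False
        for _ in range(max_bracket_expansions + 1):
            t_lo, t_hi = T(bhat - half), T(bhat + half)
            if t_lo > z_crit and t_hi < -z_crit:
                ok = True
                break
            half *= 2.0
        if not ok:
            warnings.warn(
                f"rank-score inversion could not bracket the acceptance region for "
                f"{d.names[j]!r}; falling back to a paired bootstrap",
                RuntimeWarning,
                stacklevel=2,
            )
            lo[j], hi[j] = _pairs_bootstrap_ci(d.X, y, p, j, alpha, n_boot, rng)
            tag = "bootstrap"
            continue

        tol = max(se * bisect_rtol, 1e-10)
        lo[j] = _bisect_boundary(T, bhat - half, bhat, z_crit, tol)
        hi[j] = _bisect_boundary(T, bhat, bhat + half, -z_crit, tol)

    # a vertex estimate always sits inside its own acceptance region; guard
    # against bisection resolution placing a boundary on the wrong side
    tested = np.array([j in set(indices) for j in range(k)])
    lo[tested] = np.minimum(lo[tested], fit.coefficients[tested])
    hi[tested] = np.maximum(hi[tested], fit.coefficients[tested])
    fit.ci_lower, fit.ci_upper, fit.alpha, fit.method_tag = lo, hi, alpha, tag
    return fit


def _bisect_boundary(T, a: float, b: float, level: float, tol: float) -> float:
    """Find the xi in [a, b] where the monotone-decreasing T crosses ``level``."""
    while b - a > tol:
        m = 0.5 * (a + b)
        if T(m) > level:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# mean regression and collinearity diagnostics


def fit_ols(X, y, names=None) -> OLSResult:
    """Least squares with classical standard errors and t-test p-values."""
    d = _as_design(X, names)
    y = np.asarray(y, dtype=float).ravel()
    _check_rank(d.X, d.names)
    n, k = d.X.shape
    if n <= k:
        raise ValueError(f"need n > columns for OLS inference (n={n}, k={k})")
    beta, _, _, _ = np.linalg.lstsq(d.X, y, rcond=None)
    resid = y - d.X @ beta
    df = n - k
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(d.X.T @ d.X)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    tstat = beta / se
    pvals = 2.0 * student_t.sf(np.abs(tstat), df)
    return OLSResult(beta, se, pvals, list(d.names), df)


def vif(X, names=None) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from regressing covariate j on the remaining covariates
    (intercept included).  Perfectly collinear covariates get ``inf``.
    """
    d = _as_design(X, names)
    k = d.n_columns - 1
    if k < 2:
        raise ValueError("VIF needs at least two covariates")
    out: dict[str, float] = {}
    for j in range(1, d.n_columns):
        target = d.X[:, j]
        others = np.delete(d.X, j, axis=1)  # keeps the intercept
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(np.sum((target - target.mean()) ** 2))
        if tss <= 0:
            out[d.names[j]] = np.inf
            continue
        r2 = 1.0 - float(resid @ resid) / tss
        out[d.names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def center_covariates(X, names=None) -> DesignMatrix:
    """Center every covariate column to mean zero, recording the offsets.

    Slopes are unchanged by centering; the intercept becomes the fitted
    response at the covariate means.  Constant columns center to zero and
    trigger a warning (they are then collinear with the intercept).
    """
    d = _as_design(X, names)
    Xc = d.X.copy()
    offsets: dict[str, float] = {}
    for j in range(1, d.n_columns):
        mu = float(Xc[:, j].mean())
        if np.allclose(Xc[:, j], Xc[0, j]):
            warnings.warn(
                f"covariate {d.names[j]!r} is constant; centering leaves an "
                "all-zero column",
                RuntimeWarning,
                stacklevel=2,
            )
        Xc[:, j] -= mu
        offsets[d.names[j]] = mu
    return DesignMatrix(Xc, list(d.names), offsets)


# ---------------------------------------------------------------------------
# estimator facade


class PinballQuantileRegressor:
    """Scikit-learn style linear quantile regressor with rank-score CIs.

    Parameters
    ----------
    quantile : float
        Level p of the conditional quantile to fit.
    alpha : float
        Significance level of the test-inversion confidence intervals.
    ci : {"rankscore_nid", "rankscore_iid", "bootstrap", None}
        Interval method; None skips interval construction.
    fit_intercept : bool
        Prepend a unit column when X does not already carry one.
    n_bootstrap : int
        Replicates for the bootstrap fallback.
    random_state : int
        Seed for the bootstrap fallback.
    """

    def __init__(
        self,
        quantile: float = 0.5,
        alpha: float = 0.05,
        ci: str | None = "rankscore_nid",
        fit_intercept: bool = True,
        n_bootstrap: int = 1000,
        random_state: int = 0,
    ):
        self.quantile = quantile
        self.alpha = alpha
        self.ci = ci
        self.fit_intercept = fit_intercept
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "quantile": self.quantile,
            "alpha": self.alpha,
            "ci": self.ci,
            "fit_intercept": self.fit_intercept,
            "n_bootstrap": self.n_bootstrap,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "PinballQuantileRegressor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _design(self, X) -> DesignMatrix:
        if isinstance(X, DesignMatrix):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept and not (X.shape[1] and np.allclose(X[:, 0], 1.0)):
            return DesignMatrix.from_covariates(X)
        if self.fit_intercept:
            return _as_design(X)
        names = [f"x{j + 1}" for j in range(X.shape[1])]
        d = DesignMatrix.__new__(DesignMatrix)
        d.X, d.names, d.offsets = X, names, {}
        return d

    def fit(self, X, y) -> "PinballQuantileRegressor":
        d = self._design(X)
        y = np.asarray(y, dtype=float).ravel()
        if self.ci is None:
            res = fit_quantile_regression(d, y, self.quantile)
        elif self.ci in ("rankscore_nid", "rankscore_iid"):
            res = rankscore_ci(
                d,
                y,
                self.quantile,
                alpha=self.alpha,
                variant=self.ci.split("_")[1],
                n_boot=self.n_bootstrap,
                random_state=self.random_state,
            )
        elif self.ci == "bootstrap":
            res = fit_quantile_regression(d, y, self.quantile)
            rng = np.random.default_rng(self.random_state)
            k = d.n_columns if isinstance(d, DesignMatrix) else d.X.shape[1]
            lo = np.empty(k)
            hi = np.empty(k)
            for j in range(k):
                lo[j], hi[j] = _pairs_bootstrap_ci(
                    d.X, y, self.quantile, j, self.alpha, self.n_bootstrap, rng
                )
            res.ci_lower = np.minimum(lo, res.coefficients)
            res.ci_upper = np.maximum(hi, res.coefficients)
            res.alpha, res.method_tag = self.alpha, "bootstrap"
        else:
            raise ValueError(f"unknown ci method {self.ci!r}")
        self.result_ = res
        has_intercept = res.names and res.names[0] == "intercept"
        self.intercept_ = res.coefficients[0] if has_intercept else 0.0
        self.coef_ = res.coefficients[1:] if has_intercept else res.coefficients
        self.objective_ = res.objective
        self.feature_names_in_ = np.asarray(res.names[1:] if has_intercept else res.names)
        self.n_features_in_ = len(self.coef_)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] == self.n_features_in_:
            return self.intercept_ + X @ self.coef_
        return X @ self.result_.coefficients

    def score(self, X, y) -> float:
        """Negative mean pinball loss (higher is better)."""
        y = np.asarray(y, dtype=float).ravel()
        return -float(np.mean(pinball_loss(y - self.predict(X), self.quantile)))
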