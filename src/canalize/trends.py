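"""Trend regressions, LOESS smoothing, and generalized-differences
correlation for autocorrelated time series.

The headline trend test regresses species-level CVs on bin mid-age.  The
LOESS smoother is a locally weighted polynomial with tricube weights over
span-fraction neighborhoods (the classic Cleveland smoother, degree 2 and
span 0.75 by default).

Correlating two time series that each carry trend and autocorrelation
inflates significance; the generalized-differences procedure first
detrends each series by OLS on time, estimates the lag-1 autocorrelation
``rho`` of the residuals ``e``, and forms ``gd_i = e_{i+1} - rho * e_i``
before correlating the transformed series (Spearman by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TrendFit",
    "LoessFit",
    "GenDiffResult",
    "fit_ols",
    "fit_loess",
    "subset_regressions",
    "sample_size_diagnostics",
    "generalized_differences",
    "gen_diff_correlation",
    "spearman_exact",
]


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_slope: float
    n_points: int
    residuals: np.ndarray
    label: str = "full"


@dataclass
class LoessFit:
    span: float
    degree: int
    x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray

    def confidence_band(self, z: float = 1.96):
        return self.fitted - z * self.se, self.fitted + z * self.se


@dataclass
class GenDiffResult:
    rho_resid: tuple[float, float]   # lag-1 residual autocorrelation per series
    transformed: tuple[np.ndarray, np.ndarray]
    rho: float                       # correlation of the transformed pair
    p: float                         # two-sided
    method: str = "spearman"
    dropped_bins: list[str] = field(default_factory=list)


def fit_ols(x, y, label: str = "full") -> TrendFit:
    """Least-squares line with intercept; two-sided slope p from the
    t statistic on n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        p_slope=float(model.pvalues[1]),
        n_points=int(x.size),
        residuals=np.asarray(model.resid),
        label=label,
    )


def _loess_weights(x: np.ndarray, x0: float, span: float) -> np.ndarray:
    """Tricube weights of the span-fraction neighborhood around x0,
    matching the classic implementation: the window radius is the distance
    to the floor(span*n)-th nearest point (inflated by span for span>1)."""
    n = x.size
    d = np.abs(x - x0)
    q = int(min(math.floor(span * n + 1e-9), n))
    h = np.partition(d, q - 1)[q - 1]
    if span > 1.0:
        h *= span
    if h <= 0:
        w = (d == 0).astype(float)
        return w
    u = np.clip(d / h, 0.0, 1.0)
    return (1.0 - u**3) ** 3


def fit_loess(x, y, span: float = 0.75, degree: int = 2) -> LoessFit:
    """Locally weighted polynomial regression evaluated at the observed x.

    Pointwise standard errors come from the smoother's linear-operator
    rows: ``se_i = sigma * ||l_i||`` with ``sigma^2 = RSS / tr[(I-L)(I-L)']``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y lengths differ")
    if n < degree + 2:
        raise ValueError("need at least degree + 2 points")
    if int(math.floor(span * n + 1e-9)) < degree + 1:
        raise ValueError("span too small for the local polynomial degree")

    L = np.zeros((n, n))
    for i, x0 in enumerate(x):
        w = _loess_weights(x, x0, span)
        X = np.vander(x - x0, N=degree + 1, increasing=True)
        XtW = X.T * w
        # row of the linear smoother: e1' (X'WX)^{-1} X'W
        beta_rows = np.linalg.lstsq(XtW @ X, XtW, rcond=None)[0]
        L[i] = beta_rows[0]
    fitted = L @ y
    resid = y - fitted
    I_L = np.eye(n) - L
    denom = float(np.trace(I_L @ I_L.T))
    sigma2 = float(resid @ resid) / denom if denom > 0 else 0.0
    se = np.sqrt(np.maximum(sigma2, 0.0)) * np.linalg.norm(L, axis=1)
    return LoessFit(span=span, degree=degree, x=x, fitted=fitted, se=se)


def subset_regressions(
    x, y, mode: str, periods=None, exclude_bin: str | None = None,
    invariant_tol: float = 0.0,
) -> TrendFit:
    """OLS trend on a filtered subset of species-level points.

    mode ``exclude_invariant`` removes points with y (CV) equal to zero;
    mode ``exclude_bin`` removes points whose period equals
    ``exclude_bin`` (``periods`` must then be given, one label per point).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "exclude_invariant":
        keep = y > invariant_tol
        label = "exclude_invariant"
    elif mode == "exclude_bin":
        if periods is None or exclude_bin is None:
            raise ValueError("exclude_bin mode needs periods and exclude_bin")
        from .timescale import canonical_period

        target = canonical_period(exclude_bin)
        keep = np.array([canonical_period(p) != target for p in periods])
        label = f"exclude_{target}"
    else:
        raise ValueError(f"unknown subset mode {mode!r}")
    return fit_ols(x[keep], y[keep], label=label)


def sample_size_diagnostics(summaries, series) -> tuple[TrendFit, TrendFit]:
    """Two sampling-artifact checks: species CV against specimens per
    species, and bin mean CV against species per bin."""
    cv = np.array([s.cv for s in summaries], dtype=float)
    n_spec = np.array([s.n_specimens for s in summaries], dtype=float)
    if np.ptp(cv) == 0:
        # degenerate all-invariant case: slope is exactly 0 by construction
        fit1 = TrendFit(0.0, 0.0, 0.0, 0.0, 1.0, len(cv), np.zeros(len(cv)),
                        label="cv_vs_n_specimens")
    else:
        fit1 = fit_ols(n_spec, cv, label="cv_vs_n_specimens")
    if np.ptp(series.m) == 0:
        fit2 = TrendFit(0.0, float(series.m[0]), 0.0, 0.0, 1.0, len(series),
                        np.zeros(len(series)), label="mean_cv_vs_n_species")
    else:
        fit2 = fit_ols(series.n.astype(float), series.m, label="mean_cv_vs_n_species")
    return fit1, fit2


def generalized_differences(y, t):
    """Detrend, estimate lag-1 residual autocorrelation, and difference it
    out.

    Returns ``(gd, rho_resid, residuals)`` where ``gd_i = e_{i+1} -
    rho_resid * e_i`` has length n−1.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.size != t.size:
        raise ValueError("y and t lengths differ")
    if y.size < 4:
        raise ValueError("need at least 4 points")
    fit = fit_ols(t, y)
    e = fit.residuals
    s2 = float(e @ e)
    if s2 <= 1e-24 * max(1.0, float(y @ y)):
        raise ValueError("series carries no signal after detrending")
    rho = float(e[:-1] @ e[1:]) / s2
    gd = e[1:] - rho * e[:-1]
    return gd, rho, e


def spearman_exact(a, b) -> tuple[float, float]:
    """Spearman rank correlation with an exact two-sided permutation
    p-value (all n! rank permutations); intended for n <= 9."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom = math.sqrt(float(ra_c @ ra_c) * float(rb_c @ rb_c))
    if denom == 0:
        return float("nan"), float("nan")
    rho = float(ra_c @ rb_c) / denom
    perms = np.array(list(itertools.permutations(rb_c)))
    rhos = perms @ ra_c / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p


def gen_diff_correlation(
    y1, y2, t, method: str = "spearman", exact_max_n: int = 9,
) -> GenDiffResult:
    """Correlation of two series after generalized differencing of each.

    Both series must share the time axis ``t`` (undefined bins removed
    beforehand).  Spearman rho by default, with an exact permutation
    p-value when the transformed length is at most ``exact_max_n``;
    Pearson available via ``method="pearson"``.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (y1.size == y2.size == t.size):
        raise ValueError("series and time axis lengths differ")
    gd1, rho1, _ = generalized_differences(y1, t)
    gd2, rho2, _ = generalized_differences(y2, t)
    if gd1.size < 3:
        raise ValueError("fewer than 3 transformed pairs")
    if method == "pearson":
        rho, p = stats.pearsonr(gd1, gd2)
    elif method == "spearman":
        if gd1.size <= exact_max_n:
            rho, p = spearman_exact(gd1, gd2)
        else:
            rho, p = stats.spearmanr(gd1, gd2)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return GenDiffResult(
        rho_resid=(rho1, rho2),
        transformed=(gd1, gd2),
        rho=float(rho),
        p=float(p),
        method=method,
    )
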