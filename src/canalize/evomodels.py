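"""Maximum-likelihood fitting and AICc comparison of trait-evolution models.

Three classic models for a time series of trait means (here, per-bin mean
CVs with sampling variances) are supported:

Stasis
    Bin means fluctuate independently around a constant optimum ``theta``
    with variance ``omega``.
URW (unbiased random walk)
    Evolutionary increments are independent Gaussians with zero mean and
    variance ``sigma2_s`` per unit time.
GRW (general / directional random walk)
    As URW but with a non-zero step mean ``mu_s``, producing a trend; a
    negative ``mu_s`` on a variation series is the signature of
    canalisation.

Each model is available in two parameterizations:

``joint``
    The observed means ``m`` are one draw from a multivariate normal.  For
    the random walks the mean is ``a + mu_s * elapsed`` and the covariance
    is ``sigma2_s * min(t_i, t_j)`` plus the sampling variance ``eps`` on
    the diagonal; stasis has mean ``theta`` and diagonal covariance
    ``omega + eps``.
``ad``
    (Ancestor–descendant) successive differences ``d_i = m_{i+1} - m_i``
    are independent normals ``N(mu_s * dt, sigma2_s * dt + eps_i +
    eps_{i+1})``; stasis evaluates ``m_i ~ N(theta, omega + eps_i)`` for
    bins 2..B (the first sample conditions the series).

Fitting profiles the mean parameters out analytically by generalized least
squares, leaving a one-dimensional bounded optimization over the log of the
variance parameter, run from several perturbed starts.  Support is
summarized by the small-sample Akaike information criterion
``AICc = -2 logL + 2K + 2K(K+1)/(N-K-1)`` and Akaike weights
``w_j = exp(-Delta_j/2) / sum exp(-Delta/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .timescale import BinSeries

__all__ = [
    "MODELS",
    "ModelFitResult",
    "ModeComparison",
    "loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "compare_modes",
]

#: Reporting order; also the tie-break order for equal AICc scores.
MODELS = ("Stasis", "URW", "GRW")

_VAR_FLOOR = 1e-9
_LOGL_TOL = 1e-8

# (K, number of GLS-profiled mean parameters q) per (model, parameterization)
_K = {
    ("GRW", "joint"): 3, ("URW", "joint"): 2, ("Stasis", "joint"): 2,
    ("GRW", "ad"): 2, ("URW", "ad"): 1, ("Stasis", "ad"): 2,
}
_Q = {
    ("GRW", "joint"): 2, ("URW", "joint"): 1, ("Stasis", "joint"): 1,
    ("GRW", "ad"): 1, ("URW", "ad"): 0, ("Stasis", "ad"): 1,
}


@dataclass
class ModelFitResult:
    model: str
    parameterization: str
    params: dict[str, float]
    logL: float
    K: int
    n_obs: int
    aicc: float
    akaike_weight: float | None = None
    converged: bool = True
    messages: list[str] = field(default_factory=list)


@dataclass
class ModeComparison:
    """Joint comparison of the three models on one series."""

    fits: list[ModelFitResult]
    winner: str | None
    insufficient: bool = False
    reason: str | None = None

    def best(self) -> ModelFitResult | None:
        for f in self.fits:
            if f.model == self.winner:
                return f
        return None


def aicc(logL: float, K: int, n_obs: int) -> float:
    """Small-sample Akaike information criterion."""
    if n_obs <= K + 1:
        raise ValueError(f"AICc undefined: n_obs={n_obs} <= K+1={K + 1}")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n_obs - K - 1)


def akaike_weights(scores) -> np.ndarray:
    """Proportional support for each model from its AICc score."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0 or not np.all(np.isfinite(scores)):
        raise ValueError("scores must be non-empty and finite")
    delta = scores - scores.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


# ---------------------------------------------------------------------------
# likelihood machinery


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Log density of y under N(mean, cov) via a Cholesky factor; returns
    -inf when cov is not positive definite."""
    try:
        c, low = linalg.cho_factor(cov, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    diag = np.diag(c)
    if np.any(diag <= 0):
        return -np.inf
    resid = y - mean
    alpha = linalg.cho_solve((c, low), resid, check_finite=False)
    logdet = 2.0 * np.sum(np.log(diag))
    return -0.5 * (len(y) * math.log(2.0 * math.pi) + logdet + resid @ alpha)


def _design(model: str, parameterization: str, series: BinSeries):
    """Return (y, X, base covariance builder) for the GLS profile."""
    t = series.elapsed
    eps = series.eps
    m = series.m
    if parameterization == "joint":
        if model in ("URW", "GRW"):
            C = np.minimum.outer(t, t)
            X = np.ones((len(t), 1)) if model == "URW" else np.column_stack([np.ones_like(t), t])
            return m, X, lambda v: v * C + np.diag(eps)
        X = np.ones((len(t), 1))
        return m, X, lambda v: np.diag(v + eps)
    # ancestor-descendant
    if model in ("URW", "GRW"):
        d = np.diff(m)
        dt = np.diff(t)
        evar = eps[:-1] + eps[1:]
        X = np.zeros((len(d), 0)) if model == "URW" else dt[:, None]
        return d, X, lambda v: np.diag(v * dt + evar)
    y = m[1:]
    X = np.ones((len(y), 1))
    return y, X, lambda v: np.diag(v + eps[1:])


def _gls_profile(y, X, V):
    """GLS mean estimate and profile log-likelihood for covariance V."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None, -np.inf
    if np.any(np.diag(c) <= 0):
        return None, -np.inf
    if X.shape[1] == 0:
        beta = np.zeros(0)
        mean = np.zeros_like(y)
    else:
        Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
        Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
        try:
            beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        except np.linalg.LinAlgError:
            return None, -np.inf
        mean = X @ beta
    resid = y - mean
    alpha = linalg.cho_solve((c, low), resid, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    ll = -0.5 * (len(y) * math.log(2.0 * math.pi) + logdet + resid @ alpha)
    return beta, ll


def _check_model(model: str, parameterization: str) -> tuple[str, str]:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    parameterization = parameterization.lower()
    if parameterization not in ("joint", "ad"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return model, parameterization


def loglik(
    model: str,
    params: dict[str, float],
    series: BinSeries,
    parameterization: str = "joint",
) -> float:
    """Log-likelihood of a fully specified model at given parameter values.

    Raises ``ValueError`` when a bin contributes zero total variance (the
    covariance is then singular) naming the offending bin.
    """
    model, parameterization = _check_model(model, parameterization)
    t, m, eps = series.elapsed, series.m, series.eps

    if model == "Stasis":
        omega = float(params["omega"])
        theta = float(params["theta"])
        if omega < 0:
            raise ValueError("omega must be >= 0")
        idx = range(len(m)) if parameterization == "joint" else range(1, len(m))
        total = np.array([omega + eps[i] for i in idx])
        _raise_on_zero_variance(total, series, list(idx))
        y = m[list(idx)]
        return float(np.sum(-0.5 * (np.log(2 * np.pi * total) + (y - theta) ** 2 / total)))

    sigma2 = float(params["sigma2_s"])
    if sigma2 < 0:
        raise ValueError("sigma2_s must be >= 0")
    mu = 0.0 if model == "URW" else float(params["mu_s"])
    if parameterization == "joint":
        a = float(params["a"])
        cov = sigma2 * np.minimum.outer(t, t) + np.diag(eps)
        _raise_on_zero_variance(np.diag(cov), series, list(range(len(m))))
        ll = _mvn_loglik(m, a + mu * t, cov)
        if not np.isfinite(ll):
            raise ValueError("covariance matrix is singular")
        return float(ll)
    d, dt = np.diff(m), np.diff(t)
    total = sigma2 * dt + eps[:-1] + eps[1:]
    _raise_on_zero_variance(total, series, list(range(1, len(m))))
    return float(np.sum(-0.5 * (np.log(2 * np.pi * total) + (d - mu * dt) ** 2 / total)))


def _raise_on_zero_variance(variances, series: BinSeries, bins: list[int]) -> None:
    bad = np.flatnonzero(np.asarray(variances) <= 0.0)
    if bad.size:
        name = series.names[bins[bad[0]]]
        raise ValueError(
            f"zero total variance at bin {name!r}: likelihood is singular"
        )


# ---------------------------------------------------------------------------
# fitting


def _start_variance(model: str, parameterization: str, series: BinSeries) -> float:
    m, t, eps = series.m, series.elapsed, series.eps
    if model == "Stasis":
        return max(float(np.var(m, ddof=0) - np.mean(eps)), _VAR_FLOOR)
    d, dt = np.diff(m), np.diff(t)
    return max(float(np.mean(d**2 / dt)), _VAR_FLOOR)


def fit_model(
    model: str,
    series: BinSeries,
    parameterization: str = "joint",
    seed: int | None = None,
    n_restarts: int = 3,
    correct_variance_bias: bool = True,
) -> ModelFitResult:
    """Maximum-likelihood fit of one model to a binned series.

    The mean parameters are profiled out by GLS; the single variance
    parameter is optimized on a log scale (floor 1e-9) from the analytic
    start and ``n_restarts`` perturbed restarts, keeping the best optimum.

    The reported variance parameter carries a first-order
    degrees-of-freedom correction ``N/(N-q)`` (q = number of profiled mean
    parameters) against the familiar downward bias of profile-ML variance
    estimates; set ``correct_variance_bias=False`` for the raw MLE.  The
    reported ``logL`` (hence AICc) is always the uncorrected ML optimum.
    """
    model, parameterization = _check_model(model, parameterization)
    key = (model, parameterization)
    K, q = _K[key], _Q[key]
    y, X, cov_of = _design(model, parameterization, series)
    n_obs = len(y) if parameterization == "ad" and model != "Stasis" else (
        len(series) if parameterization == "joint" else len(series) - 1
    )
    if n_obs < K + 2:
        raise ValueError(
            f"{model}/{parameterization}: need n_obs >= K+2 = {K + 2}, have {n_obs}"
        )

    def negll(logv) -> float:
        _, ll = _gls_profile(y, X, cov_of(math.exp(float(np.squeeze(logv)))))
        return -ll if np.isfinite(ll) else 1e300

    v0 = _start_variance(model, parameterization, series)
    scale = float(np.var(series.m, ddof=0) + series.eps.max() + _VAR_FLOOR)
    lo, hi = math.log(_VAR_FLOOR), math.log(1e4 * scale / max(np.median(np.diff(series.elapsed)), 1e-6))
    hi = max(hi, math.log(v0) + 2.0)

    rng = np.random.default_rng(seed)
    starts = [math.log(v0), lo + 0.5]  # include the floor region: boundary
    starts += list(math.log(v0) + rng.normal(0.0, 2.0, size=n_restarts))
    best_logv, best_nll = None, np.inf
    messages: list[str] = []
    for s in starts:
        res = optimize.minimize(
            negll, x0=[np.clip(s, lo, hi)], method="L-BFGS-B",
            bounds=[(lo, hi)], options={"ftol": _LOGL_TOL, "maxiter": 500},
        )
        if res.fun < best_nll:
            best_nll, best_logv = float(res.fun), float(res.x[0])
        if not res.success:
            messages.append(str(res.message))
    # deterministic bounded polish
    res = optimize.minimize_scalar(
        negll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    if res.fun < best_nll:
        best_nll, best_logv = float(res.fun), float(res.x)
    if best_logv is None or not np.isfinite(best_nll):
        raise RuntimeError(
            f"{model}/{parameterization}: optimizer failed after restarts: {messages}"
        )
    if best_nll >= 1e299:
        raise ValueError(
            f"{model}/{parameterization}: likelihood is singular for every "
            "variance value (a bin with zero sampling variance?)"
        )

    v_hat = math.exp(best_logv)
    beta, logL = _gls_profile(y, X, cov_of(v_hat))
    v_report = v_hat * n_obs / (n_obs - q) if (correct_variance_bias and q) else v_hat
    if v_hat <= _VAR_FLOOR * 1.0001:
        v_report = v_hat  # at the floor: leave untouched, effectively zero

    params: dict[str, float] = {}
    if model == "Stasis":
        params["theta"] = float(beta[0])
        params["omega"] = v_report
    elif model == "URW":
        params["sigma2_s"] = v_report
        if parameterization == "joint":
            params["a"] = float(beta[0])
    else:
        params["sigma2_s"] = v_report
        if parameterization == "joint":
            params["a"] = float(beta[0])
            params["mu_s"] = float(beta[1])
        else:
            params["mu_s"] = float(beta[0])

    return ModelFitResult(
        model=model,
        parameterization=parameterization,
        params=params,
        logL=float(logL),
        K=K,
        n_obs=n_obs,
        aicc=aicc(float(logL), K, n_obs),
        messages=messages,
    )


def compare_modes(
    series: BinSeries,
    parameterization: str = "joint",
    seed: int | None = None,
    correct_variance_bias: bool = True,
) -> ModeComparison:
    """Fit Stasis, URW and GRW on one series and weigh them by AICc.

    Series too short for a finite AICc of every candidate (fewer than five
    bins for the joint parameterization, fewer than five increments+1 for
    ancestor–descendant) yield a structured insufficient-data result rather
    than an exception.
    """
    _, parameterization = _check_model("Stasis", parameterization)
    B = len(series)
    n_min = 5 if parameterization == "joint" else 5
    if B < n_min:
        return ModeComparison(
            fits=[], winner=None, insufficient=True,
            reason=f"need >= {n_min} bins for finite AICc of all models, have {B}",
        )
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(MODELS))]
    try:
        fits = [
            fit_model(mname, series, parameterization, seed=cs,
                      correct_variance_bias=correct_variance_bias)
            for mname, cs in zip(MODELS, child_seeds)
        ]
    except ValueError as exc:  # degenerate series, not an optimizer failure
        return ModeComparison(fits=[], winner=None, insufficient=True,
                              reason=str(exc))
    weights = akaike_weights([f.aicc for f in fits])
    for f, w in zip(fits, weights):
        f.akaike_weight = float(w)
    # tie-break: first model in MODELS order among the minimal AICc scores
    scores = np.array([f.aicc for f in fits])
    winner = fits[int(np.argmin(scores))].model
    return ModeComparison(fits=fits, winner=winner)
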