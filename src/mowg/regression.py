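"""Log-location-scale regression for right-censored lifetimes.

Taking logs of a Weibull-baseline composed lifetime X with shape
``gamma = 1/sigma`` and scale ``delta = e^mu`` yields a location-scale
error law for Y = log X:

    f(y) = (alpha c / (sigma beta^c)) e^{c z} exp(-(e^z / beta)^c)
           / [1 - (1 - alpha) exp(-(e^z / beta)^c)]^2,      z = (y - mu)/sigma
    S(y) = alpha exp(-(e^z / beta)^c)
           / [1 - (1 - alpha) exp(-(e^z / beta)^c)].

With mu_i = v_i' tau this is an accelerated-failure-time regression; the
censored log-likelihood is sum over failures of log f plus sum over
censored subjects of log S.  Note that the standardized error Z carries no
1/sigma factor in its own density (that factor belongs to Y, not Z).

Event convention: 1 = observed failure, 0 = right-censored.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .family import ParameterError, check_positive
from .inference import _numerical_hessian

__all__ = [
    "CensoredObservation",
    "RegressionParams",
    "RegressionFit",
    "lmoww_logpdf",
    "lmoww_logsf",
    "lmoww_rvs",
    "censored_loglik",
    "censored_loglik_expanded",
    "fit_regression",
    "simulate_censored_cohort",
]


@dataclasses.dataclass(frozen=True)
class CensoredObservation:
    """One subject: log-time ``y``, event flag and covariate row (leading 1)."""

    y: float
    event: int
    v: tuple

    def __post_init__(self):
        if not math.isfinite(self.y):
            raise ParameterError("log-time y must be finite")
        if self.event not in (0, 1):
            raise ParameterError("event indicator must be 0 or 1")
        if len(self.v) == 0 or self.v[0] != 1.0:
            raise ParameterError("covariate vector must start with the "
                                 "intercept entry 1")


@dataclasses.dataclass(frozen=True)
class RegressionParams:
    """(alpha, c, beta, sigma) error-law parameters plus coefficients tau."""

    alpha: float
    c: float
    beta: float
    sigma: float
    tau: tuple

    def __post_init__(self):
        check_positive(alpha=self.alpha, c=self.c, beta=self.beta,
                       sigma=self.sigma)
        object.__setattr__(self, "tau", tuple(float(t) for t in self.tau))

    @property
    def k(self) -> int:
        return 4 + len(self.tau)


@dataclasses.dataclass
class RegressionFit:
    params: RegressionParams
    se: Optional[np.ndarray]
    negloglik: float
    aic: float
    bic: float
    n: int
    r: int
    converged: bool

    def to_dict(self) -> dict:
        names = (["alpha", "c", "beta", "sigma"]
                 + [f"tau{i}" for i in range(len(self.params.tau))])
        values = [self.params.alpha, self.params.c, self.params.beta,
                  self.params.sigma, *self.params.tau]
        return {
            "params": dict(zip(names, values)),
            "se": None if self.se is None else [
                None if not math.isfinite(v) else float(v) for v in self.se
            ],
            "negloglik": self.negloglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "r": self.r,
            "converged": self.converged,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


# ---------------------------------------------------------------------------
# Density / survival of the log-lifetime
# ---------------------------------------------------------------------------

def _core(y, mu, params):
    z = (np.asarray(y, dtype=float) - mu) / params.sigma
    t = np.exp((z - math.log(params.beta)) * params.c)
    logd = np.log1p(-(1.0 - params.alpha) * np.exp(-t))
    return z, t, logd


def lmoww_logpdf(y, mu, params: RegressionParams):
    """Log density of the log-lifetime at location ``mu``."""
    z, t, logd = _core(y, mu, params)
    return (
        math.log(params.alpha) + math.log(params.c) - math.log(params.sigma)
        - params.c * math.log(params.beta)
        + params.c * z - t - 2.0 * logd
    )


def lmoww_logsf(y, mu, params: RegressionParams):
    """Log survival of the log-lifetime; -> 0 as y -> -inf."""
    _, t, logd = _core(y, mu, params)
    return math.log(params.alpha) - t - logd


def lmoww_standard_quantile(p, params: RegressionParams):
    """Quantile of the standardized error Z (mu = 0, sigma folded out)."""
    p = np.asarray(p, dtype=float)
    big_t = np.log1p(-(1.0 - params.alpha) * p) - np.log1p(-p)
    return math.log(params.beta) + np.log(big_t) / params.c


def lmoww_rvs(n: int, mu, params: RegressionParams, rng=None, seed=None):
    """Log-lifetimes ``mu + sigma Z`` by inversion sampling."""
    if rng is None:
        rng = np.random.default_rng(seed)
    z = lmoww_standard_quantile(rng.uniform(size=int(n)), params)
    return np.asarray(mu, dtype=float) + params.sigma * z


# ---------------------------------------------------------------------------
# Censored likelihood (compact and expanded forms)
# ---------------------------------------------------------------------------

def _as_arrays(data: Sequence[CensoredObservation]):
    y = np.array([o.y for o in data], dtype=float)
    event = np.array([o.event for o in data], dtype=int)
    V = np.array([o.v for o in data], dtype=float)
    return y, event, V


def censored_loglik(data: Sequence[CensoredObservation],
                    params: RegressionParams) -> float:
    """``sum_F log f(y_i) + sum_C log S(y_i)`` with mu_i = v_i' tau."""
    y, event, V = _as_arrays(data)
    if np.linalg.matrix_rank(V) < V.shape[1]:
        raise ParameterError("design matrix is rank deficient")
    mu = V @ np.asarray(params.tau)
    f_mask = event == 1
    total = 0.0
    if np.any(f_mask):
        total += float(np.sum(lmoww_logpdf(y[f_mask], mu[f_mask], params)))
    if np.any(~f_mask):
        total += float(np.sum(lmoww_logsf(y[~f_mask], mu[~f_mask], params)))
    return total


def censored_loglik_expanded(data: Sequence[CensoredObservation],
                             params: RegressionParams) -> float:
    """The same likelihood written out termwise (cross-check form):

    r log(alpha c / (sigma beta^c)) + c sum_F z_i - beta^-c sum_F e^{c z_i}
    - 2 sum_F log(1 - (1-alpha) e^{-(e^{z_i}/beta)^c}) + (n - r) log alpha
    - beta^-c sum_C e^{c z_i} - sum_C log(1 - (1-alpha) e^{-(e^{z_i}/beta)^c}).
    """
    y, event, V = _as_arrays(data)
    mu = V @ np.asarray(params.tau)
    z = (y - mu) / params.sigma
    t = np.exp((z - math.log(params.beta)) * params.c)
    logd = np.log1p(-(1.0 - params.alpha) * np.exp(-t))
    F = event == 1
    C = ~F
    r = int(F.sum())
    n = len(y)
    return float(
        r * (math.log(params.alpha) + math.log(params.c)
             - math.log(params.sigma) - params.c * math.log(params.beta))
        + params.c * np.sum(z[F])
        - np.sum(t[F])
        - 2.0 * np.sum(logd[F])
        + (n - r) * math.log(params.alpha)
        - np.sum(t[C])
        - np.sum(logd[C])
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _ridge_aware_se(hess: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """Standard errors from an observed information with flat directions.

    The likelihood here depends on (c, beta, sigma, tau0) only through
    c / sigma and tau0 + sigma log(beta), so the information matrix has a
    two-dimensional null space.  A coordinate with weight on a null
    eigenvector is not estimable: its standard error is +inf, not a
    pseudo-inverse artifact.
    """
    vals, vecs = np.linalg.eigh(hess)
    scale = np.max(np.abs(vals))
    good = vals > rel_tol * scale
    var = np.sum(vecs[:, good] ** 2 / vals[good], axis=1)
    flat = np.sum(vecs[:, ~good] ** 2, axis=1) > 1e-6
    if np.any(~good):
        warnings.warn(
            "observed information has flat (non-identifiable) directions; "
            "affected standard errors reported as +inf",
            RuntimeWarning,
            stacklevel=3,
        )
    se = np.sqrt(np.maximum(var, 0.0))
    se[flat] = math.inf
    return se


def _pack(params: RegressionParams) -> np.ndarray:
    return np.concatenate([
        np.log([params.alpha, params.c, params.beta, params.sigma]),
        np.asarray(params.tau, dtype=float),
    ])


def _unpack(phi: np.ndarray, p_tau: int) -> RegressionParams:
    a, c, b, s = np.exp(phi[:4])
    return RegressionParams(alpha=a, c=c, beta=b, sigma=s,
                            tau=tuple(phi[4:4 + p_tau]))


def fit_log_weibull(y, event, V):
    """Restricted fit with alpha = c = beta = 1 (classical log-Weibull AFT).

    Returns (sigma, tau, negloglik); used both as the multi-start anchor
    and as the reduction oracle.
    """
    n, p1 = V.shape
    tau0, *_ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ tau0
    s0 = max(float(np.std(resid)), 1e-3)

    def nll(phi):
        sigma = math.exp(phi[0])
        params = RegressionParams(1.0, 1.0, 1.0, sigma, tuple(phi[1:]))
        ll = censored_loglik_norank(y, event, V, params)
        return -ll if math.isfinite(ll) else math.inf

    res = optimize.minimize(
        nll, np.concatenate([[math.log(s0)], tau0]), method="Nelder-Mead",
        options=dict(maxiter=4000, maxfev=6000, xatol=1e-9, fatol=1e-10),
    )
    res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                            options=dict(maxiter=4000, maxfev=6000,
                                         xatol=1e-9, fatol=1e-10))
    return math.exp(res.x[0]), res.x[1:], float(res.fun)


def censored_loglik_norank(y, event, V, params) -> float:
    """Array-level likelihood without the rank re-check (inner loop use)."""
    mu = V @ np.asarray(params.tau)
    F = event == 1
    total = 0.0
    if np.any(F):
        total += float(np.sum(lmoww_logpdf(y[F], mu[F], params)))
    if np.any(~F):
        total += float(np.sum(lmoww_logsf(y[~F], mu[~F], params)))
    return total


def fit_regression(data: Sequence[CensoredObservation],
                   starts: Optional[list] = None, seed: int = 0,
                   compute_se: bool = True) -> RegressionFit:
    """Multi-start ML fit of the censored location-scale model.

    The classical log-Weibull regression fit anchors the start list;
    generator-parameter variations and seeded random perturbations are
    layered on top.  Deterministic given (data, starts, seed).
    """
    y, event, V = _as_arrays(data)
    n, p1 = V.shape
    r = int(event.sum())
    if r == 0:
        raise ParameterError("no events: the censored likelihood is "
                             "uninformative about the density")
    if np.linalg.matrix_rank(V) < p1:
        raise ParameterError("design matrix is rank deficient")
    if n < p1 + 5:
        raise ParameterError(f"need at least {p1 + 5} observations, got {n}")

    def nll(phi):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                params = _unpack(phi, p1)
            except ParameterError:
                return math.inf
            ll = censored_loglik_norank(y, event, V, params)
        return -ll if math.isfinite(ll) else math.inf

    if starts is None:
        s_hat, tau_hat, _ = fit_log_weibull(y, event, V)
        starts = []
        for a0, c0, b0 in [(1.0, 1.0, 1.0), (0.1, 2.0, 1.0), (5.0, 0.7, 1.0),
                           (2.0, 1.5, 0.8), (0.02, 5.0, 2.0)]:
            starts.append(RegressionParams(a0, c0, b0, s_hat, tuple(tau_hat)))
        rng = np.random.default_rng(seed)
        for _ in range(10):
            starts.append(RegressionParams(
                float(np.exp(rng.uniform(-3, 3))),
                float(np.exp(rng.uniform(-1.5, 1.5))),
                float(np.exp(rng.uniform(-1.5, 1.5))),
                s_hat * float(np.exp(rng.uniform(-1, 1))),
                tuple(tau_hat + rng.normal(0, 0.5, size=p1)),
            ))

    best = None
    for sp in starts:
        phi0 = _pack(sp) if isinstance(sp, RegressionParams) else np.asarray(sp)
        if not math.isfinite(nll(phi0)):
            continue
        res = optimize.minimize(
            nll, phi0, method="Nelder-Mead",
            options=dict(maxiter=6000, maxfev=9000, xatol=1e-9, fatol=1e-10),
        )
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("no start converged")
    res = optimize.minimize(nll, best.x, method="Nelder-Mead",
                            options=dict(maxiter=6000, maxfev=9000,
                                         xatol=1e-9, fatol=1e-10))
    if res.fun < best.fun:
        best = res

    params = _unpack(best.x, p1)
    nll_hat = float(best.fun)
    k = params.k
    se = None
    if compute_se:
        def nll_nat(theta):
            if np.any(theta[:4] <= 0.0):
                return math.inf
            pr = RegressionParams(theta[0], theta[1], theta[2], theta[3],
                                  tuple(theta[4:]))
            ll = censored_loglik_norank(y, event, V, pr)
            return -ll if math.isfinite(ll) else math.inf

        theta_hat = np.concatenate([
            [params.alpha, params.c, params.beta, params.sigma], params.tau])
        try:
            se = _ridge_aware_se(_numerical_hessian(nll_nat, theta_hat))
        except Exception:
            se = np.full(k, math.nan)

    return RegressionFit(
        params=params, se=se, negloglik=nll_hat,
        aic=2.0 * k + 2.0 * nll_hat, bic=k * math.log(n) + 2.0 * nll_hat,
        n=n, r=r, converged=True,
    )


# ---------------------------------------------------------------------------
# Synthetic censored cohort
# ---------------------------------------------------------------------------

def simulate_censored_cohort(n: int, params: RegressionParams,
                             covariate_law=None, censoring_rate: float = 0.2,
                             seed: int = 0) -> list:
    """Generate a right-censored cohort with known truth.

    Covariates default to a single balanced binary arm indicator (two-arm
    trial layout).  Lifetimes come from the location-scale inversion at
    mu_i = v_i' tau; censoring times are exponential on the natural-time
    scale with the rate calibrated so the expected censored fraction hits
    ``censoring_rate``.  Deterministic given ``seed``.
    """
    if not 0.0 <= censoring_rate < 1.0:
        raise ParameterError("censoring_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if covariate_law is None:
        def covariate_law(size, rng):
            return rng.integers(0, 2, size=size).astype(float)[:, None]
    covs = np.atleast_2d(covariate_law(n, rng))
    V = np.column_stack([np.ones(n), covs])
    if V.shape[1] != len(params.tau):
        raise ParameterError(
            f"covariate law produced {V.shape[1] - 1} covariates but tau has "
            f"{len(params.tau) - 1} slopes"
        )
    mu = V @ np.asarray(params.tau)
    y_true = lmoww_rvs(n, mu, params, rng=rng)
    x_true = np.exp(y_true)

    if censoring_rate == 0.0:
        y_obs, event = y_true, np.ones(n, dtype=int)
    else:
        def mean_censored(log_kappa):
            return float(np.mean(-np.expm1(-math.exp(log_kappa) * x_true))) \
                - censoring_rate
        lo, hi = -40.0, 40.0
        if mean_censored(lo) > 0 or mean_censored(hi) < 0:  # pragma: no cover
            warnings.warn("target censoring rate unattainable; returning the "
                          "achievable extreme", RuntimeWarning)
            kappa = math.exp(hi if mean_censored(hi) < 0 else lo)
        else:
            kappa = math.exp(optimize.brentq(mean_censored, lo, hi))
        c_times = rng.exponential(scale=1.0 / kappa, size=n)
        event = (x_true <= c_times).astype(int)
        y_obs = np.where(event == 1, y_true, np.log(c_times))

    return [
        CensoredObservation(y=float(y_obs[i]), event=int(event[i]),
                            v=tuple(V[i]))
        for i in range(n)
    ]
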