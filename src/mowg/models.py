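"""Concrete model parameterizations and the named model registry.

The registry exposes the two headline models built from the full
tilt + Weibull composition,

* ``mow-e`` — exponential baseline, parameters (alpha, c, beta, lam),
* ``mow-w`` — Weibull baseline, parameters (alpha, c, beta, gamma, delta),

and the comparison models assembled from the same building blocks:
tilt-only (``mo-e``, ``mo-w``), Weibull-composition-only (``weibull-e``,
``weibull-w``) and exponentiated (``exp-e``, ``exp-w``) families.

Parameter ordering in every API follows the conventional table layout
(mow-e: alpha, c, beta, lam; mow-w: alpha, c, beta, gamma, delta) so that
fitted vectors line up with published comparisons column for column.

The four-parameter ``mow-e`` model is deliberately over-parameterized: its
cdf depends on (lam, beta) only through lam / beta, so the pair sits on a
likelihood ridge.  ``make_model(..., reduced=True)`` exposes the
identifiable three-parameter version (alpha, c, rate = lam / beta) for
well-conditioned inference.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence, Union

import numpy as np

from .family import (
    BaselineModel,
    GeneratorParams,
    MOWGDistribution,
    ParameterError,
    check_positive,
    _as_float_array,
    _maybe_scalar,
)

__all__ = [
    "exponential_baseline",
    "weibull_baseline",
    "MOGDistribution",
    "ExpGDistribution",
    "ModelSpec",
    "MODEL_REGISTRY",
    "get_model_spec",
    "make_model",
    "expg_cdf",
    "expg_pdf",
]


# ---------------------------------------------------------------------------
# Baselines (support (0, inf); cdf at x <= 0 is 0, pdf is 0, not an error)
# ---------------------------------------------------------------------------

def _exp_cdf(x, lam):
    return np.where(x > 0.0, -np.expm1(-lam * x), 0.0)


def _exp_pdf(x, lam):
    return np.where(x > 0.0, lam * np.exp(-lam * x), 0.0)


def _exp_logpdf(x, lam):
    return np.where(x > 0.0, math.log(lam) - lam * x, -np.inf)


def _exp_quantile(p, lam):
    return -np.log1p(-p) / lam


def _exp_cum_hazard(x, lam):
    return np.where(x > 0.0, lam * x, 0.0)


def _exp_cum_hazard_inv(h, lam):
    return h / lam


def _exp_log_hazard(x, lam):
    return np.full_like(np.asarray(x, dtype=float), math.log(lam))


def exponential_baseline(lam: float) -> BaselineModel:
    """Exponential baseline with rate ``lam``: cdf ``1 - exp(-lam x)``."""
    return BaselineModel(
        name="exponential",
        tau=(("lam", float(lam)),),
        cdf_fn=_exp_cdf,
        pdf_fn=_exp_pdf,
        quantile_fn=_exp_quantile,
        logpdf_fn=_exp_logpdf,
        cum_hazard_fn=_exp_cum_hazard,
        cum_hazard_inv_fn=_exp_cum_hazard_inv,
        log_hazard_fn=_exp_log_hazard,
    )


def _wei_cum_hazard(x, gamma, delta):
    return np.where(x > 0.0, (x / delta) ** gamma, 0.0)


def _wei_cdf(x, gamma, delta):
    return -np.expm1(-_wei_cum_hazard(x, gamma, delta))


def _wei_log_hazard(x, gamma, delta):
    # density -> +inf as x -> 0+ when gamma < 1; the limit value is returned
    with np.errstate(divide="ignore"):
        shape_term = (
            0.0 if gamma == 1.0
            else (gamma - 1.0) * (np.log(np.maximum(x, 0.0)) - math.log(delta))
        )
        return np.where(
            x > 0.0,
            math.log(gamma / delta) + shape_term,
            -np.inf,
        )


def _wei_logpdf(x, gamma, delta):
    return np.where(
        x > 0.0,
        _wei_log_hazard(x, gamma, delta) - _wei_cum_hazard(x, gamma, delta),
        -np.inf,
    )


def _wei_pdf(x, gamma, delta):
    with np.errstate(invalid="ignore"):
        return np.exp(_wei_logpdf(x, gamma, delta))


def _wei_quantile(p, gamma, delta):
    return delta * (-np.log1p(-p)) ** (1.0 / gamma)


def _wei_cum_hazard_inv(h, gamma, delta):
    return delta * h ** (1.0 / gamma)


def weibull_baseline(gamma: float, delta: float) -> BaselineModel:
    """Weibull baseline with shape ``gamma``, scale ``delta``."""
    return BaselineModel(
        name="weibull",
        tau=(("gamma", float(gamma)), ("delta", float(delta))),
        cdf_fn=_wei_cdf,
        pdf_fn=_wei_pdf,
        quantile_fn=_wei_quantile,
        logpdf_fn=_wei_logpdf,
        cum_hazard_fn=_wei_cum_hazard,
        cum_hazard_inv_fn=_wei_cum_hazard_inv,
        log_hazard_fn=_wei_log_hazard,
    )


_BASELINE_BUILDERS = {
    "exponential": exponential_baseline,
    "weibull": weibull_baseline,
}


# ---------------------------------------------------------------------------
# Tilt-only and exponentiated families
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MOGDistribution:
    """Tilt transform applied directly to a baseline: F = G / (a + (1-a)G)."""

    alpha: float
    baseline: BaselineModel

    def __post_init__(self):
        check_positive(alpha=self.alpha)

    def cdf(self, x):
        g = self.baseline.cdf(x)
        return g / (self.alpha + (1.0 - self.alpha) * g)

    def logsf(self, x):
        arr = _as_float_array(x)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        h = self.baseline.cum_hazard(np.maximum(arr, self.baseline.support[0]))
        h = np.where(arr > self.baseline.support[0], h, 0.0)
        # S = alpha (1-G) / (1 - (1-alpha)(1-G)), with 1-G = e^{-h}
        out = math.log(self.alpha) - h - np.log1p(-(1.0 - self.alpha) * np.exp(-h))
        return _maybe_scalar(out, scalar)

    def sf(self, x):
        return np.exp(self.logsf(x))

    def logpdf(self, x):
        arr = _as_float_array(x)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        lo, hi = self.baseline.support
        inside = (arr > lo) & (arr < hi)
        xs = np.where(inside, arr, lo + 1.0)
        h = self.baseline.cum_hazard(xs)
        val = (
            math.log(self.alpha)
            + self.baseline.logpdf(xs)
            - 2.0 * np.log1p(-(1.0 - self.alpha) * np.exp(-h))
        )
        return _maybe_scalar(np.where(inside, val, -np.inf), scalar)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def quantile(self, p):
        arr = _as_float_array(p)
        if np.any((arr < 0.0) | (arr >= 1.0)):
            raise ParameterError("quantile level p must lie in [0, 1)")
        g = self.alpha * arr / (1.0 - (1.0 - self.alpha) * arr)
        return self.baseline.quantile(g)

    def median(self):
        return self.quantile(0.5)

    def rvs(self, n: int, seed=None, rng=None):
        if rng is None:
            rng = np.random.default_rng(seed)
        return self.quantile(rng.uniform(size=int(n)))


@dataclasses.dataclass(frozen=True)
class ExpGDistribution:
    """Exponentiated family: F = G^c_exp, f = c_exp g G^(c_exp - 1)."""

    c_exp: float
    baseline: BaselineModel

    def __post_init__(self):
        check_positive(c_exp=self.c_exp)

    def cdf(self, x):
        return self.baseline.cdf(x) ** self.c_exp

    def logsf(self, x):
        arr = _as_float_array(x)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        g = np.clip(self.baseline.cdf(arr), 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logg = np.log(g)
            out = np.where(
                g >= 1.0, -np.inf,
                np.log(-np.expm1(np.where(g > 0, self.c_exp * logg, -np.inf))),
            )
        out = np.where(g <= 0.0, 0.0, out)
        return _maybe_scalar(out, scalar)

    def sf(self, x):
        return np.exp(self.logsf(x))

    def logpdf(self, x):
        arr = _as_float_array(x)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        lo, hi = self.baseline.support
        inside = (arr > lo) & (arr < hi)
        xs = np.where(inside, arr, lo + 1.0)
        g = np.clip(self.baseline.cdf(xs), 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            shape_term = (
                0.0 if self.c_exp == 1.0 else (self.c_exp - 1.0) * np.log(g)
            )
            val = math.log(self.c_exp) + self.baseline.logpdf(xs) + shape_term
        return _maybe_scalar(np.where(inside, val, -np.inf), scalar)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def quantile(self, p):
        arr = _as_float_array(p)
        if np.any((arr < 0.0) | (arr >= 1.0)):
            raise ParameterError("quantile level p must lie in [0, 1)")
        return self.baseline.quantile(arr ** (1.0 / self.c_exp))

    def median(self):
        return self.quantile(0.5)

    def rvs(self, n: int, seed=None, rng=None):
        if rng is None:
            rng = np.random.default_rng(seed)
        return self.quantile(rng.uniform(size=int(n)))


def expg_cdf(c_exp: float, base: BaselineModel, x):
    """Exponentiated-family cdf ``G(x)^c_exp``."""
    return ExpGDistribution(c_exp, base).cdf(x)


def expg_pdf(c_exp: float, base: BaselineModel, x):
    """Exponentiated-family density ``c_exp g(x) G(x)^(c_exp - 1)``."""
    return ExpGDistribution(c_exp, base).pdf(x)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A registered model: family transform + baseline + parameter names."""

    name: str
    family: str    # MOWG | MOG | WEIBULLG | EXPG
    baseline: str  # exponential | weibull
    param_names: tuple

    @property
    def free_parameter_count(self) -> int:
        return len(self.param_names)


MODEL_REGISTRY: dict = {
    spec.name: spec
    for spec in [
        ModelSpec("mow-e", "MOWG", "exponential", ("alpha", "c", "beta", "lam")),
        ModelSpec("mow-w", "MOWG", "weibull",
                  ("alpha", "c", "beta", "gamma", "delta")),
        ModelSpec("mo-e", "MOG", "exponential", ("alpha", "lam")),
        ModelSpec("mo-w", "MOG", "weibull", ("alpha", "c", "beta")),
        ModelSpec("weibull-e", "WEIBULLG", "exponential", ("c", "beta", "lam")),
        ModelSpec("weibull-w", "WEIBULLG", "weibull",
                  ("c", "beta", "gamma", "delta")),
        ModelSpec("exp-e", "EXPG", "exponential", ("delta", "lam")),
        ModelSpec("exp-w", "EXPG", "weibull", ("alpha", "c", "beta")),
    ]
}


def get_model_spec(model: Union[str, ModelSpec]) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODEL_REGISTRY[model]
    except KeyError:
        raise ParameterError(
            f"unknown model {model!r}; available models: "
            + ", ".join(sorted(MODEL_REGISTRY))
        ) from None


def make_model(model: Union[str, ModelSpec], params: Sequence[float],
               reduced: bool = False):
    """Instantiate a registered model from an ordered parameter vector.

    With ``reduced=True`` (``mow-e`` only) the vector is (alpha, c, rate)
    and the model is built with beta = 1, lam = rate — the identifiable
    parameterization of the (lam, beta) ridge.
    """
    spec = get_model_spec(model)
    params = [float(v) for v in params]
    if reduced:
        if spec.name != "mow-e":
            raise ParameterError("reduced parameterization exists for 'mow-e' only")
        if len(params) != 3:
            raise ParameterError(
                f"model 'mow-e' (reduced) expects 3 parameters (alpha, c, rate), "
                f"got {len(params)}"
            )
        alpha, c, rate = params
        check_positive(alpha=alpha, c=c, rate=rate)
        return MOWGDistribution(GeneratorParams(alpha, c, 1.0),
                                exponential_baseline(rate))
    if len(params) != spec.free_parameter_count:
        raise ParameterError(
            f"model {spec.name!r} expects {spec.free_parameter_count} parameters "
            f"{spec.param_names}, got {len(params)}"
        )
    check_positive(**dict(zip(spec.param_names, params)))
    named = dict(zip(spec.param_names, params))

    if spec.family == "MOWG":
        gen = GeneratorParams(named["alpha"], named["c"], named["beta"])
        if spec.baseline == "exponential":
            base = exponential_baseline(named["lam"])
        else:
            base = weibull_baseline(named["gamma"], named["delta"])
        return MOWGDistribution(gen, base)
    if spec.family == "MOG":
        if spec.baseline == "exponential":
            base = exponential_baseline(named["lam"])
        else:  # mo-w: (alpha, c, beta) = tilt + Weibull(shape c, scale beta)
            base = weibull_baseline(named["c"], named["beta"])
        return MOGDistribution(named["alpha"], base)
    if spec.family == "WEIBULLG":
        gen = GeneratorParams(1.0, named["c"], named["beta"])
        if spec.baseline == "exponential":
            base = exponential_baseline(named["lam"])
        else:
            base = weibull_baseline(named["gamma"], named["delta"])
        return MOWGDistribution(gen, base)
    if spec.family == "EXPG":
        if spec.baseline == "exponential":  # exp-e: (delta, lam), exponent delta
            return ExpGDistribution(named["delta"], exponential_baseline(named["lam"]))
        # exp-w: (alpha, c, beta) = exponent alpha + Weibull(shape c, scale beta)
        return ExpGDistribution(named["alpha"], weibull_baseline(named["c"], named["beta"]))
    raise ParameterError(f"unknown family {spec.family!r}")  # pragma: no cover
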