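"""Generator algebra for tilted Weibull-composed distribution families.

This module implements three cdf-level transformations and their
composition:

* the tilt (Marshall-Olkin) map ``G -> G / (alpha + (1 - alpha) G)``,
* the Weibull-composition map ``G -> 1 - exp(-((-log(1 - G)) / beta)^c)``,
* the full composition of both applied to an arbitrary baseline cdf,

together with density, survival, hazard, quantile and random-variate
evaluation.  All heavy lifting is done in log-space so that extreme
parameter values (large ``(-log(1 - G)/beta)^c``) do not overflow.

The quantile function implemented here is the algebraic inversion of the
composed cdf,

    Q(p) = G^{-1}[1 - exp(-beta (-log((1 - p) / (1 - (1 - alpha) p)))^{1/c})].

Note the numerator ``1 - p``: a published variant of this formula carries
``1 - alpha p`` in the numerator instead, which is not the inverse of the
cdf (it produces log of a non-positive number at, e.g., alpha = 2,
p = 0.5).  The cdf-quantile round-trip tests pin down the corrected form.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ParameterError",
    "SurvivalUnderflowWarning",
    "GeneratorParams",
    "BaselineModel",
    "MOWGDistribution",
    "mo_cdf",
    "weibullg_cdf",
    "mowg_cdf",
    "mowg_pdf",
    "mowg_logpdf",
    "mowg_sf",
    "mowg_quantile",
    "mowg_median",
    "mowg_hazard",
    "mowg_rvs",
]


class ParameterError(ValueError):
    """A distribution parameter is outside its domain."""


class SurvivalUnderflowWarning(RuntimeWarning):
    """The survival function underflowed to zero while computing a hazard."""


def check_positive(**params: float) -> None:
    """Raise :class:`ParameterError` naming the first non-positive parameter."""
    for name, value in params.items():
        if not math.isfinite(value) or value <= 0.0:
            raise ParameterError(
                f"parameter {name!r} must be a positive finite real, got {value!r}"
            )


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(np.asarray(arr).reshape(-1)[0]) if scalar else arr


@dataclasses.dataclass(frozen=True)
class GeneratorParams:
    """The (alpha, c, beta) triple shared by every composed-family member.

    ``alpha`` is the tilt parameter (alpha = 1 switches the tilt off),
    ``c`` and ``beta`` are the shape and scale of the Weibull composition
    layer.  All three must be positive.
    """

    alpha: float
    c: float
    beta: float

    def __post_init__(self) -> None:
        check_positive(alpha=self.alpha, c=self.c, beta=self.beta)

    @property
    def alpha_bar(self) -> float:
        """Derived complement ``1 - alpha`` (never stored independently)."""
        return 1.0 - self.alpha


@dataclasses.dataclass(frozen=True)
class BaselineModel:
    """A baseline distribution contract over parameters ``tau``.

    The three mandatory callables take ``(x_or_p, *tau_values)`` and must be
    vectorised over their first argument.  The optional log-scale callables
    (cumulative hazard ``-log(1 - G)``, its inverse, the log hazard
    ``log(g / (1 - G))`` and the log density) make the composed evaluations
    exact in the far tail; generic fallbacks from ``cdf``/``pdf`` are used
    when they are absent.
    """

    name: str
    tau: tuple  # ordered ((name, value), ...) pairs, values positive
    cdf_fn: Callable
    pdf_fn: Callable
    quantile_fn: Callable
    logpdf_fn: Optional[Callable] = None
    cum_hazard_fn: Optional[Callable] = None
    cum_hazard_inv_fn: Optional[Callable] = None
    log_hazard_fn: Optional[Callable] = None
    support: tuple = (0.0, math.inf)

    def __post_init__(self) -> None:
        check_positive(**dict(self.tau))

    @property
    def tau_values(self) -> tuple:
        return tuple(v for _, v in self.tau)

    # -- contract surface -------------------------------------------------
    def cdf(self, x):
        return self.cdf_fn(_as_float_array(x), *self.tau_values)

    def pdf(self, x):
        return self.pdf_fn(_as_float_array(x), *self.tau_values)

    def quantile(self, p):
        return self.quantile_fn(_as_float_array(p), *self.tau_values)

    def logpdf(self, x):
        if self.logpdf_fn is not None:
            return self.logpdf_fn(_as_float_array(x), *self.tau_values)
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(x))

    def cum_hazard(self, x):
        """``-log(1 - G(x))``, the integrated hazard of the baseline."""
        if self.cum_hazard_fn is not None:
            return self.cum_hazard_fn(_as_float_array(x), *self.tau_values)
        g = np.clip(self.cdf(x), 0.0, 1.0)
        with np.errstate(divide="ignore"):
            return -np.log1p(-g)

    def cum_hazard_inv(self, h):
        if self.cum_hazard_inv_fn is not None:
            return self.cum_hazard_inv_fn(_as_float_array(h), *self.tau_values)
        return self.quantile(-np.expm1(-_as_float_array(h)))

    def log_hazard(self, x):
        """``log g(x) - log(1 - G(x))``."""
        if self.log_hazard_fn is not None:
            return self.log_hazard_fn(_as_float_array(x), *self.tau_values)
        g = np.clip(self.cdf(x), 0.0, 1.0)
        with np.errstate(divide="ignore"):
            return self.logpdf(x) - np.log1p(-g)


@dataclasses.dataclass(frozen=True)
class MOWGDistribution:
    """The tilt-and-Weibull composition of an arbitrary baseline.

    cdf:  F(x) = (1 - e^{-t}) / (1 - (1 - alpha) e^{-t}),
    with  t = (H(x) / beta)^c  and  H = -log(1 - G)  the baseline
    cumulative hazard.
    """

    gen: GeneratorParams
    baseline: BaselineModel

    # -- internals --------------------------------------------------------
    def _t(self, x: np.ndarray) -> np.ndarray:
        lo = self.baseline.support[0]
        h = np.where(x > lo, self.baseline.cum_hazard(np.maximum(x, lo)), 0.0)
        return (h / self.gen.beta) ** self.gen.c

    # -- distribution surface ---------------------------------------------
    def cdf(self, x):
        arr = _as_float_array(x)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        t = self._t(arr)
        e = np.exp(-t)
        out = -np.expm1(-t) / (1.0 - self.gen.alpha_bar * e)
        return _maybe_scalar(np.clip(out, 0.0, 1.0), scalar)

    def logsf(self, x):
        arr = _as_float_array(x)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        t = self._t(arr)
        with np.errstate(divide="ignore"):
            out = (
                math.log(self.gen.alpha)
                - t
                - np.log1p(-self.gen.alpha_bar * np.exp(-t))
            )
        return _maybe_scalar(out, scalar)

    def sf(self, x):
        return np.exp(self.logsf(x))

    def logpdf(self, x):
        gen = self.gen
        arr = _as_float_array(x)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        lo, hi = self.baseline.support
        inside = (arr > lo) & (arr < hi)
        xs = np.where(inside, arr, lo + 1.0)  # dummy to keep math finite
        h = self.baseline.cum_hazard(xs)
        t = (h / gen.beta) ** gen.c
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ht = np.log(h) - math.log(gen.beta)
            shape_term = 0.0 if gen.c == 1.0 else (gen.c - 1.0) * log_ht
            val = (
                math.log(gen.alpha)
                + math.log(gen.c)
                - math.log(gen.beta)
                + self.baseline.log_hazard(xs)
                + shape_term
                - t
                - 2.0 * np.log1p(-gen.alpha_bar * np.exp(-t))
            )
        out = np.where(inside, val, -np.inf)
        return _maybe_scalar(out, scalar)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def hazard(self, x):
        lp = np.atleast_1d(_as_float_array(self.logpdf(x)))
        ls = np.atleast_1d(_as_float_array(self.logsf(x)))
        scalar = np.asarray(x).ndim == 0
        underflow = np.isneginf(ls) & ~np.isneginf(lp)
        if np.any(underflow):
            warnings.warn(
                "survival function underflowed to 0; hazard reported as +inf",
                SurvivalUnderflowWarning,
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            out = np.where(underflow, np.inf, np.exp(lp - ls))
        out = np.where(np.isneginf(lp) & np.isneginf(ls), np.inf, out)
        return _maybe_scalar(out, scalar)

    def quantile(self, p):
        gen = self.gen
        arr = _as_float_array(p)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        if np.any((arr < 0.0) | (arr >= 1.0)):
            raise ParameterError("quantile level p must lie in [0, 1)")
        # -log((1 - p) / (1 - (1 - alpha) p)), always >= 0 for valid alpha
        big_t = np.log1p(-gen.alpha_bar * arr) - np.log1p(-arr)
        h = gen.beta * big_t ** (1.0 / gen.c)
        out = np.where(arr == 0.0, self.baseline.support[0],
                       self.baseline.cum_hazard_inv(h))
        return _maybe_scalar(out, scalar)

    def median(self):
        return self.quantile(0.5)

    def rvs(self, n: int, seed=None, rng=None):
        """Inversion sampling: quantile applied to a seeded uniform stream."""
        if n < 1:
            raise ParameterError(f"sample size n must be >= 1, got {n}")
        if rng is None:
            rng = np.random.default_rng(seed)
        return self.quantile(rng.uniform(size=int(n)))


# ---------------------------------------------------------------------------
# Functional layer (scalar/array transforms on cdf values)
# ---------------------------------------------------------------------------

def mo_cdf(alpha: float, base_cdf_value):
    """Tilt transform of a cdf value: ``G / (alpha + (1 - alpha) G)``."""
    check_positive(alpha=alpha)
    g = _as_float_array(base_cdf_value)
    if np.any((g < 0.0) | (g > 1.0)):
        raise ParameterError("base_cdf_value must lie in [0, 1]")
    scalar = g.ndim == 0
    out = np.atleast_1d(g) / (alpha + (1.0 - alpha) * np.atleast_1d(g))
    return _maybe_scalar(out, scalar)


def weibullg_cdf(c: float, beta: float, base_cdf_value):
    """Weibull-composition transform ``1 - exp(-((-log(1 - G)) / beta)^c)``."""
    check_positive(c=c, beta=beta)
    g = _as_float_array(base_cdf_value)
    if np.any((g < 0.0) | (g > 1.0)):
        raise ParameterError("base_cdf_value must lie in [0, 1]")
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    with np.errstate(divide="ignore"):
        h = -np.log1p(-g)
    out = np.where(g >= 1.0, 1.0, -np.expm1(-((h / beta) ** c)))
    return _maybe_scalar(out, scalar)


def mowg_cdf(dist: MOWGDistribution, x):
    return dist.cdf(x)


def mowg_pdf(dist: MOWGDistribution, x):
    return dist.pdf(x)


def mowg_logpdf(dist: MOWGDistribution, x):
    return dist.logpdf(x)


def mowg_sf(dist: MOWGDistribution, x):
    return dist.sf(x)


def mowg_quantile(dist: MOWGDistribution, p):
    return dist.quantile(p)


def mowg_median(dist: MOWGDistribution):
    return dist.median()


def mowg_hazard(dist: MOWGDistribution, x):
    return dist.hazard(x)


def mowg_rvs(dist: MOWGDistribution, n: int, seed=None, rng=None):
    return dist.rvs(n, seed=seed, rng=rng)
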