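"""Mathematical properties: series expansion of the density, numerical
moments, mgf, incomplete moments, Renyi entropy and order statistics.

The density of the composed family admits an infinite linear-combination
representation in terms of exponentiated-baseline densities
``a g(x) G(x)^(a-1)`` with powers ``a = c(i+1) + m + r``.  Two regimes
exist (tilt parameter below / above one); ``alpha = 1`` needs no series at
all — the direct density applies.  The truncated series is exposed here as
a cross-check oracle for the direct density, never as the production
evaluation path.

Moments, mgf and entropies are computed quadrature-first on the
quantile-transformed integral (``int_0^1 Q(p)^r dp`` etc.), which avoids
infinite-support truncation error.
"""

from __future__ import annotations

import dataclasses
import functools
import math
import warnings
from fractions import Fraction

import numpy as np
from scipy import integrate, special

from .family import MOWGDistribution, ParameterError

__all__ = [
    "IntegralDivergedWarning",
    "ptm",
    "SeriesCoefficients",
    "series_coefficients",
    "series_pdf",
    "raw_moment",
    "incomplete_moment",
    "mgf",
    "renyi_entropy",
    "shannon_entropy",
    "order_stat_pdf",
]


class IntegralDivergedWarning(RuntimeWarning):
    """A numerical integral failed to converge (moment/mgf may not exist)."""


# ---------------------------------------------------------------------------
# The P_{t,m} recursion
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _ptm_fraction(t: int, m: int) -> Fraction:
    if m == 0:
        return Fraction(1)
    total = Fraction(0)
    for l in range(1, m + 1):
        total += (
            Fraction((-1) ** l)
            * Fraction(l * (t + 1) - m, l + 1)
            * _ptm_fraction(t, m - l)
        )
    return total / m


def ptm(t: int, m: int) -> float:
    """Recursion constants of the power-series expansion of ``(-log(1-x))^a``.

    ``P(t, 0) = 1``; for m >= 1,
    ``P(t, m) = m^-1 sum_{l=1}^{m} (-1)^l [l(t+1) - m] / (l+1) P(t, m-l)``.
    Evaluated in exact rational arithmetic and memoized.
    """
    if t < 0 or m < 0:
        raise ParameterError(f"ptm indices must be nonnegative, got t={t}, m={m}")
    return float(_ptm_fraction(int(t), int(m)))


# ---------------------------------------------------------------------------
# Series representation of the density
# ---------------------------------------------------------------------------

def _singular_ratio(a: float, t: int, m: int) -> float:
    """(a - 1) * binom(m - a + 1, m) / (a - 1 - t), with removable
    singularities at a - 1 = t resolved by a symmetric numerical limit."""
    def value(aa: float) -> float:
        return (aa - 1.0) * special.binom(m - aa + 1.0, m) / (aa - 1.0 - t)

    if abs(a - 1.0 - t) > 1e-6:
        v = value(a)
        if math.isfinite(v):
            return v
    h = 1e-4
    return 0.5 * (value(a + h) + value(a - h))


@dataclasses.dataclass(frozen=True)
class SeriesCoefficients:
    """Truncated mixture representation: sum of w * [a g G^(a-1)] terms.

    ``terms`` is an (n_terms, 2) array of (weight, power) pairs; ``weights``
    aggregates the weight mass per outer index j for inspection.
    """

    terms: np.ndarray
    weights: np.ndarray
    truncation_J: int
    inner_truncations: tuple  # (I, R, M)
    regime: str               # "alpha_below_one" | "alpha_above_one"


def series_coefficients(gen, truncation_J: int = 20,
                        inner_truncations=(20, 20, 20)) -> SeriesCoefficients:
    """Compute the truncated mixture weights for a generator triple.

    ``inner_truncations`` is (I, R, M) for the inner exponential-series,
    geometric and log-power sums.  In the above-one regime the tail sum
    over the auxiliary index k (which arises from swapping a binomial
    double sum) is evaluated in closed form,

        sum_{k>=j} (k+1) C(k, j) q^k = (j + 1) q^j / (1 - q)^(j+2),
        q = 1 - 1/alpha.

    Caution: that swapped rearrangement converges only where
    (alpha - 1) e^{-t} < 1 (t the composed exponent); for alpha >= 2 the
    series is divergent at small x, which is a property of the expansion
    itself, not of this implementation.
    """
    alpha, c, beta = gen.alpha, gen.c, gen.beta
    J = int(truncation_J)
    I, R, M = (int(v) for v in inner_truncations)
    if J < 0 or I < 0 or R < 0 or M < 0:
        raise ParameterError("series truncations must be nonnegative")
    if alpha == 1.0:
        raise ParameterError(
            "series representation is undefined at alpha = 1; "
            "use the direct density instead"
        )

    below = alpha < 1.0
    regime = "alpha_below_one" if below else "alpha_above_one"

    # outer(j, i): the tilt-expansion factor
    jj = np.arange(J + 1, dtype=float)[:, None]
    ii = np.arange(I + 1, dtype=float)[None, :]
    inv_fact = 1.0 / special.factorial(np.arange(I + 1))[None, :]
    if below:
        outer = ((-1.0) ** ii * alpha * (1.0 - alpha) ** jj
                 * (jj + 1.0) ** (ii + 1.0) * inv_fact)
    else:
        q = 1.0 - 1.0 / alpha
        tail = (jj + 1.0) * q ** jj / (1.0 - q) ** (jj + 2.0)
        outer = ((-1.0) ** (ii + jj) * inv_fact * (jj + 1.0) ** ii
                 * tail / alpha)

    # terms with equal mixture power a + m + r share one coefficient:
    # collapse the (m, r) double sum over s = m + r by convolving the
    # per-m log-power kernel with the geometric (r) indicator.
    n_s = M + R + 1
    term_w = np.zeros((I + 1, n_s))
    powers = np.zeros((I + 1, n_s))
    outer_i = outer.sum(axis=0)
    weights_per_j = np.zeros(J + 1)
    for i in range(I + 1):
        a = c * (i + 1)
        mt = np.zeros(M + 1)
        for m in range(M + 1):
            acc = 0.0
            for t in range(m + 1):
                sfac = _singular_ratio(a, t, m)
                if sfac != 0.0:
                    acc += ((-1.0) ** (t + m) * special.binom(m, t)
                            * ptm(t, m) * sfac)
            mt[m] = acc
        conv = np.convolve(mt, np.ones(R + 1))  # length M + R + 1
        s_idx = np.arange(n_s, dtype=float)
        wv = (c / beta ** a) * conv / (a + s_idx)
        term_w[i] = outer_i[i] * wv
        powers[i] = a + s_idx
        weights_per_j += outer[:, i] * wv.sum()
    terms = np.column_stack([term_w.ravel(), powers.ravel()])
    return SeriesCoefficients(
        terms=terms,
        weights=weights_per_j,
        truncation_J=J,
        inner_truncations=(I, R, M),
        regime=regime,
    )


def series_pdf(dist: MOWGDistribution, x, coeffs: SeriesCoefficients = None):
    """Evaluate the truncated mixture density at ``x``.

    Converges to ``dist.pdf(x)`` as all truncations grow; a cross-check
    oracle, not a production evaluator.
    """
    if coeffs is None:
        coeffs = series_coefficients(dist.gen)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    g = np.clip(dist.baseline.cdf(xs), 0.0, 1.0)
    dens = dist.baseline.pdf(xs)
    w = coeffs.terms[:, 0][:, None]
    a = coeffs.terms[:, 1][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        powered = np.where(g[None, :] > 0.0, g[None, :] ** (a - 1.0), 0.0)
    out = np.sum(w * a * powered, axis=0) * dens
    return float(out[0]) if np.asarray(x).ndim == 0 else out


# ---------------------------------------------------------------------------
# Quadrature-based moments, mgf and entropies
# ---------------------------------------------------------------------------

_QUAD_KW = dict(limit=200)


def _quad(fn, lo, hi, warn_label):
    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            value, err = integrate.quad(fn, lo, hi, **_QUAD_KW)
        except integrate.IntegrationWarning as exc:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", integrate.IntegrationWarning)
                value, err = integrate.quad(fn, lo, hi, **_QUAD_KW)
            warnings.warn(
                f"{warn_label}: quadrature did not converge cleanly ({exc}); "
                f"value {value!r} with error estimate {err!r}",
                IntegralDivergedWarning,
                stacklevel=3,
            )
    return value


def raw_moment(dist: MOWGDistribution, r_ord: int) -> float:
    """r-th raw moment by adaptive quadrature of ``int_0^1 Q(p)^r dp``."""
    if r_ord < 0:
        raise ParameterError("moment order must be nonnegative")
    if r_ord == 0:
        return 1.0
    return _quad(lambda p: dist.quantile(p) ** r_ord, 0.0, 1.0,
                 f"raw_moment(r={r_ord})")


def incomplete_moment(dist: MOWGDistribution, s_ord: int, z_upper: float) -> float:
    """``int_lo^z x^s f(x) dx`` via the quantile transform."""
    if s_ord < 0:
        raise ParameterError("moment order must be nonnegative")
    if z_upper <= dist.baseline.support[0]:
        return 0.0
    p_hi = float(dist.cdf(z_upper))
    return _quad(lambda p: dist.quantile(p) ** s_ord, 0.0, p_hi,
                 f"incomplete_moment(s={s_ord}, z={z_upper})")


def mgf(dist: MOWGDistribution, t_arg: float) -> float:
    """Moment generating function ``E[exp(tX)]``.

    Divergence beyond the exponential-tail abscissa is detected by probing
    ``t Q(p) + log(1 - p)`` near p = 1; a diverged mgf returns +inf with an
    :class:`IntegralDivergedWarning` rather than crashing.
    """
    if t_arg == 0.0:
        return 1.0
    if t_arg > 0.0:
        ks = np.arange(6, 15)
        p = 1.0 - 10.0 ** (-ks.astype(float))
        v = t_arg * dist.quantile(p) + np.log1p(-p)
        if v[-1] >= v[-3] - 1e-9:  # integrand not decaying like o(1/(1-p))
            warnings.warn(
                f"mgf diverges at t={t_arg} (beyond abscissa of convergence)",
                IntegralDivergedWarning,
                stacklevel=2,
            )
            return math.inf
    return _quad(lambda p: math.exp(t_arg * dist.quantile(p)), 0.0, 1.0,
                 f"mgf(t={t_arg})")


def renyi_entropy(dist: MOWGDistribution, R_ord: float) -> float:
    """Renyi entropy ``(1 - R)^-1 log int f(x)^R dx`` by quadrature."""
    if R_ord <= 0.0:
        raise ParameterError("Renyi order must be positive")
    if R_ord == 1.0:
        raise ParameterError(
            "Renyi order 1 is the Shannon limit; use shannon_entropy()"
        )
    integral = _quad(
        lambda p: math.exp((R_ord - 1.0) * dist.logpdf(dist.quantile(p))),
        0.0, 1.0, f"renyi_entropy(R={R_ord})",
    )
    return math.log(integral) / (1.0 - R_ord)


def shannon_entropy(dist: MOWGDistribution) -> float:
    """Shannon entropy ``-int f log f`` (the R -> 1 limit)."""
    return _quad(lambda p: -dist.logpdf(dist.quantile(p)), 0.0, 1.0,
                 "shannon_entropy")


def order_stat_pdf(dist: MOWGDistribution, q_idx: int, n_total: int, x):
    """Density of the q-th of n order statistics, computed in log-space."""
    if not (1 <= q_idx <= n_total):
        raise ParameterError(
            f"order statistic index must satisfy 1 <= q <= n, "
            f"got q={q_idx}, n={n_total}"
        )
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    logcoef = (
        special.gammaln(n_total + 1)
        - special.gammaln(q_idx)
        - special.gammaln(n_total - q_idx + 1)
    )
    lp = dist.logpdf(xs)
    with np.errstate(divide="ignore"):
        logF = np.log(np.clip(dist.cdf(xs), 0.0, 1.0))
    logS = dist.logsf(xs)
    total = logcoef + lp
    if q_idx > 1:
        total = total + (q_idx - 1) * logF
    if n_total - q_idx > 0:
        total = total + (n_total - q_idx) * logS
    out = np.where(np.isneginf(lp), 0.0, np.exp(total))
    return float(out[0]) if np.asarray(x).ndim == 0 else out
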