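"""Latent marginal distributions, represented through their quantile functions.

Partial-identification bounds for a latent correlation need only three
things from each latent marginal distribution F: its (generalized) quantile
function F^{-1}, its mean, and its standard deviation.  A :class:`Marginal`
bundles exactly those, with closed forms for the built-in families and
numerical quadrature for user-supplied quantile functions.

Quantile functions of unbounded families (normal, Laplace) diverge at 0 and
1; every integral over (0,1) in this package therefore uses quadrature
nodes strictly inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "Marginal",
    "MarginalError",
    "make_marginal",
    "moments",
    "parse_marginal",
    "numeric_moments",
]


class MarginalError(ValueError):
    """Invalid marginal family, parameters, or quantile function."""


@dataclass(frozen=True)
class Marginal:
    """A univariate latent distribution seen through its quantile function.

    Attributes
    ----------
    family : str
        Family name ("normal", "uniform", "laplace", "beta", "custom").
    params : tuple of float
        Family parameters (empty for "custom").
    quantile : callable
        Vectorized generalized inverse F^{-1} on (0,1); may return
        +/-inf at the endpoints for unbounded families.
    cdf : callable
        Vectorized distribution function F; for "custom" marginals this is
        a numerical inversion of the quantile function.
    mean : float
        mu_F, the mean of F.
    sd : float
        sd(F), finite and strictly positive.
    """

    family: str
    params: tuple
    quantile: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    cdf: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd) or self.sd <= 0:
            raise MarginalError(
                f"marginal must have finite mean and strictly positive finite "
                f"sd, got mean={self.mean}, sd={self.sd}"
            )


def numeric_moments(
    quantile: Callable[[np.ndarray], np.ndarray], tol: float = 1e-8
) -> tuple[float, float]:
    """Mean and sd of the distribution with the given quantile function.

    Uses adaptive quadrature of F^{-1} and (F^{-1})^2 over (0,1).  The
    integrands may be singular (but integrable) at the endpoints; the
    adaptive rule never evaluates at 0 or 1 exactly.
    """
    q = lambda u: float(quantile(np.asarray(u)))
    mean, _ = integrate.quad(q, 0.0, 1.0, epsabs=tol, epsrel=tol, limit=200)
    m2, _ = integrate.quad(
        lambda u: q(u) ** 2, 0.0, 1.0, epsabs=tol, epsrel=tol, limit=200
    )
    var = m2 - mean**2
    if not np.isfinite(var) or var <= 0:
        raise MarginalError(f"quantile function has non-finite or zero variance ({var})")
    return mean, float(np.sqrt(var))


def _check_monotone(quantile, n_probe: int = 513) -> None:
    grid = np.linspace(1e-6, 1 - 1e-6, n_probe)
    vals = np.asarray(quantile(grid), dtype=float)
    if np.any(np.diff(vals) < -1e-12):
        raise MarginalError("custom quantile function is decreasing on the probe grid")


def _invert_quantile(quantile) -> Callable[[np.ndarray], np.ndarray]:
    """CDF of a custom marginal via monotone bisection of its quantile."""

    def cdf(x):
        x = np.asarray(x, dtype=float)
        lo = np.full(x.shape, 1e-14)
        hi = np.full(x.shape, 1 - 1e-14)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            below = np.asarray(quantile(mid)) <= x
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)

    return cdf


def make_marginal(
    family: str,
    params: Sequence[float] = (),
    *,
    quantile: Optional[Callable] = None,
    mean: Optional[float] = None,
    sd: Optional[float] = None,
) -> Marginal:
    """Construct a :class:`Marginal`.

    Built-in families and their parameters:

    ==========  =====================  =========================
    family      params                 default
    ==========  =====================  =========================
    normal      (mu, sigma)            (0, 1)
    uniform     (a, b)                 (0, 1)
    laplace     (mu, b)                (0, 1)
    beta        (alpha, beta)          required
    custom      ()                     quantile= keyword required
    ==========  =====================  =========================

    For ``custom``, supply a vectorized nondecreasing ``quantile`` and
    optionally ``mean``/``sd``; absent moments are computed by adaptive
    quadrature (tolerance 1e-8).
    """
    family = family.lower()
    params = tuple(float(p) for p in params)

    if family == "custom":
        if quantile is None:
            raise MarginalError("custom marginal requires a quantile function")
        _check_monotone(quantile)
        if mean is None or sd is None:
            nmean, nsd = numeric_moments(quantile)
            mean = nmean if mean is None else mean
            sd = nsd if sd is None else sd
        return Marginal("custom", (), quantile, _invert_quantile(quantile), mean, sd)

    if quantile is not None:
        raise MarginalError("quantile= is only valid with family='custom'")

    if family == "normal":
        mu, sigma = params if params else (0.0, 1.0)
        if sigma <= 0:
            raise MarginalError(f"normal scale must be positive, got {sigma}")
        d = stats.norm(mu, sigma)
        return Marginal("normal", (mu, sigma), d.ppf, d.cdf, mu, sigma)
    if family == "uniform":
        a, b = params if params else (0.0, 1.0)
        if b <= a:
            raise MarginalError(f"uniform requires a < b, got ({a}, {b})")
        d = stats.uniform(a, b - a)
        return Marginal(
            "uniform", (a, b), d.ppf, d.cdf, (a + b) / 2, (b - a) / np.sqrt(12.0)
        )
    if family == "laplace":
        mu, b = params if params else (0.0, 1.0)
        if b <= 0:
            raise MarginalError(f"laplace scale must be positive, got {b}")
        d = stats.laplace(mu, b)
        return Marginal("laplace", (mu, b), d.ppf, d.cdf, mu, b * np.sqrt(2.0))
    if family == "beta":
        if len(params) != 2:
            raise MarginalError("beta marginal requires (alpha, beta)")
        a, b = params
        if a <= 0 or b <= 0:
            raise MarginalError(f"beta parameters must be positive, got ({a}, {b})")
        d = stats.beta(a, b)
        m = a / (a + b)
        s = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        return Marginal("beta", (a, b), d.ppf, d.cdf, m, float(s))

    raise MarginalError(
        f"unknown marginal family {family!r}; expected one of "
        "normal, uniform, laplace, beta, custom"
    )


def moments(m: Marginal) -> tuple[float, float]:
    """Return (mean, sd) of a marginal."""
    return m.mean, m.sd


def parse_marginal(spec: str) -> Marginal:
    """Parse a marginal specification string.

    Accepted forms: ``"normal"``, ``"normal:mu,sigma"``, ``"uniform:a,b"``,
    ``"laplace:mu,b"``, ``"beta:alpha,beta"``.
    """
    name, _, rest = spec.partition(":")
    try:
        params = tuple(float(t) for t in rest.split(",")) if rest else ()
    except ValueError as exc:
        raise MarginalError(f"cannot parse marginal parameters in {spec!r}") from exc
    return make_marginal(name.strip(), params)
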