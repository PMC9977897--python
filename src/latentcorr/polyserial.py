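"""Identification interval for the polyserial-type latent correlation.

Here X is ordinal with I categories while the second latent coordinate Z2
is observed directly, so V = F2(Z2) is an observable uniform variable.
The observable object is the family of curves

    Pi*_iv = P(X <= i, V <= v) = C(c_i, v),   c_i = P(X <= i),

for the I-1 interior cut levels c_i.  Every copula compatible with those
curves is squeezed between two explicit bound copulas,

    M(u,v) = min(u, v, min_i [Pi*_iv + (u - c_i)^+]),
    W(u,v) = max(0, u + v - 1, max_i [Pi*_iv - (c_i - u)^+]),

and the identification set for the latent correlation is the interval
[rho(W; F1, F2), rho(M; F1, F2)], where rho(C; F1, F2) is evaluated through
Hoeffding's covariance formula

    rho(C; F1, F2) = (sd F1 sd F2)^{-1} iint [C(u,v) - uv] dF1^{-1}(u) dF2^{-1}(v),

computed here in x-space as iint [C(F1(x), F2(y)) - F1(x) F2(y)] dx dy with
the unbounded tails truncated at extreme quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .marginals import Marginal
from .ordinal import CorrelationInterval
from .tables import CopulaSpec, TableError

__all__ = [
    "PolyserialProblem",
    "QuadratureError",
    "problem_from_copula",
    "problem_from_sample",
    "bound_copulas",
    "hoeffding_correlation",
    "interval",
]


class QuadratureError(RuntimeError):
    """Double integral failed to reach the requested tolerance."""


@dataclass(frozen=True)
class PolyserialProblem:
    """Observable data of the one-ordinal-coordinate problem.

    ``cuts`` holds the interior marginal levels c_1 < ... < c_{I-1} in
    (0,1); ``curve(i, v)`` evaluates Pi*_iv for cut index i (0-based) at
    probabilities v.  Each curve is nondecreasing with curve(i, 0) = 0 and
    curve(i, 1) = c_i, lies between the pointwise Frechet bounds
    max(0, c_i + v - 1) and min(c_i, v), and curves are nondecreasing in i.
    """

    cuts: np.ndarray
    curve: Callable[[int, np.ndarray], np.ndarray] = field(repr=False)

    def validate(self, n_probe: int = 101, tol: float = 1e-9) -> None:
        v = np.linspace(0, 1, n_probe)
        prev = np.zeros_like(v)
        for i, c in enumerate(self.cuts):
            cv = np.asarray(self.curve(i, v), dtype=float)
            if np.any(np.diff(cv) < -tol):
                raise TableError(f"curve {i} is decreasing")
            if abs(cv[0]) > tol or abs(cv[-1] - c) > tol:
                raise TableError(f"curve {i} endpoints are not (0, c_i)")
            if np.any(cv > np.minimum(c, v) + tol) or np.any(
                cv < np.maximum(0.0, c + v - 1) - tol
            ):
                raise TableError(f"curve {i} violates the Frechet bounds")
            if np.any(cv < prev - tol):
                raise TableError("curves are not nondecreasing in i")
            prev = cv


def _check_cuts(cuts: np.ndarray) -> np.ndarray:
    cuts = np.asarray(cuts, dtype=float)
    if cuts.size and (
        np.any(np.diff(cuts) <= 0) or cuts[0] <= 0 or cuts[-1] >= 1
    ):
        raise TableError("cuts must be strictly increasing within (0, 1)")
    return cuts


def problem_from_copula(
    C: CopulaSpec | Callable, cuts: np.ndarray
) -> PolyserialProblem:
    """Population problem with curves Pi*_iv = C(c_i, v)."""
    ev = C.evaluate if isinstance(C, CopulaSpec) else C
    cuts = _check_cuts(cuts)

    def curve(i: int, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return ev(np.full_like(v, cuts[i]), v)

    return PolyserialProblem(cuts, curve)


def problem_from_sample(x: np.ndarray, z: np.ndarray) -> PolyserialProblem:
    """Empirical problem from paired observations (x ordinal, z continuous).

    z is reduced to mid-rank pseudo-observations V = (rank - 0.5)/n; the
    cuts are the empirical marginal CDF levels of x and the curves are the
    empirical joint step functions.  Invariants hold up to the 1/n step
    granularity.
    """
    x = np.asarray(x)
    z = np.asarray(z, dtype=float)
    if x.ndim != 1 or x.shape != z.shape or len(x) < 2:
        raise TableError("x and z must be equal-length 1-D arrays with n >= 2")
    if np.all(z == z[0]):
        raise TableError("z is constant; ranks are uninformative")
    n = len(x)
    V = (stats.rankdata(z, method="average") - 0.5) / n
    levels = np.unique(x)
    cum = np.array([(x <= lv).mean() for lv in levels[:-1]])
    cuts = _check_cuts(np.unique(cum[(cum > 0) & (cum < 1)]))
    sorted_v = [np.sort(V[x <= lv]) for lv, c in zip(levels[:-1], cum) if 0 < c < 1]

    def curve(i: int, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return np.searchsorted(sorted_v[i], v, side="right") / n

    return PolyserialProblem(cuts, curve)


def bound_copulas(P: PolyserialProblem) -> tuple[Callable, Callable]:
    """The extremal copulas (M, W) compatible with the problem.

    With no cuts these reduce to the Frechet-Hoeffding bounds min(u, v)
    and max(u + v - 1, 0).
    """

    def M(u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        out = np.minimum(u, v)
        for i, c in enumerate(P.cuts):
            out = np.minimum(out, P.curve(i, v) + np.maximum(u - c, 0.0))
        return out

    def W(u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        out = np.maximum(u + v - 1.0, 0.0)
        for i, c in enumerate(P.cuts):
            out = np.maximum(out, P.curve(i, v) - np.maximum(c - u, 0.0))
        return out

    return M, W


def hoeffding_correlation(
    C: CopulaSpec | Callable,
    F1: Marginal,
    F2: Marginal,
    *,
    tol: float = 1e-4,
    eps: float = 1e-7,
    panels: int = 8,
    order: int = 12,
    max_doublings: int = 5,
    return_info: bool = False,
) -> float | tuple[float, dict]:
    """Pearson correlation of the distribution C(F1(x), F2(y)) via
    Hoeffding's covariance formula.

    The double integral of C(F1(x), F2(y)) - F1(x) F2(y) is evaluated on
    [F1^{-1}(eps), F1^{-1}(1-eps)] x [F2^{-1}(eps), F2^{-1}(1-eps)] with a
    tensorized panel Gauss-Legendre rule, doubling the panel count until
    two successive estimates differ by less than ``tol``.  The neglected
    tail is bounded by |C - uv| <= min(u, 1-u, v, 1-v) <= eps.  The result
    is clamped to [-1, 1].

    Raises
    ------
    QuadratureError
        If successive estimates still differ by more than ``tol`` at the
        maximum panel count.
    """
    ev = C.evaluate if isinstance(C, CopulaSpec) else C
    lo1, hi1 = F1.quantile(eps), F1.quantile(1 - eps)
    lo2, hi2 = F2.quantile(eps), F2.quantile(1 - eps)
    xg, wg = np.polynomial.legendre.leggauss(order)
    prev = None
    val = np.nan
    for d in range(max_doublings + 1):
        P = panels * 2**d

        def _nodes(lo, hi):
            edges = np.linspace(lo, hi, P + 1)
            a, b = edges[:-1, None], edges[1:, None]
            return (0.5 * (a + b) + 0.5 * (b - a) * xg).ravel(), (
                0.5 * (b - a) * wg
            ).ravel()

        x1, w1 = _nodes(lo1, hi1)
        x2, w2 = _nodes(lo2, hi2)
        u = np.asarray(F1.cdf(x1), dtype=float)
        v = np.asarray(F2.cdf(x2), dtype=float)
        total = 0.0
        chunk = max(1, int(2_000_000 // len(v)))
        for s in range(0, len(u), chunk):
            U, V = np.meshgrid(u[s : s + chunk], v, indexing="ij")
            total += float(
                np.sum((w1[s : s + chunk, None] * w2[None, :]) * (ev(U, V) - U * V))
            )
        val = total / (F1.sd * F2.sd)
        if prev is not None and abs(val - prev) < tol:
            out = float(np.clip(val, -1.0, 1.0))
            if return_info:
                return out, {
                    "panels": P,
                    "nodes_per_axis": P * order,
                    "last_delta": abs(val - prev),
                }
            return out
        prev = val
    raise QuadratureError(
        f"Hoeffding integral did not converge to tol={tol}: last two estimates "
        f"{prev:.6g} (at {P // 2} panels) and {val:.6g} (at {P} panels)"
    )


def interval(
    P: PolyserialProblem,
    F1: Marginal,
    F2: Marginal,
    *,
    tol: float = 1e-4,
    **quad_opts,
) -> CorrelationInterval:
    """Identification interval [rho(W; F1, F2), rho(M; F1, F2)]."""
    M, W = bound_copulas(P)
    upper = hoeffding_correlation(M, F1, F2, tol=tol, **quad_opts)
    lower = hoeffding_correlation(W, F1, F2, tol=tol, **quad_opts)
    if lower > upper:  # can only happen within quadrature tolerance
        lower, upper = upper, lower
    return CorrelationInterval(
        lower=lower, upper=upper, quad_error=tol, n_segments=len(P.cuts)
    )
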