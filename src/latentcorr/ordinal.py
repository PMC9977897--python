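"""Sharp identification interval for the latent correlation of an ordinal pair.

Given the cumulative probability matrix Pi of (X, Y) and known latent
marginals F1, F2, the set of latent correlations compatible with Pi is a
closed interval [rho_L, rho_U].  The endpoints are attained by the extremal
(Carley-type) extensions of the observed subcopula, whose mass lies on IJ
line segments of slope +1 (upper bound) or -1 (lower bound) in the copula
square.  The segments are read off four auxiliary matrices alpha, beta,
gamma, delta built from Pi:

    alpha_ij = Pi_{(i-1)J} + Pi_{i(j-1)} - Pi_{(i-1)(j-1)}
    beta_ij  = Pi_{I(j-1)} + Pi_{(i-1)j} - Pi_{(i-1)(j-1)}
    gamma_ij = Pi_{iJ} - (Pi_{i(J-j+1)} - Pi_{(i-1)(J-j+1)})
    delta_ij = Pi_{I(J-j+1)} - (Pi_{i(J-j+1)} - Pi_{i(J-j)})

with the boundary convention Pi_{0j} = Pi_{i0} = 0.  Row-major flattening
of alpha (resp. gamma), appended with 1, gives the nondecreasing u-grid of
the upper (resp. lower) segment system; beta and delta give the segments'
v-offsets.  The endpoint correlations are then segment-wise integrals of
F1^{-1}(u) F2^{-1}(v(u)), standardized by the marginal moments.

Quadrature is fixed-order Gauss-Legendre per segment, vectorized across
segments, with geometric refinement of the segments that touch u in {0,1}
or v in {0,1}, where unbounded quantile functions have integrable
singularities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .marginals import Marginal
from .tables import CumulativeProbMatrix, TableError, collapse, pmf_of

__all__ = [
    "AuxMatrices",
    "SegmentSystem",
    "CorrelationInterval",
    "aux_matrices",
    "support_vectors",
    "interval",
]

_UCLIP = (1e-16, 1.0 - 1e-16)


@dataclass(frozen=True)
class AuxMatrices:
    """The four I x J probability matrices behind the extremal couplings."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray


@dataclass(frozen=True)
class SegmentSystem:
    """Support of the extremal couplings as slope +/-1 mass segments.

    Segment k of the upper system carries the graph
    {(u, vU_k - uU_k + u) : u in [uU_k, uU_{k+1}]}; segment k of the lower
    system carries {(u, vL_k + uL_{k+1} - u) : u in [uL_k, uL_{k+1}]}.
    The u-projections of each system partition [0,1], as do the
    v-projections.
    """

    uU: np.ndarray
    vU: np.ndarray
    uL: np.ndarray
    vL: np.ndarray

    def cell_masses(self, xcdf: np.ndarray, ycdf: np.ndarray, system: str) -> np.ndarray:
        """Mass each segment system places in the rectangles of the Pi-grid.

        Both extremal couplings are compatible with Pi, so this must
        reproduce the cell masses p_ij; used as a structural invariant.
        """
        if system == "upper":
            u0, u1, voff, sgn = self.uU[:-1], self.uU[1:], self.vU - self.uU[:-1], +1
        elif system == "lower":
            u0, u1, voff, sgn = self.uL[:-1], self.uL[1:], self.vL + self.uL[1:], -1
        else:
            raise ValueError("system must be 'upper' or 'lower'")
        xg = np.concatenate(([0.0], xcdf))
        yg = np.concatenate(([0.0], ycdf))
        out = np.zeros((len(xcdf), len(ycdf)))
        for a, b, c in zip(u0, u1, voff):
            if b - a <= 0:
                continue
            for i in range(len(xcdf)):
                lo, hi = max(a, xg[i]), min(b, xg[i + 1])
                if hi <= lo:
                    continue
                for j in range(len(ycdf)):
                    # u-interval where v(u) = c + sgn*u falls in the j-th band
                    if sgn > 0:
                        vlo, vhi = yg[j] - c, yg[j + 1] - c
                    else:
                        vlo, vhi = c - yg[j + 1], c - yg[j]
                    seg = min(hi, vhi) - max(lo, vlo)
                    if seg > 0:
                        out[i, j] += seg
        return out


@dataclass(frozen=True)
class CorrelationInterval:
    """Endpoints of the partial identification set for the latent correlation."""

    lower: float
    upper: float
    quad_error: float = 0.0
    n_segments: int = 0

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")

    def __contains__(self, rho: float) -> bool:
        return self.lower <= rho <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def aux_matrices(Pi: CumulativeProbMatrix, check: bool = True) -> AuxMatrices:
    """Compute the alpha/beta/gamma/delta matrices from Pi.

    Pi must have no zero-mass categories (apply :func:`latentcorr.tables.collapse`
    first).  With ``check=True`` the probability-form identities for alpha
    and beta (P(X<i) + P(X=i, Y<j), etc.) are recomputed from the cell
    masses and compared against the cumulative-form arithmetic.
    """
    I, J = Pi.I, Pi.J
    P = Pi.padded()
    alpha = P[:-1, [J] * J] + P[1:, :-1] - P[:-1, :-1]
    beta = P[[I], :-1].repeat(I, axis=0) + P[:-1, 1:] - P[:-1, :-1]
    gamma = P[1:, [J] * J] - (P[1:, J:0:-1] - P[:-1, J:0:-1])
    delta = P[[I], J:0:-1].repeat(I, axis=0) - (P[1:, J:0:-1] - P[1:, J - 1 :: -1])
    A = AuxMatrices(alpha, beta, gamma, delta)
    if check:
        p = pmf_of(Pi)
        x_lt = np.concatenate(([0.0], Pi.xcdf))[:-1]  # P(X < i)
        y_lt = np.concatenate(([0.0], Pi.ycdf))[:-1]  # P(Y < j)
        row_lt = np.concatenate((np.zeros((I, 1)), p.cumsum(axis=1)), axis=1)[:, :-1]
        col_lt = np.concatenate((np.zeros((1, J)), p.cumsum(axis=0)), axis=0)[:-1, :]
        if (
            np.max(np.abs(alpha - (x_lt[:, None] + row_lt))) > 1e-9
            or np.max(np.abs(beta - (y_lt[None, :] + col_lt))) > 1e-9
        ):
            raise TableError("probability- and cumulative-form aux matrices disagree")
        for name, m in (("alpha", alpha), ("beta", beta), ("gamma", gamma), ("delta", delta)):
            if np.any(m < -1e-9) or np.any(m > 1 + 1e-9):
                raise TableError(f"aux matrix {name} has entries outside [0, 1]")
        if np.any(np.diff(alpha.ravel()) < -1e-9) or np.any(np.diff(gamma.ravel()) < -1e-9):
            raise TableError(
                "alpha/gamma not nondecreasing in row-major order; Pi is malformed "
                "or contains zero-mass categories (collapse first)"
            )
    return A


def support_vectors(A: AuxMatrices) -> SegmentSystem:
    """Flatten the aux matrices into the segment-limit vectors.

    Row-major order (i outer, j inner) makes uU and uL nondecreasing:
    successive alpha entries within a row differ by a cell mass, and
    alpha_{i+1,1} = Pi_{iJ} >= alpha_{iJ}.
    """
    uU = np.append(A.alpha.ravel(), 1.0)
    vU = A.beta.ravel()
    uL = np.append(A.gamma.ravel(), 1.0)
    vL = A.delta.ravel()
    if np.any(np.diff(uU) < -1e-9) or np.any(np.diff(uL) < -1e-9):
        raise TableError("segment u-grids are not nondecreasing")
    return SegmentSystem(uU, vU, uL, vL)


def _gl_segments(a, b, c, sgn, qf1, qf2, nodes, weights):
    """Vectorized sum over segments of int_a^b F1^{-1}(u) F2^{-1}(c + sgn u) du."""
    mid = 0.5 * (a + b)
    half = 0.5 * (b - a)
    U = mid[:, None] + half[:, None] * nodes
    V = np.clip(c[:, None] + sgn * U, *_UCLIP)
    U = np.clip(U, *_UCLIP)
    return float(np.sum(half[:, None] * qf1(U) * qf2(V) * weights))


def _refine_endpoint(a, b, c, sgn, qf1, qf2, side, nodes, weights, tol):
    """Integrate one segment with a singular endpoint by geometric grading.

    Halves the interval toward the singular side, integrating the regular
    outer half at each step, until the remaining contribution is below tol
    or the interval underflows.  Returns (integral, error bound).
    """
    total = 0.0
    lo, hi = a, b
    rest = 0.0
    arr = lambda x: np.asarray([x], dtype=float)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if side == "left":
            total += _gl_segments(arr(mid), arr(hi), arr(c), sgn, qf1, qf2, nodes, weights)
            hi = mid
        else:
            total += _gl_segments(arr(lo), arr(mid), arr(c), sgn, qf1, qf2, nodes, weights)
            lo = mid
        rest = _gl_segments(arr(lo), arr(hi), arr(c), sgn, qf1, qf2, nodes, weights)
        if abs(rest) < tol or hi - lo < 1e-16:
            break
    return total + rest, abs(rest) + tol


def _bound_value(uk, vk, sgn, F1, F2, order, refine_tol):
    """One Theorem-1 endpoint integral (unstandardized) plus an error estimate.

    sgn=+1: isotone segments v = vk - uk + u (upper bound); sgn=-1:
    antitone segments v = vk + u_{k+1} - u (lower bound).
    """
    qf1, qf2 = F1.quantile, F2.quantile
    a, b = uk[:-1], uk[1:]
    c = vk - a if sgn > 0 else vk + b
    keep = (b - a) > 1e-15
    a, b, c = a[keep], b[keep], c[keep]
    v_at_a = c + sgn * a
    v_at_b = c + sgn * b
    edge = 1e-12
    sing_left = (a < edge) | (np.abs(v_at_a) < edge) | (np.abs(v_at_a - 1) < edge)
    sing_right = (b > 1 - edge) | (np.abs(v_at_b) < edge) | (np.abs(v_at_b - 1) < edge)
    plain = ~(sing_left | sing_right)

    x_hi, w_hi = np.polynomial.legendre.leggauss(order)
    x_lo, w_lo = np.polynomial.legendre.leggauss(max(order // 2, 4))
    total = _gl_segments(a[plain], b[plain], c[plain], sgn, qf1, qf2, x_hi, w_hi)
    err = abs(
        total - _gl_segments(a[plain], b[plain], c[plain], sgn, qf1, qf2, x_lo, w_lo)
    )
    for k in np.where(sing_left & ~sing_right)[0]:
        t, e = _refine_endpoint(a[k], b[k], c[k], sgn, qf1, qf2, "left", x_hi, w_hi, refine_tol)
        total += t
        err += e
    for k in np.where(sing_right & ~sing_left)[0]:
        t, e = _refine_endpoint(a[k], b[k], c[k], sgn, qf1, qf2, "right", x_hi, w_hi, refine_tol)
        total += t
        err += e
    for k in np.where(sing_left & sing_right)[0]:
        m = 0.5 * (a[k] + b[k])
        t1, e1 = _refine_endpoint(a[k], m, c[k], sgn, qf1, qf2, "left", x_hi, w_hi, refine_tol)
        t2, e2 = _refine_endpoint(m, b[k], c[k], sgn, qf1, qf2, "right", x_hi, w_hi, refine_tol)
        total += t1 + t2
        err += e1 + e2
    return total, err


def interval(
    Pi: CumulativeProbMatrix,
    F1: Marginal,
    F2: Marginal,
    *,
    order: int = 32,
    refine_tol: float = 1e-10,
) -> CorrelationInterval:
    """Sharp identification interval [rho_L, rho_U] for the latent correlation.

    Parameters
    ----------
    Pi : CumulativeProbMatrix
        Observable distribution of the ordinal pair.  Zero-mass categories
        are collapsed internally.
    F1, F2 : Marginal
        Known latent marginals with finite positive standard deviation.
    order : int
        Gauss-Legendre order per segment.
    refine_tol : float
        Absolute stopping tolerance for the geometric endpoint refinement.

    Returns
    -------
    CorrelationInterval
        Endpoints in [-1, 1] with a quadrature-error estimate in
        ``quad_error`` (dominant-order difference plus refinement bounds)
        and the number of mass segments in ``n_segments``.
    """
    Pi = collapse(Pi)
    seg = support_vectors(aux_matrices(Pi))
    mu = F1.mean * F2.mean
    denom = F1.sd * F2.sd
    up, e_up = _bound_value(seg.uU, seg.vU, +1, F1, F2, order, refine_tol)
    lo, e_lo = _bound_value(seg.uL, seg.vL, -1, F1, F2, order, refine_tol)
    upper = min(1.0, (up - mu) / denom)
    lower = max(-1.0, (lo - mu) / denom)
    return CorrelationInterval(
        lower=float(lower),
        upper=float(upper),
        quad_error=float(max(e_up, e_lo) / denom),
        n_segments=int(len(seg.vU)),
    )
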