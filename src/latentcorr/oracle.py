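"""Brute-force verification of the analytic bounds.

Two independent routes to the same quantities:

* :func:`lp_interval` discretizes the set of couplings compatible with a
  cumulative probability matrix into a transportation polytope (uniform
  margins at grid resolution, block sums over the Pi-rectangles equal to
  the cell masses) and optimizes the discretized correlation functional by
  linear programming.  As the grid is refined it converges to the analytic
  interval endpoints from the inside.

* :func:`grid_correlation` evaluates the Hoeffding covariance functional
  of an explicit copula by a plain midpoint Riemann sum in x-space.

Neither shares code with the segment-integration or panel-quadrature
implementations they are used to check.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .marginals import Marginal
from .ordinal import CorrelationInterval
from .tables import CopulaSpec, CumulativeProbMatrix, collapse, pmf_of

__all__ = ["lp_interval", "grid_correlation"]


def _union_grid(n: int, cdf_vals: np.ndarray) -> np.ndarray:
    """Uniform n-grid joined with the Pi cut values (rounded to dedupe)."""
    return np.union1d(
        np.round(np.linspace(0.0, 1.0, n + 1), 12),
        np.round(np.concatenate(([0.0], np.clip(cdf_vals, 0.0, 1.0))), 12),
    )


def lp_interval(
    Pi: CumulativeProbMatrix,
    F1: Marginal,
    F2: Marginal,
    n: int = 200,
) -> CorrelationInterval:
    """Interval endpoints by discretized optimal-transport linear programs.

    The coupling mass lives on an (n-ish x n-ish) grid whose lines include
    every marginal cut value of Pi, so the block-sum constraints are exact.
    Cell representative points are grid midpoints mapped through the
    quantile functions.  Solved with the HiGHS interior-point method (the
    dual system has only O(n) rows, which makes IPM fast and deterministic
    for fixed inputs).
    """
    Pi = collapse(Pi)
    if n < max(Pi.I, Pi.J):
        raise ValueError("grid resolution must be at least the category count")
    ga = _union_grid(n, Pi.xcdf)
    gb = _union_grid(n, Pi.ycdf)
    wa, wb = np.diff(ga), np.diff(gb)
    na, nb = len(wa), len(wb)
    fa = np.asarray(F1.quantile((ga[:-1] + ga[1:]) / 2), dtype=float)
    gb_mid = np.asarray(F2.quantile((gb[:-1] + gb[1:]) / 2), dtype=float)
    cost = (fa[:, None] * gb_mid[None, :]).ravel()

    # constraint rows: u-margins, v-margins, one block sum per Pi-cell
    ii = np.repeat(np.arange(na), nb)
    jj = np.tile(np.arange(nb), na)
    block_i = np.searchsorted(np.round(np.concatenate(([0.0], Pi.xcdf)), 12), ga[:-1] + 1e-12) - 1
    block_j = np.searchsorted(np.round(np.concatenate(([0.0], Pi.ycdf)), 12), gb[:-1] + 1e-12) - 1
    nv = na * nb
    rows = np.concatenate((ii, na + jj, na + nb + block_i[ii] * Pi.J + block_j[jj]))
    cols = np.concatenate((np.arange(nv),) * 3)
    A = sp.csc_matrix(
        (np.ones(3 * nv), (rows, cols)), shape=(na + nb + Pi.I * Pi.J, nv)
    )
    rhs = np.concatenate((wa, wb, pmf_of(Pi).ravel()))

    sols = {}
    for sign, name in ((-1.0, "upper"), (1.0, "lower")):
        res = linprog(sign * cost, A_eq=A, b_eq=rhs, bounds=(0, None), method="highs-ipm")
        if res.status != 0:
            raise RuntimeError(f"transport LP ({name}) failed: {res.message}")
        sols[name] = sign * res.fun
    mu = F1.mean * F2.mean
    denom = F1.sd * F2.sd
    return CorrelationInterval(
        lower=float((sols["lower"] - mu) / denom),
        upper=float((sols["upper"] - mu) / denom),
        quad_error=float(max(wa.max(), wb.max())),
        n_segments=nv,
    )


def grid_correlation(
    C: CopulaSpec,
    F1: Marginal,
    F2: Marginal,
    n: int = 500,
    eps: float = 1e-9,
) -> float:
    """Midpoint Riemann sum of the x-space Hoeffding integrand on an n x n grid.

    Agrees with the adaptive panel quadrature within O(1/n); used purely as
    a cross-check.
    """
    ev = C.evaluate if isinstance(C, CopulaSpec) else C
    x = np.linspace(F1.quantile(eps), F1.quantile(1 - eps), n + 1)
    y = np.linspace(F2.quantile(eps), F2.quantile(1 - eps), n + 1)
    dx, dy = x[1] - x[0], y[1] - y[0]
    u = np.asarray(F1.cdf((x[:-1] + x[1:]) / 2), dtype=float)
    v = np.asarray(F2.cdf((y[:-1] + y[1:]) / 2), dtype=float)
    total = 0.0
    chunk = max(1, int(2_000_000 // n))
    for s in range(0, n, chunk):
        U, V = np.meshgrid(u[s : s + chunk], v, indexing="ij")
        total += float(np.sum(ev(U, V) - U * V))
    return total * dx * dy / (F1.sd * F2.sd)
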