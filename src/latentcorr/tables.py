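"""Cumulative probability matrices and the threshold discretization model.

An ordinal pair (X, Y) with I and J categories is fully described by its
cumulative probability matrix Pi with entries Pi_{ij} = P(X <= i, Y <= j)
(1-based indices; the boundary convention Pi_{0j} = Pi_{i0} = 0 is used
throughout).  When (X, Y) arises by thresholding a continuous latent vector
Z with copula C, the observable matrix is the restriction of C to the grid
of marginal cutoffs: Pi_{ij} = C(Pi_{iJ}, Pi_{Ij}) — a subcopula.  This
module builds such matrices from probability tables, counts, or a copula
plus cutoffs, and exposes the mesh quantities that drive the convergence
of the identification sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np

__all__ = [
    "CumulativeProbMatrix",
    "CopulaSpec",
    "TableError",
    "CopulaError",
    "from_pmf",
    "pmf_of",
    "from_counts",
    "discretize",
    "equiprobable_cuts",
    "mesh",
    "collapse",
    "read_table_csv",
    "write_table_csv",
]

_ATOL = 1e-9


class TableError(ValueError):
    """Malformed contingency table or cumulative probability matrix."""


class CopulaError(ValueError):
    """Copula specification violating uniform margins or 2-increasingness."""


@dataclass(frozen=True)
class CumulativeProbMatrix:
    """I x J matrix with entries Pi_{ij} = P(X <= i, Y <= j).

    The last column holds the marginal CDF of X, the last row that of Y,
    and Pi_{IJ} = 1.  Entries are nondecreasing along rows and columns and
    the matrix is 2-increasing (all cell masses nonnegative).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise TableError("cumulative probability matrix must be 2-D and non-empty")
        object.__setattr__(self, "values", v)
        if np.any(v < -_ATOL) or np.any(v > 1 + _ATOL):
            raise TableError("entries must lie in [0, 1]")
        if abs(v[-1, -1] - 1.0) > _ATOL:
            raise TableError(f"Pi_IJ must equal 1, got {v[-1, -1]}")
        if np.any(np.diff(v, axis=0) < -_ATOL) or np.any(np.diff(v, axis=1) < -_ATOL):
            raise TableError("entries must be nondecreasing along rows and columns")
        if np.any(pmf_of_values(v) < -_ATOL):
            raise TableError("matrix is not 2-increasing (negative cell mass)")

    @property
    def I(self) -> int:  # noqa: E743 — matches the field's notation
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    @property
    def xcdf(self) -> np.ndarray:
        """Marginal CDF values of X: (Pi_{iJ})_{i=1..I}."""
        return self.values[:, -1]

    @property
    def ycdf(self) -> np.ndarray:
        """Marginal CDF values of Y: (Pi_{Ij})_{j=1..J}."""
        return self.values[-1, :]

    def padded(self) -> np.ndarray:
        """(I+1) x (J+1) array with the boundary zeros Pi_{0j} = Pi_{i0} = 0."""
        out = np.zeros((self.I + 1, self.J + 1))
        out[1:, 1:] = self.values
        return out


@dataclass(frozen=True)
class CopulaSpec:
    """A bivariate copula given by its pointwise evaluation.

    ``evaluate(u, v)`` must be vectorized, have uniform margins and be
    2-increasing.  ``sampler(n, rng)``, when present, draws n pairs from
    the copula.
    """

    evaluate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    sampler: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None
    name: str = "copula"

    def validate(self, n_probe: int = 21, tol: float = 1e-9) -> None:
        """Check uniform margins and 2-increasingness on a probe grid."""
        g = np.linspace(0, 1, n_probe)
        if (
            np.max(np.abs(self.evaluate(g, np.ones_like(g)) - g)) > tol
            or np.max(np.abs(self.evaluate(np.ones_like(g), g) - g)) > tol
            or np.max(np.abs(self.evaluate(g, np.zeros_like(g)))) > tol
            or np.max(np.abs(self.evaluate(np.zeros_like(g), g))) > tol
        ):
            raise CopulaError(f"{self.name}: margins are not uniform on probe grid")
        U, V = np.meshgrid(g, g, indexing="ij")
        c = self.evaluate(U, V)
        masses = c[1:, 1:] - c[:-1, 1:] - c[1:, :-1] + c[:-1, :-1]
        if np.any(masses < -1e-12):
            raise CopulaError(f"{self.name}: negative rectangle mass on probe grid")


def pmf_of_values(values: np.ndarray) -> np.ndarray:
    """Cell masses p_ij from a cumulative array (no validation)."""
    v = np.asarray(values, dtype=float)
    padded = np.zeros((v.shape[0] + 1, v.shape[1] + 1))
    padded[1:, 1:] = v
    return padded[1:, 1:] - padded[:-1, 1:] - padded[1:, :-1] + padded[:-1, :-1]


def from_pmf(P: np.ndarray) -> CumulativeProbMatrix:
    """Cumulative probability matrix from an I x J probability table."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.size == 0:
        raise TableError("probability table must be 2-D and non-empty")
    if np.any(P < -_ATOL):
        raise TableError("probability table has negative entries")
    total = P.sum()
    if abs(total - 1.0) > 1e-9:
        raise TableError(f"probability table must sum to 1, got {total}")
    return CumulativeProbMatrix(np.clip(P, 0, None).cumsum(axis=0).cumsum(axis=1))


def pmf_of(Pi: CumulativeProbMatrix) -> np.ndarray:
    """Cell masses p_ij = P(X = i, Y = j); inverse of :func:`from_pmf`."""
    return pmf_of_values(Pi.values)


def from_counts(N: np.ndarray) -> CumulativeProbMatrix:
    """Empirical cumulative probability matrix from a table of counts."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0) or np.any(N != np.floor(N)):
        raise TableError("count table must contain nonnegative integers")
    total = N.sum()
    if total <= 0:
        raise TableError("count table is all zeros")
    return from_pmf(N / total)


def discretize(
    C: CopulaSpec | Callable, xcuts: np.ndarray, ycuts: np.ndarray
) -> CumulativeProbMatrix:
    """Discretize a copula on marginal cutoff grids.

    With a = xcuts followed by 1 and b = ycuts followed by 1, the result
    has Pi_{ij} = C(a_i, b_j): the subcopula an observer of the ordinal
    pair can identify.
    """
    ev = C.evaluate if isinstance(C, CopulaSpec) else C
    xcuts = np.asarray(xcuts, dtype=float)
    ycuts = np.asarray(ycuts, dtype=float)
    for name, cuts in (("xcuts", xcuts), ("ycuts", ycuts)):
        if cuts.size and (
            np.any(np.diff(cuts) <= 0) or cuts[0] <= 0 or cuts[-1] >= 1
        ):
            raise TableError(f"{name} must be strictly increasing within (0, 1)")
    a = np.append(xcuts, 1.0)
    b = np.append(ycuts, 1.0)
    U, V = np.meshgrid(a, b, indexing="ij")
    try:
        return CumulativeProbMatrix(np.asarray(ev(U, V), dtype=float))
    except TableError as exc:
        raise CopulaError(f"copula violates table invariants on the cut grid: {exc}")


def equiprobable_cuts(k: int, Q: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Cutoffs Q(i/k), i = 1..k-1, for a k-category discretization.

    Q is a quantile-like map from (0,1) into (0,1) (e.g. a Beta quantile
    function); with Q the identity the categories are equiprobable.
    """
    if k < 1:
        raise TableError(f"category count must be >= 1, got {k}")
    if k == 1:
        return np.empty(0)
    cuts = np.asarray(Q(np.arange(1, k) / k), dtype=float)
    if np.any(cuts <= 0) or np.any(cuts >= 1):
        raise TableError("cut generator must map (0,1) into (0,1)")
    if np.any(np.diff(cuts) <= 0):
        raise TableError("cut generator produced non-increasing cutoffs")
    return cuts


def mesh(Pi: CumulativeProbMatrix) -> tuple[float, float]:
    """(X-mesh, Y-mesh): the largest marginal cell probabilities.

    Sequences of tables whose mesh decreases uniformly to zero have
    identification sets converging to the point rho(C; F1, F2).
    """
    x = float(np.max(np.diff(np.concatenate(([0.0], Pi.xcdf)))))
    y = float(np.max(np.diff(np.concatenate(([0.0], Pi.ycdf)))))
    return x, y


def collapse(Pi: CumulativeProbMatrix, tol: float = 1e-12) -> CumulativeProbMatrix:
    """Merge zero-mass categories (duplicate adjacent rows/columns).

    Empirical tables can contain empty categories; these contribute
    zero-length segments to the bound construction and are removed before
    computing.  The last row and column are always kept.
    """
    xinc = np.diff(np.concatenate(([0.0], Pi.xcdf))) > tol
    yinc = np.diff(np.concatenate(([0.0], Pi.ycdf))) > tol
    keep_i = np.where(xinc)[0] if xinc.any() else np.array([Pi.I - 1])
    keep_j = np.where(yinc)[0] if yinc.any() else np.array([Pi.J - 1])
    if keep_i[-1] != Pi.I - 1:
        keep_i = np.append(keep_i, Pi.I - 1)
    if keep_j[-1] != Pi.J - 1:
        keep_j = np.append(keep_j, Pi.J - 1)
    return CumulativeProbMatrix(Pi.values[np.ix_(keep_i, keep_j)])


def read_table_csv(path: str | Path, header: bool = False) -> np.ndarray:
    """Read a plain rectangular numeric CSV (no header unless told so)."""
    try:
        arr = np.loadtxt(path, delimiter=",", skiprows=1 if header else 0, ndmin=2)
    except (OSError, ValueError) as exc:
        raise TableError(f"cannot read table from {path}: {exc}") from exc
    return arr


def write_table_csv(path: str | Path, table: np.ndarray) -> None:
    np.savetxt(path, np.asarray(table), delimiter=",", fmt="%.12g")
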