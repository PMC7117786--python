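"""Linear-algebra kernel: column spaces, intersections, consistency.

Exact mode operates on object-dtype arrays of :class:`fractions.Fraction`
via rational Gauss-Jordan elimination, so rank, membership and subspace
intersection are decided without tolerances.  Float-mode inputs fall back
to SVD-based decisions with a relative singular-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._numeric import DEFAULT_TOL, float_array, is_exact, zeros_exact

__all__ = [
    "Subspace",
    "RoucheCapelliResult",
    "column_space",
    "intersect",
    "contains",
    "rouche_capelli",
    "matrix_rank",
    "nullspace",
    "solve_linear",
]


# ---------------------------------------------------------------------------
# rational Gauss-Jordan core

def _rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row-echelon form of a list-of-rows rational matrix.

    Returns the reduced rows and the pivot column indices.
    """
    if not rows:
        return rows, []
    n_cols = len(rows[0])
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pivot_row = next((i for i in range(r, len(rows)) if rows[i][c] != 0), None)
        if pivot_row is None:
            continue
        rows[r], rows[pivot_row] = rows[pivot_row], rows[r]
        inv = rows[r][c]
        rows[r] = [x / inv for x in rows[r]]
        lead = rows[r]
        for i in range(len(rows)):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], lead)]
        pivots.append(c)
        r += 1
        if r == len(rows):
            break
    return rows, pivots


def _as_rows(a: np.ndarray) -> list[list[Fraction]]:
    return [list(row) for row in a]


def _svd_tol(s: np.ndarray, tol: float) -> float:
    return tol * (s[0] if s.size else 1.0)


def matrix_rank(a: np.ndarray, tol: float = DEFAULT_TOL) -> int:
    """Rank of a matrix; exact for Fraction entries."""
    a = np.atleast_2d(a)
    if a.shape[0] == 0 or a.shape[1] == 0:
        return 0
    if is_exact(a):
        _, pivots = _rref(_as_rows(a))
        return len(pivots)
    s = np.linalg.svd(float_array(a), compute_uv=False)
    return int(np.sum(s > _svd_tol(s, tol)))


def nullspace(a: np.ndarray, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Basis (as columns) of the right null space of ``a``."""
    a = np.atleast_2d(a)
    n_cols = a.shape[1]
    if n_cols == 0:
        return (zeros_exact((0, 0)) if is_exact(a) else np.zeros((0, 0)))
    if a.shape[0] == 0:
        return _identity_like(a, n_cols)
    if is_exact(a):
        rows, pivots = _rref(_as_rows(a))
        free = [c for c in range(n_cols) if c not in pivots]
        basis = zeros_exact((n_cols, len(free)))
        for k, fcol in enumerate(free):
            basis[fcol, k] = Fraction(1)
            for r, pcol in enumerate(pivots):
                basis[pcol, k] = -rows[r][fcol]
        return basis
    u, s, vt = np.linalg.svd(float_array(a))
    rank = int(np.sum(s > _svd_tol(s, tol)))
    return vt[rank:].T.copy()


def _identity_like(a: np.ndarray, n: int) -> np.ndarray:
    if is_exact(a):
        out = zeros_exact((n, n))
        for i in range(n):
            out[i, i] = Fraction(1)
        return out
    return np.eye(n)


def solve_linear(a: np.ndarray, b: np.ndarray, tol: float = DEFAULT_TOL):
    """One solution ``x`` of ``a @ x = b``, or ``None`` if unsolvable."""
    a = np.atleast_2d(a)
    b = np.asarray(b)
    n_cols = a.shape[1]
    if is_exact(a):
        aug = np.concatenate([a, b.reshape(-1, 1)], axis=1)
        rows, pivots = _rref(_as_rows(aug))
        if n_cols in pivots:
            return None
        x = zeros_exact((n_cols,))
        for r, pcol in enumerate(pivots):
            x[pcol] = rows[r][n_cols]
        return x
    if n_cols == 0:
        return np.zeros(0) if np.allclose(float_array(b), 0, atol=tol) else None
    af, bf = float_array(a), float_array(b).astype(float)
    x, *_ = np.linalg.lstsq(af, bf, rcond=None)
    residual = np.linalg.norm(af @ x - bf)
    scale = 1.0 + np.linalg.norm(bf) + np.linalg.norm(af)
    return x if residual <= tol * scale else None


# ---------------------------------------------------------------------------
# subspaces

@dataclass
class Subspace:
    """A linear subspace of R^ambient, represented by basis columns."""

    ambient: int
    basis: np.ndarray  # (ambient, dim); empty basis = zero subspace
    tol: float = DEFAULT_TOL

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    @property
    def exact(self) -> bool:
        return is_exact(self.basis)

    def __post_init__(self) -> None:
        if self.basis.shape[0] != self.ambient:
            raise ValueError("basis rows must equal ambient dimension")
        if self.dim and matrix_rank(self.basis, self.tol) != self.dim:
            raise ValueError("basis columns are linearly dependent")


def column_space(matrix: np.ndarray, tol: float = DEFAULT_TOL) -> Subspace:
    """Span of the columns of ``matrix`` (basis: its pivot columns)."""
    matrix = np.atleast_2d(matrix)
    ambient = matrix.shape[0]
    if matrix.shape[1] == 0:
        return Subspace(ambient, _empty_basis(matrix, ambient), tol)
    if is_exact(matrix):
        _, pivots = _rref(_as_rows(matrix))
    else:
        # pivot columns via greedy rank growth (stable enough at these sizes)
        pivots = []
        for c in range(matrix.shape[1]):
            cand = pivots + [c]
            if matrix_rank(matrix[:, cand], tol) == len(cand):
                pivots.append(c)
    basis = matrix[:, pivots] if pivots else _empty_basis(matrix, ambient)
    return Subspace(ambient, basis, tol)


def _empty_basis(like: np.ndarray, ambient: int) -> np.ndarray:
    return (np.empty((ambient, 0), dtype=object) if is_exact(like)
            else np.zeros((ambient, 0)))


def intersect(a: Subspace, b: Subspace) -> Subspace:
    """Exact intersection via the stacked-nullspace method.

    Solves ``A x + B y = 0``; intersection vectors are ``A x``.
    """
    if a.ambient != b.ambient:
        raise ValueError("ambient dimension mismatch")
    tol = min(a.tol, b.tol)
    if a.dim == 0 or b.dim == 0:
        return Subspace(a.ambient, _empty_basis(a.basis, a.ambient), tol)
    stacked = np.concatenate([a.basis, b.basis], axis=1)
    ns = nullspace(stacked, tol)
    if ns.shape[1] == 0:
        return Subspace(a.ambient, _empty_basis(a.basis, a.ambient), tol)
    vectors = a.basis.dot(ns[: a.dim, :])  # .dot: object dtype safe
    return column_space(vectors, tol)


def contains(s: Subspace, v: np.ndarray, tol: float | None = None) -> bool:
    """True iff vector ``v`` lies in the subspace ``s``."""
    v = np.asarray(v)
    if v.shape[0] != s.ambient:
        raise ValueError("vector dimension mismatch")
    if s.dim == 0:
        if is_exact(v) or s.exact:
            return all(x == 0 for x in v)
        return bool(np.allclose(float_array(v), 0.0, atol=tol or s.tol))
    return solve_linear(s.basis, v, tol or s.tol) is not None


# ---------------------------------------------------------------------------
# Rouché-Capelli consistency

@dataclass
class RoucheCapelliResult:
    """Consistency report for the system ``e^T A_bar + b^T = 0``."""

    consistent: bool
    rank_coeff: int
    rank_augmented: int
    particular: np.ndarray | None  # one solution e in R^N, if consistent
    nullspace_basis: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    @property
    def solution_dim(self) -> int:
        return self.nullspace_basis.shape[1]


def rouche_capelli(coeff: np.ndarray, rhs: np.ndarray,
                   tol: float = DEFAULT_TOL) -> RoucheCapelliResult:
    """Decide solvability of ``e^T coeff + rhs^T = 0`` for ``e``.

    ``coeff`` is N x K (one row per unknown payoff, one column per
    relation); ``rhs`` has length K.  The system is consistent iff the
    rank of ``coeff`` equals the rank of the matrix augmented with the
    ``rhs`` row.  When consistent, returns one particular solution and a
    basis of the homogeneous solutions (the affine solution set).
    """
    coeff = np.atleast_2d(coeff)
    rhs = np.asarray(rhs)
    n, k = coeff.shape
    if rhs.shape[0] != k:
        raise ValueError("rhs length must equal the number of relations")
    if k == 0:
        particular = (zeros_exact((n,)) if is_exact(coeff) else np.zeros(n))
        return RoucheCapelliResult(True, 0, 0, particular, _identity_like(coeff, n))
    augmented = np.concatenate([coeff, rhs.reshape(1, -1)], axis=0)
    r_coeff = matrix_rank(coeff, tol)
    r_aug = matrix_rank(augmented, tol)
    consistent = r_coeff == r_aug
    particular = None
    ns = nullspace(coeff.T, tol)
    if consistent:
        particular = solve_linear(coeff.T, -rhs, tol)
    return RoucheCapelliResult(consistent, r_coeff, r_aug, particular, ns)
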