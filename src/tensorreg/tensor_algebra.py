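"""Low-rank 3-way tensor primitives.

A coefficient tensor B of shape ``(d1, d2, d3)`` is stored in CP
(CANDECOMP/PARAFAC) form as three factor matrices ``U1 (d1,R)``,
``U2 (d2,R)``, ``U3 (d3,R)``::

    B = sum_r  U1[:, r]  o  U2[:, r]  o  U3[:, r]

where ``o`` is the vector outer product.  B is never materialized at full
size except on explicit request; inner products against data volumes are
computed by mode-wise contraction.

Unfolding convention (the single place it is defined): ``mode_unfold(X, j)``
moves mode ``j`` to the front and reshapes in C (row-major) order, so its
columns enumerate the remaining modes in increasing mode order with the
*higher* remaining mode varying fastest.  Under this convention, for a
rank-1 tensor ``u o v o w``::

    <u o v o w, X> == u @ mode_unfold(X, 1) @ kron(v, w)
                   == v @ mode_unfold(X, 2) @ kron(u, w)
                   == w @ mode_unfold(X, 3) @ kron(u, v)

``khatri_rao`` follows the same ordering (for single vectors it is exactly
the Kronecker product).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CPTensor",
    "outer_product",
    "khatri_rao",
    "mode_unfold",
    "cp_inner_product",
    "n_voxels",
]


def _as_finite_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    return x


def outer_product(u, v, w) -> np.ndarray:
    """Rank-1 tensor ``result[a,b,c] = u[a]*v[b]*w[c]``."""
    u = _as_finite_vector(u, "u")
    v = _as_finite_vector(v, "v")
    w = _as_finite_vector(w, "w")
    return np.einsum("a,b,c->abc", u, v, w)


def khatri_rao(a, b) -> np.ndarray:
    """Column-wise Kronecker product.

    For 1-D inputs this is the plain Kronecker product (length
    ``len(a)*len(b)``, with ``b``'s index varying fastest).  For matrices of
    matching column count R, returns a ``(len(a)*len(b), R)`` matrix whose
    r-th column is ``kron(a[:, r], b[:, r])``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1 and b.ndim == 1:
        return np.kron(a, b)
    if a.ndim == 2 and b.ndim == 2:
        if a.shape[1] != b.shape[1]:
            raise ValueError(
                f"column count mismatch: {a.shape[1]} vs {b.shape[1]}"
            )
        return np.einsum("ir,jr->ijr", a, b).reshape(-1, a.shape[1])
    raise ValueError("khatri_rao expects two vectors or two matrices")


def mode_unfold(X, mode: int) -> np.ndarray:
    """Mode-``j`` matricization of a 3-way array (``mode`` in {1, 2, 3}).

    Rows are the mode-j fibers; columns enumerate the remaining modes in
    increasing order, C-style (higher remaining mode fastest).
    """
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError(f"expected a 3-way array, got ndim={X.ndim}")
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")
    return np.moveaxis(X, mode - 1, 0).reshape(X.shape[mode - 1], -1)


def n_voxels(shape) -> int:
    """Number of voxels in a volume of the given shape."""
    return int(np.prod([int(s) for s in shape]))


class CPTensor:
    """A 3-way tensor held in CP form as factor matrices.

    Parameters
    ----------
    factors : sequence of three arrays
        ``U1 (d1,R)``, ``U2 (d2,R)``, ``U3 (d3,R)``.  1-D vectors are
        accepted as rank-1 columns.
    """

    def __init__(self, factors):
        if len(factors) != 3:
            raise ValueError("CPTensor needs exactly three factor matrices")
        mats = []
        for j, f in enumerate(factors, start=1):
            f = np.asarray(f, dtype=float)
            if f.ndim == 1:
                f = f[:, None]
            if f.ndim != 2:
                raise ValueError(f"factor {j} must be 1-D or 2-D")
            if not np.all(np.isfinite(f)):
                raise ValueError(f"factor {j} contains non-finite entries")
            mats.append(f)
        ranks = {m.shape[1] for m in mats}
        if len(ranks) != 1:
            raise ValueError(f"factor matrices disagree on rank: {ranks}")
        if mats[0].shape[1] < 1:
            raise ValueError("rank must be >= 1")
        self.factors = mats

    @classmethod
    def from_vectors(cls, *rank_one_terms) -> "CPTensor":
        """Build from one ``(u, v, w)`` triple per rank-1 term."""
        cols = [[], [], []]
        for term in rank_one_terms:
            for j in range(3):
                cols[j].append(np.asarray(term[j], dtype=float))
        return cls([np.column_stack(c) for c in cols])

    @classmethod
    def zeros(cls, shape, rank: int = 1) -> "CPTensor":
        return cls([np.zeros((d, rank)) for d in shape])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(m.shape[0] for m in self.factors)

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]

    @property
    def n_free_parameters(self) -> int:
        """R*(d1+d2+d3), ignoring the CP scale indeterminacy."""
        return self.rank * sum(self.shape)

    def materialize(self) -> np.ndarray:
        """Full dense array ``sum_r U1[:,r] o U2[:,r] o U3[:,r]``."""
        U1, U2, U3 = self.factors
        return np.einsum("ar,br,cr->abc", U1, U2, U3)

    def copy(self) -> "CPTensor":
        return CPTensor([m.copy() for m in self.factors])

    def __mul__(self, c: float) -> "CPTensor":
        U1, U2, U3 = self.factors
        return CPTensor([U1 * float(c), U2, U3])

    __rmul__ = __mul__

    def surface(self, modes: tuple[int, int]) -> np.ndarray:
        """Pairwise outer-product matrix ``sum_r U_j[:,r] U_l[:,r]^T``.

        ``modes`` is a pair from {1,2,3}; e.g. ``(1, 2)`` gives the
        ``d1 x d2`` matrix beta^1 o beta^2 summed over rank.
        """
        j, l = modes
        if {j, l} - {1, 2, 3} or j == l:
            raise ValueError(f"modes must be two distinct values in 1..3, got {modes}")
        return self.factors[j - 1] @ self.factors[l - 1].T

    def __repr__(self) -> str:
        return f"CPTensor(shape={self.shape}, rank={self.rank})"


def cp_inner_product(B: CPTensor, X) -> float:
    """``<B, X> = sum_abc B[a,b,c] X[a,b,c]`` without materializing B.

    X is contracted mode-wise against each factor (largest modes first via
    einsum's path optimizer); the result is summed over rank.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != B.shape:
        raise ValueError(
            f"shape mismatch: CPTensor has shape {B.shape}, image has {X.shape}"
        )
    U1, U2, U3 = B.factors
    return float(np.einsum("abc,ar,br,cr->", X, U1, U2, U3, optimize=True))
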