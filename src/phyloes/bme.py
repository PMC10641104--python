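"""Balanced minimum evolution length function and numerical tolerance.

The balanced length of a phylogeny ``T`` under a dissimilarity matrix ``d``
is

    L(T) = sum_{ {i,j} } d_ij * 2^(1 - tau_ij)

over unordered taxon pairs, where ``tau_ij`` is the number of edges on the
path from leaf ``i`` to leaf ``j`` (Pauplin's balanced weighting; equal to
the ordered-pair sum of ``d_ij * 2^(-tau_ij)``).  The pair weights
``2^(1 - tau_ij)`` sum to 1 along every row, for every topology.

Because ``2^(1 - tau)`` underflows the interesting digits once ``tau``
exceeds ~50, comparisons between computed lengths are only certified up to

    omega = n^2 * 2^(-49) * max_ij d_ij,

a bound on the total contribution of all pairs with ``tau_ij >= 50`` (an
unrooted binary tree has at least two cherries, so fewer than ``n^2/2``
such pairs exist).  ``L~(T1) + omega < L~(T2)`` certifies ``L(T1) < L(T2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .errors import InvalidMatrixError, LeafSetMismatchError
from .tree_core import Phylogeny, path_length_matrix

#: relative tolerance for symmetry of input matrices
SYMMETRY_RTOL = 1e-9
#: absolute tolerance for the diagonal of input matrices
DIAGONAL_ATOL = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative taxon-taxon dissimilarities with names.

    ``values[i, j]`` is the dissimilarity between taxa ``i+1`` and ``j+1``
    (internal indices are 1-based; array rows are 0-based).
    """

    values: np.ndarray
    names: Tuple[str, ...]

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InvalidMatrixError(f"matrix must be square, got {d.shape}")
        n = d.shape[0]
        if n < 3:
            raise InvalidMatrixError(f"need at least 3 taxa, got {n}")
        names = tuple(str(x) for x in self.names)
        if len(names) != n:
            raise InvalidMatrixError(
                f"{len(names)} names for {n} taxa")
        if len(set(names)) != n or any(not s.strip() for s in names):
            raise InvalidMatrixError("taxon names must be unique and non-empty")
        if np.any(d < 0):
            raise InvalidMatrixError("negative dissimilarity")
        if np.any(np.abs(np.diag(d)) > DIAGONAL_ATOL):
            raise InvalidMatrixError("nonzero diagonal")
        asym = np.abs(d - d.T)
        tol = SYMMETRY_RTOL * np.maximum(1.0, np.abs(d))
        if np.any(asym > tol):
            i, j = np.unravel_index(np.argmax(asym - tol), d.shape)
            raise InvalidMatrixError(
                f"asymmetric entries d[{i + 1},{j + 1}]={d[i, j]:g} vs "
                f"d[{j + 1},{i + 1}]={d[j, i]:g}")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d.flags.writeable = False
        object.__setattr__(self, "values", d)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_array(cls, values, names: Optional[Sequence[str]] = None
                   ) -> "DistanceMatrix":
        values = np.asarray(values, dtype=float)
        if names is None:
            names = tuple(f"t{i}" for i in range(1, values.shape[0] + 1))
        return cls(values, tuple(names))


def as_array(d: Union[DistanceMatrix, np.ndarray]) -> np.ndarray:
    """Accept either a DistanceMatrix or a bare symmetric array."""
    if isinstance(d, DistanceMatrix):
        return d.values
    return np.asarray(d, dtype=float)


def pauplin_weights(tree: Phylogeny) -> np.ndarray:
    """Balanced pair weights ``w_ij = 2^(1 - tau_ij)``, zero on the diagonal.

    Every row sums to exactly 1 for any unrooted binary topology.
    """
    tau = path_length_matrix(tree)
    w = np.exp2(1.0 - tau)
    np.fill_diagonal(w, 0.0)
    return w


def bme_length(d: Union[DistanceMatrix, np.ndarray], tree: Phylogeny) -> float:
    """Balanced tree length ``L(T)`` by direct summation over the path-length
    matrix (row-major accumulation; bit-stable across runs)."""
    dm = as_array(d)
    if dm.shape[0] != tree.n:
        raise LeafSetMismatchError(
            f"matrix has {dm.shape[0]} taxa, tree has {tree.n}")
    w = pauplin_weights(tree)
    return float(np.sum(w * dm)) / 2.0


def omega_bound(n: int, d: Union[DistanceMatrix, np.ndarray]) -> float:
    """Error tolerance ``omega = n^2 * 2^(-49) * max d_ij`` for comparing
    computed lengths of two n-taxon trees."""
    dm = as_array(d)
    return float(n * n * 2.0 ** (-49) * dm.max())


def certified_less(l1: float, l2: float, omega: float) -> bool:
    """True iff ``l1 + omega < l2``, which certifies that the exact lengths
    satisfy ``L1 < L2``.  False means "not certified", not "greater"."""
    return l1 + omega < l2
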