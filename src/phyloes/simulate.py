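"""Synthetic data: random topologies, additive and noisy distance matrices.

These generators stand in for real distance matrices (which in practice are
estimated from alignments by external tools).  An *additive* matrix is one
whose entries are path sums on a positively-weighted tree; on such input
the balanced-length optimum is exactly the generating topology, which makes
additive instances the natural correctness oracle.  Multiplicative Gaussian
noise (clamped at zero) degrades additivity while keeping matrices
symmetric and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .bme import DistanceMatrix
from .encoding import TreeCode, decode, random_code
from .errors import InvalidMatrixError
from .tree_core import Phylogeny


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic instance.

    Branch lengths are exponential with mean ``branch_mean`` (a conventional
    phylogenetic simulation default; strictly positive).  ``sigma`` is the
    standard deviation of the multiplicative Gaussian noise; 0 keeps the
    matrix exactly additive.
    """

    n: int
    branch_mean: float = 0.1
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise InvalidMatrixError(f"need at least 3 taxa, got {self.n}")
        if self.branch_mean <= 0:
            raise InvalidMatrixError("branch_mean must be positive")
        if self.sigma < 0:
            raise InvalidMatrixError("sigma must be non-negative")


def _additive_from_tree(tree: Phylogeny, lengths: dict) -> np.ndarray:
    """Leaf-to-leaf path sums of per-edge ``lengths`` keyed by (min, max)."""
    n = tree.n
    d = np.zeros((n, n))
    for i in range(1, n + 1):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in tree.adj[u]:
                if v not in dist:
                    e = (u, v) if u < v else (v, u)
                    dist[v] = dist[u] + lengths[e]
                    stack.append(v)
        for j in range(i + 1, n + 1):
            d[i - 1, j - 1] = d[j - 1, i - 1] = dist[j]
    return d


def random_additive_matrix(spec: SyntheticSpec
                           ) -> Tuple[DistanceMatrix, Phylogeny]:
    """Sample a uniform topology, draw exponential branch lengths, and set
    ``d_ij`` to the path sum.  The result satisfies the four-point condition
    exactly (up to float round-off).  ``spec.sigma`` must be 0; perturb
    afterwards with :func:`perturb_matrix`."""
    if spec.sigma != 0:
        raise InvalidMatrixError(
            "random_additive_matrix requires sigma=0; use perturb_matrix")
    rng = np.random.default_rng(spec.seed)
    tree = decode(random_code(spec.n, rng))
    lengths = {}
    for e in tree.edges():
        b = 0.0
        while b <= 0.0:  # exponential draws are a.s. positive; belt and braces
            b = float(rng.exponential(spec.branch_mean))
        lengths[e] = b
    d = _additive_from_tree(tree, lengths)
    return DistanceMatrix.from_array(d), tree


def perturb_matrix(d: DistanceMatrix, sigma: float,
                   seed: int = 0) -> DistanceMatrix:
    """Multiplicative noise: ``d'_ij = d_ij * max(0, 1 + eps_ij)`` with
    ``eps_ij ~ N(0, sigma)``, one draw per unordered pair (symmetric by
    construction); the diagonal stays zero."""
    if sigma < 0:
        raise InvalidMatrixError("sigma must be non-negative")
    if sigma == 0:
        return d
    rng = np.random.default_rng(seed)
    n = d.n
    vals = d.values.copy()
    for i in range(n):
        for j in range(i + 1, n):
            f = max(0.0, 1.0 + sigma * rng.standard_normal())
            vals[i, j] = vals[j, i] = vals[i, j] * f
    return DistanceMatrix(vals, d.names)


def four_point_violation(d) -> float:
    """Largest violation of the four-point condition
    ``d_ij + d_kr <= max(d_ik + d_jr, d_ir + d_jk)`` over all quadruples
    (0 for an additive matrix)."""
    from itertools import combinations

    from .bme import as_array
    dm = as_array(d)
    n = dm.shape[0]
    worst = 0.0
    for i, j, k, r in combinations(range(n), 4):
        sums = sorted((dm[i, j] + dm[k, r], dm[i, k] + dm[j, r],
                       dm[i, r] + dm[j, k]))
        worst = max(worst, sums[2] - sums[1])  # two largest must be equal
    return worst


def caterpillar_tree(n: int) -> Phylogeny:
    """The maximally unbalanced topology: internal nodes form a path; taxa
    1 and 2 hang off one end, n-1 and n off the other.  Realizes the largest
    possible leaf-to-leaf path length, ``tau(1, n) = n - 1``."""
    if n < 4:
        return decode(TreeCode(3, ()))
    first, last = n + 1, 2 * n - 2
    adj = {first: [1, 2, first + 1], last: [n - 1, n, last - 1],
           1: [first], 2: [first], n - 1: [last], n: [last]}
    for k, node in enumerate(range(first + 1, last), start=3):
        adj[node] = [k, node - 1, node + 1]
        adj[k] = [node]
    return Phylogeny(n, adj)


def worked_example_trees() -> Tuple[Phylogeny, Phylogeny]:
    """The two 5-taxon demonstration topologies used throughout the docs:
    codes (3,5) -> ((t1,t2),t5,(t3,t4)) and (1,3) -> ((t1,t4),t2,(t3,t5))."""
    return decode(TreeCode(5, (3, 5))), decode(TreeCode(5, (1, 3)))
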