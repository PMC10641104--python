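"""Unrooted binary leaf-labeled trees: structure, path lengths, splits, RF.

A phylogeny on ``n`` taxa is an unrooted tree whose leaves carry the labels
``1..n`` and whose internal nodes (labels ``> n``, canonically
``n+1..2n-2``) all have degree 3.  Topological comparisons (splits,
Robinson--Foulds distance) ignore internal labels entirely.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .errors import InvalidTreeError, LeafSetMismatchError

Edge = Tuple[int, int]


class Phylogeny:
    """Unrooted binary tree with leaves ``1..n``.

    Parameters
    ----------
    n:
        Number of taxa (>= 3).
    adjacency:
        Mapping node -> iterable of neighbor nodes.  Symmetry is assumed;
        neighbor lists are stored sorted for deterministic iteration.
    validate:
        Check the structural invariants (degree-1 leaves, degree-3 internal
        nodes, connectedness, ``2n-3`` edges) on construction.
    """

    __slots__ = ("n", "adj")

    def __init__(self, n: int, adjacency: Dict[int, Iterable[int]],
                 validate: bool = True):
        self.n = int(n)
        self.adj: Dict[int, List[int]] = {
            int(u): sorted(int(v) for v in vs) for u, vs in adjacency.items()
        }
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def leaves(self) -> range:
        return range(1, self.n + 1)

    @property
    def internal_nodes(self) -> List[int]:
        return sorted(u for u in self.adj if u > self.n)

    def edges(self) -> List[Edge]:
        """All edges as (min, max) pairs in canonical sorted order."""
        out = []
        for u, vs in self.adj.items():
            for v in vs:
                if u < v:
                    out.append((u, v))
        out.sort()
        return out

    def internal_edges(self) -> List[Edge]:
        n = self.n
        return [(u, v) for (u, v) in self.edges() if u > n and v > n]

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.n, {u: list(vs) for u, vs in self.adj.items()},
                         validate=False)

    def validate(self) -> None:
        n = self.n
        if n < 3:
            raise InvalidTreeError(f"need at least 3 taxa, got {n}")
        for leaf in range(1, n + 1):
            if leaf not in self.adj:
                raise InvalidTreeError(f"missing leaf {leaf}")
            if len(self.adj[leaf]) != 1:
                raise InvalidTreeError(
                    f"leaf {leaf} has degree {len(self.adj[leaf])}, expected 1")
        internal = [u for u in self.adj if u > n]
        if any(u <= 0 for u in self.adj):
            raise InvalidTreeError("non-positive node label")
        if len(internal) != n - 2:
            raise InvalidTreeError(
                f"expected {n - 2} internal nodes, found {len(internal)}")
        for u in internal:
            if len(self.adj[u]) != 3:
                raise InvalidTreeError(
                    f"internal node {u} has degree {len(self.adj[u])}, expected 3")
        m = sum(len(vs) for vs in self.adj.values())
        if m % 2 or m // 2 != 2 * n - 3:
            raise InvalidTreeError(
                f"expected {2 * n - 3} edges, found {m / 2:g}")
        for u, vs in self.adj.items():
            for v in vs:
                if u not in self.adj.get(v, ()):
                    raise InvalidTreeError(f"asymmetric adjacency {u}-{v}")
        # connectivity
        seen = {1}
        stack = [1]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(self.adj):
            raise InvalidTreeError("tree is not connected")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Phylogeny(n={self.n}, edges={self.edges()})"


def bfs_distances(adj: Dict[int, List[int]], source: int) -> Dict[int, int]:
    """Edge-count distances from ``source`` to every node."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def path_length_matrix(tree: Phylogeny) -> np.ndarray:
    """Leaf-to-leaf topological distances tau (edge counts).

    Returns an ``(n, n)`` symmetric integer matrix with zero diagonal; taxon
    ``i`` is row ``i - 1``.
    """
    n = tree.n
    tau = np.zeros((n, n), dtype=np.int64)
    for i in range(1, n + 1):
        dist = bfs_distances(tree.adj, i)
        for j in range(i + 1, n + 1):
            tau[i - 1, j - 1] = tau[j - 1, i - 1] = dist[j]
    return tau


def _side_leaves(tree: Phylogeny, u: int, v: int) -> Set[int]:
    """Leaves in the component of ``v`` after removing edge (u, v)."""
    seen = {u, v}
    stack = [v]
    side = set()
    while stack:
        w = stack.pop()
        if w <= tree.n:
            side.add(w)
        for x in tree.adj[w]:
            if x not in seen:
                seen.add(x)
                stack.append(x)
    if v <= tree.n:
        side.add(v)
    return side


def splits(tree: Phylogeny) -> Set[Tuple[int, ...]]:
    """Nontrivial bipartitions induced by the internal edges.

    Each split is stored canonically as the sorted tuple of the side *not*
    containing taxon 1.  Binary trees with ``n >= 4`` have exactly ``n - 3``
    of them; the 3-taxon star has none.
    """
    result: Set[Tuple[int, ...]] = set()
    all_leaves = set(tree.leaves)
    for (u, v) in tree.internal_edges():
        side = _side_leaves(tree, u, v)
        if 1 in side:
            side = all_leaves - side
        result.add(tuple(sorted(side)))
    return result


def rf_distance(t1: Phylogeny, t2: Phylogeny) -> int:
    """Robinson--Foulds distance: |split set symmetric difference|.

    For two binary trees on the same leaf set this is an even integer in
    ``[0, 2(n-3)]``.
    """
    if t1.n != t2.n:
        raise LeafSetMismatchError(
            f"trees have different leaf sets ({t1.n} vs {t2.n} taxa)")
    s1, s2 = splits(t1), splits(t2)
    return len(s1 ^ s2)


def same_topology(t1: Phylogeny, t2: Phylogeny) -> bool:
    """True iff the two trees induce identical split sets (RF distance 0)."""
    return rf_distance(t1, t2) == 0
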