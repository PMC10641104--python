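"""Bijective step-wise tree encoding.

Every unrooted binary topology on taxa ``1..n`` can be built by starting
from the star on taxa 1,2,3 (center ``n+1``) and inserting taxon ``i+3`` at
step ``i`` on one edge of the current partial tree, the new internal node
being labeled ``n+1+i``.  Recording, for each step, the 1-based index of the
chosen edge in the *ordered edge list* gives an integer vector
``(h_1, ..., h_{n-3})`` with ``1 <= h_i <= 2i+1``; the map between codes and
topologies is a bijection, and the code space has size
``prod_i (2i+1) = (2n-5)!!``, the number of topologies.

The ordered edge list sorts edges ascending by the lower endpoint label and,
on ties, by the higher endpoint label.  This order must stay bit-stable:
codes are exchanged between individuals by the evolution strategy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Sequence, Set, Tuple

import numpy as np

from .errors import InvalidTreeError, TreeCodeError
from .tree_core import Edge, Phylogeny


@dataclass(frozen=True)
class TreeCode:
    """Step-wise construction code: ``h[i-1]`` selects the edge (1-based
    index in the ordered edge list) on which taxon ``i+3`` is inserted."""

    n: int
    h: Tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "h", tuple(int(x) for x in self.h))
        if self.n < 3:
            raise TreeCodeError(f"need at least 3 taxa, got n={self.n}")
        if len(self.h) != self.n - 3:
            raise TreeCodeError(
                f"code for n={self.n} must have {self.n - 3} components, "
                f"got {len(self.h)}")
        for i, hi in enumerate(self.h, start=1):
            if not 1 <= hi <= 2 * i + 1:
                raise TreeCodeError(
                    f"component {i} is {hi}, outside [1, {2 * i + 1}]")

    def __len__(self) -> int:
        return len(self.h)

    def __str__(self) -> str:
        return "(" + ",".join(str(x) for x in self.h) + ")"


def ordered_edge_list(tree: Phylogeny) -> List[Edge]:
    """Edges sorted ascending by (lower endpoint, higher endpoint)."""
    return tree.edges()


def _star_adj(n: int) -> Dict[int, List[int]]:
    c = n + 1
    return {1: [c], 2: [c], 3: [c], c: [1, 2, 3]}


def _insert(adj: Dict[int, List[int]], a: int, b: int, new: int,
            leaf: int) -> None:
    """Subdivide edge (a, b) with node ``new`` and attach ``leaf`` to it."""
    adj[a].remove(b)
    adj[b].remove(a)
    adj[a].append(new)
    adj[b].append(new)
    adj[new] = [a, b, leaf]
    adj[leaf] = [new]


def _edges_of(adj: Dict[int, List[int]]) -> List[Edge]:
    out = [(u, v) for u, vs in adj.items() for v in vs if u < v]
    out.sort()
    return out


def decode(code: TreeCode) -> Phylogeny:
    """Replay the step-wise construction encoded by ``code``.

    Returns a phylogeny with canonical internal labels ``n+1..2n-2`` (the
    star center is ``n+1``; the node created at step ``i`` is ``n+1+i``).
    """
    n = code.n
    adj = _star_adj(n)
    for i, hi in enumerate(code.h, start=1):
        edges = _edges_of(adj)
        if not 1 <= hi <= len(edges):
            raise TreeCodeError(
                f"component {i} is {hi}, edge list has {len(edges)} entries")
        a, b = edges[hi - 1]
        _insert(adj, a, b, n + 1 + i, i + 3)
    return Phylogeny(n, adj)


def decoding_edge_lists(code: TreeCode) -> List[List[Edge]]:
    """The ordered edge list of the partial tree before each insertion step.

    Entry ``i`` (0-based) is the list from which component ``h_{i+1}`` picks
    its edge; useful for inspecting the construction.
    """
    n = code.n
    adj = _star_adj(n)
    lists = []
    for i, hi in enumerate(code.h, start=1):
        edges = _edges_of(adj)
        lists.append(edges)
        a, b = edges[hi - 1]
        _insert(adj, a, b, n + 1 + i, i + 3)
    return lists


def encode(tree: Phylogeny) -> TreeCode:
    """The unique code whose decoding reproduces ``tree``'s topology.

    Internal labels of the input may be arbitrary; the code refers to the
    canonical labeling that :func:`decode` emits.  Works by stripping leaves
    ``n`` down to 4 (recording the edge each suppression restores), then
    replaying the construction forward with canonical labels and reading off
    each recorded edge's position in the ordered edge list.
    """
    tree.validate()
    n = tree.n
    if n == 3:
        return TreeCode(3, ())
    adj: Dict[int, Set[int]] = {u: set(vs) for u, vs in tree.adj.items()}
    records: List[Tuple[int, int, int, int]] = []  # (leaf, attach, a, b)
    for k in range(n, 3, -1):
        (p,) = adj[k]
        a, b = sorted(adj[p] - {k})
        del adj[k]
        del adj[p]
        adj[a].discard(p)
        adj[b].discard(p)
        adj[a].add(b)
        adj[b].add(a)
        records.append((k, p, a, b))
    # adj is now the star on taxa 1,2,3; map its labels to canonical ones.
    (center,) = adj[1]
    label = {1: 1, 2: 2, 3: 3, center: n + 1}
    canon = _star_adj(n)
    h: List[int] = []
    for i, (k, p, a, b) in enumerate(reversed(records), start=1):
        edge = (label[a], label[b]) if label[a] < label[b] else (label[b], label[a])
        edges = _edges_of(canon)
        try:
            h.append(edges.index(edge) + 1)
        except ValueError:  # pragma: no cover - guarded by validate()
            raise InvalidTreeError(f"edge {edge} missing during re-encoding")
        new = n + 1 + i
        _insert(canon, edge[0], edge[1], new, k)
        label[p] = new
        label[k] = k
    return TreeCode(n, tuple(h))


def random_code(n: int, rng) -> TreeCode:
    """Uniform random code: ``h_i ~ Uniform{1..2i+1}`` independently.

    Because the encoding is a bijection, the induced distribution over
    topologies is uniform over all ``(2n-5)!!`` of them.
    """
    if n < 3:
        raise TreeCodeError(f"need at least 3 taxa, got n={n}")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    h = tuple(int(rng.integers(1, 2 * i + 2)) for i in range(1, n - 2))
    return TreeCode(n, h)


def all_codes(n: int) -> Iterator[TreeCode]:
    """Exhaustive enumeration of the ``(2n-5)!!`` valid codes for ``n`` taxa."""
    ranges = [range(1, 2 * i + 2) for i in range(1, n - 2)]
    for h in itertools.product(*ranges):
        yield TreeCode(n, h)


def num_topologies(n: int) -> int:
    """(2n-5)!! — the number of unrooted binary topologies on n labeled leaves."""
    if n == 3:
        return 1
    return math.prod(range(3, 2 * n - 4, 2))
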