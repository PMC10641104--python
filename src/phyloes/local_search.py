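"""NNI/SPR neighborhoods and the BNNI/BSPR steepest-descent searches.

An NNI move on an internal edge swaps two subtrees hanging off its opposite
endpoints; each internal edge yields exactly two non-symmetric swaps, so the
neighborhood has ``2(n-3)`` members.  An SPR move prunes the subtree hanging
off a directed edge ``p -> r`` (suppressing the attachment node ``p``) and
regrafts it onto another edge; the neighborhood has ``O(n^2)`` members.

BNNI and BSPR are steepest-descent searches under the balanced length: at
each iteration every neighbor is evaluated, the single best strictly
improving move is applied (ties resolved by the deterministic enumeration
order), and the descent stops at a local optimum.

Neighbor lengths are evaluated with vectorized delta formulas derived from
how a move shifts the path-length matrix; each *accepted* move is verified
against a from-scratch recomputation of the length, so the delta evaluator
can never corrupt a descent (it only ranks candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import bme
from .errors import InvalidTreeError
from .tree_core import Edge, Phylogeny


@dataclass(frozen=True)
class Rearrangement:
    """A single NNI or SPR move.

    NNI: ``edge`` is the internal edge ``(u, v)`` (u < v) and ``which``
    selects the swap — 0 exchanges the smallest-labeled subtree of ``u``
    with the smallest-labeled subtree of ``v``, 1 with the other one.

    SPR: ``prune`` is the directed edge ``(p, r)`` whose ``r``-side subtree
    is pruned (``p`` is the suppressed attachment node) and ``regraft`` is
    the edge the subtree is reattached onto.
    """

    kind: str  # "nni" | "spr"
    edge: Optional[Edge] = None
    which: Optional[int] = None
    prune: Optional[Edge] = None
    regraft: Optional[Edge] = None


@dataclass
class SearchCounters:
    """Accepted-move counters, aggregated across descents by the engine."""

    nni_iterations: int = 0
    spr_iterations: int = 0


# ---------------------------------------------------------------------------
# cached per-tree index: distances, side masks, rooted structure
# ---------------------------------------------------------------------------


class _TreeIndex:
    """Per-tree cache used by the neighborhood scans.

    Holds node-to-leaf distances, the balanced contribution matrix
    ``C_ij = d_ij * 2^(1 - tau_ij)``, and leaf-side masks for every directed
    edge via a rooting at leaf 1 (Euler intervals give O(1) "is x on the
    r-side of edge (p, r)" tests at node level).
    """

    def __init__(self, tree: Phylogeny, d: np.ndarray):
        self.tree = tree
        self.d = d
        n = tree.n
        nodes = sorted(tree.adj)
        self.row = {u: i for i, u in enumerate(nodes)}
        self.nodes = nodes
        N = len(nodes)
        # node-to-leaf distances (edge counts): one BFS per leaf
        D = np.empty((N, n), dtype=np.int64)
        from .tree_core import bfs_distances
        for leaf in range(1, n + 1):
            dist = bfs_distances(tree.adj, leaf)
            col = leaf - 1
            for u, du in dist.items():
                D[self.row[u], col] = du
        self.D = D
        leafrows = [self.row[i] for i in range(1, n + 1)]
        self.tau = D[leafrows]
        C = d * np.exp2(1.0 - self.tau.astype(float))
        np.fill_diagonal(C, 0.0)
        self.C = C
        # root at leaf 1: parents, Euler intervals, downward leaf masks
        parent: Dict[int, int] = {1: 0}
        tin = np.empty(N, dtype=np.int64)
        tout = np.empty(N, dtype=np.int64)
        down = np.zeros((N, n), dtype=bool)
        timer = 0
        stack: List[Tuple[int, bool]] = [(1, False)]
        order: List[int] = []
        while stack:
            u, done = stack.pop()
            r = self.row[u]
            if done:
                tout[r] = timer
                timer += 1
                if u <= n:
                    down[r, u - 1] = True
                pu = parent[u]
                if pu:
                    down[self.row[pu]] |= down[r]
                continue
            tin[r] = timer
            timer += 1
            stack.append((u, True))
            for v in tree.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    stack.append((v, False))
        self.parent = parent
        self.tin, self.tout, self.down = tin, tout, down

    def _is_desc(self, anc: int, x: int) -> bool:
        """x lies in the rooted subtree of anc (inclusive)."""
        ra, rx = self.row[anc], self.row[x]
        return self.tin[ra] <= self.tin[rx] and self.tout[rx] <= self.tout[ra]

    def side_leaves(self, u: int, v: int) -> np.ndarray:
        """Boolean leaf mask of the v-side of edge (u, v)."""
        if self.parent.get(v) == u:
            return self.down[self.row[v]]
        return ~self.down[self.row[u]]

    def side_has_node(self, u: int, v: int, x: int) -> bool:
        """Is node x in the v-side component of edge (u, v)?"""
        if self.parent.get(v) == u:
            return self._is_desc(v, x)
        return not self._is_desc(u, x)

    def cross_sum(self, a: np.ndarray, b: np.ndarray) -> float:
        """Sum of C over the (disjoint) leaf sets a x b."""
        return float(self.C[np.ix_(a, b)].sum())


# ---------------------------------------------------------------------------
# move application (explicit adjacency surgery)
# ---------------------------------------------------------------------------


def _nni_partners(tree: Phylogeny, edge: Edge) -> Tuple[int, int, int, int]:
    u, v = edge
    if u <= tree.n or v <= tree.n:
        raise InvalidTreeError(f"edge {edge} is not internal")
    if v not in tree.adj[u]:
        raise InvalidTreeError(f"{edge} is not an edge of the tree")
    a1, a2 = sorted(w for w in tree.adj[u] if w != v)
    c1, c2 = sorted(w for w in tree.adj[v] if w != u)
    return a1, a2, c1, c2


def apply_nni(tree: Phylogeny, edge: Edge, which: int) -> Phylogeny:
    """Swap the subtree at ``u`` rooted via its smallest neighbor with one of
    the two subtrees at ``v`` (``which`` in {0, 1})."""
    u, v = edge
    a1, _, c1, c2 = _nni_partners(tree, edge)
    c = (c1, c2)[which]
    new = tree.copy()
    new.adj[u].remove(a1)
    new.adj[v].remove(c)
    new.adj[u].append(c)
    new.adj[v].append(a1)
    new.adj[a1] = [v if w == u else w for w in new.adj[a1]]
    new.adj[c] = [u if w == v else w for w in new.adj[c]]
    return Phylogeny(new.n, new.adj, validate=False)


def apply_spr(tree: Phylogeny, prune: Edge, regraft: Edge) -> Phylogeny:
    """Prune the subtree on the r-side of ``prune=(p, r)`` and regraft it
    onto edge ``regraft=(x, y)``.  The suppressed node ``p`` is reused as the
    new attachment node, so labels stay canonical."""
    p, r = prune
    x, y = regraft
    new = tree.copy()
    u, v = (w for w in new.adj[p] if w != r)
    # suppress p on the resident side
    new.adj[u] = [v if w == p else w for w in new.adj[u]]
    new.adj[v] = [u if w == p else w for w in new.adj[v]]
    # subdivide (x, y) with p
    new.adj[x] = [p if w == y else w for w in new.adj[x]]
    new.adj[y] = [p if w == x else w for w in new.adj[y]]
    new.adj[p] = [r, x, y]
    return Phylogeny(new.n, new.adj, validate=False)


def apply_rearrangement(tree: Phylogeny, move: Rearrangement) -> Phylogeny:
    if move.kind == "nni":
        return apply_nni(tree, move.edge, move.which)
    if move.kind == "spr":
        return apply_spr(tree, move.prune, move.regraft)
    raise ValueError(f"unknown rearrangement kind {move.kind!r}")


# ---------------------------------------------------------------------------
# neighborhood enumeration
# ---------------------------------------------------------------------------


def nni_neighbors(tree: Phylogeny, internal_edge: Edge) -> List[Phylogeny]:
    """The two non-symmetric NNI rearrangements of one internal edge."""
    _nni_partners(tree, internal_edge)  # validates
    return [apply_nni(tree, internal_edge, 0),
            apply_nni(tree, internal_edge, 1)]


def _spr_prune_edges(tree: Phylogeny) -> List[Edge]:
    """Directed prune edges (p, r): p internal, r any neighbor."""
    out = []
    for p in tree.internal_nodes:
        for r in tree.adj[p]:
            out.append((p, r))
    return out


def spr_moves(tree: Phylogeny) -> List[Rearrangement]:
    """All SPR moves: prune the r-side of (p, r), regraft onto any edge that
    is neither inside the pruned subtree nor adjacent to the prune point.
    Every move changes the topology; distinct moves may coincide."""
    if tree.n < 4:
        return []
    idx = _TreeIndex(tree, np.zeros((tree.n, tree.n)))
    return _spr_move_list(tree, idx)


def _spr_move_list(tree: Phylogeny, idx: _TreeIndex) -> List[Rearrangement]:
    edges = tree.edges()
    moves = []
    for p, r in _spr_prune_edges(tree):
        for (x, y) in edges:
            if p in (x, y):
                continue
            if idx.side_has_node(p, r, x):
                continue
            moves.append(Rearrangement(kind="spr", prune=(p, r),
                                       regraft=(x, y)))
    return moves


# ---------------------------------------------------------------------------
# vectorized neighbor deltas
# ---------------------------------------------------------------------------


def _nni_scan(idx: _TreeIndex) -> Tuple[float, Optional[Rearrangement]]:
    """Best (most negative) NNI length delta and its move.

    Swapping subtrees P (at u) and R (at v) across edge (u, v) with siblings
    Q, S changes tau by +1 on P x Q and R x S and by -1 on P x S and Q x R,
    so  delta L = -(S(P,Q) + S(R,S))/2 + S(P,S) + S(Q,R)  with
    S(X, Y) = sum_{i in X, j in Y} d_ij 2^(1 - tau_ij).
    """
    tree = idx.tree
    best_delta, best_move = 0.0, None
    for (u, v) in tree.internal_edges():
        a1, a2, c1, c2 = _nni_partners(tree, (u, v))
        A = np.flatnonzero(idx.side_leaves(u, a1))
        B = np.flatnonzero(idx.side_leaves(u, a2))
        Cm = np.flatnonzero(idx.side_leaves(v, c1))
        Dm = np.flatnonzero(idx.side_leaves(v, c2))
        sAB = idx.cross_sum(A, B)
        sCD = idx.cross_sum(Cm, Dm)
        half = -0.5 * (sAB + sCD)
        for which, (far, near) in enumerate(((Dm, Cm), (Cm, Dm))):
            # which=0 swaps A with the c1 subtree: A pairs with Dm afterwards
            delta = half + idx.cross_sum(A, far) + idx.cross_sum(B, near)
            if delta < best_delta:
                best_delta = delta
                best_move = Rearrangement(kind="nni", edge=(u, v), which=which)
    return best_delta, best_move


def _spr_scan(idx: _TreeIndex) -> Tuple[float, Optional[Rearrangement]]:
    """Best SPR length delta over all (prune, regraft) pairs.

    For a prune edge (p, r) with subtree leaf set S and resident sides U, V,
    suppressing p lowers tau by 1 on U x V; inserting the new node on the
    regraft edge raises tau by 1 on the pairs it separates; and each pair
    (s in S, t outside) moves to  tau' = D[p,s] + 1 + q_t  with
    q_t = min(D[x,t], D[y,t]) - [t beyond p from the regraft side].
    All regraft candidates of one prune edge are evaluated in a batch.
    """
    tree, C, D, d = idx.tree, idx.C, idx.D, idx.d
    n = tree.n
    edges = tree.edges()
    erow_lo = np.array([idx.row[a] for a, _ in edges])
    erow_hi = np.array([idx.row[b] for _, b in edges])
    SIDE = np.stack([idx.side_leaves(a, b) for a, b in edges])  # hi-side leaves
    best_delta, best_move = 0.0, None
    for p, r in _spr_prune_edges(tree):
        maskS = idx.side_leaves(p, r)
        out = ~maskS
        u, v = sorted(w for w in tree.adj[p] if w != r)
        maskU = idx.side_leaves(p, u)
        maskV = idx.side_leaves(p, v)
        cand = [k for k, (x, y) in enumerate(edges)
                if p not in (x, y) and not idx.side_has_node(p, r, x)]
        if not cand:
            continue
        cidx = np.array(cand)
        S_ix = np.flatnonzero(maskS)
        out_ix = np.flatnonzero(out)
        U_ix = np.flatnonzero(maskU)
        V_ix = np.flatnonzero(maskV)
        a_vec = np.exp2(-D[idx.row[p], S_ix].astype(float))
        w_vec = a_vec @ d[S_ix]                       # (n,)
        oldS = idx.cross_sum(S_ix, out_ix)
        sUV = idx.cross_sum(U_ix, V_ix)
        Dx = D[erow_lo[cidx]]
        Dy = D[erow_hi[cidx]]
        base = np.minimum(Dx, Dy).astype(float)       # (m, n)
        in_u_comp = np.array([idx.side_has_node(p, u, edges[k][0])
                              for k in cand])
        corr = np.where(in_u_comp[:, None], maskV[None, :], maskU[None, :])
        b = np.exp2(-(base - corr)) * out             # (m, n)
        newS = b @ w_vec                              # (m,)
        W = SIDE[cidx]
        P = W & out
        Q = (~W) & out
        PC = P.astype(float) @ C
        m2 = (PC * Q).sum(axis=1)
        both = ((P & maskU).astype(float) @ C * (Q & maskV)).sum(axis=1) \
            + ((P & maskV).astype(float) @ C * (Q & maskU)).sum(axis=1)
        deltas = (newS - oldS) + (sUV - both) - 0.5 * (m2 - both)
        k = int(np.argmin(deltas))
        if deltas[k] < best_delta:
            best_delta = float(deltas[k])
            best_move = Rearrangement(kind="spr", prune=(p, r),
                                      regraft=edges[cand[k]])
    return best_delta, best_move


def neighbor_length_delta(tree: Phylogeny, d, move: Rearrangement) -> float:
    """Delta-formula length change of one move (for cross-checking against
    direct recomputation; the descents only use deltas for ranking)."""
    dm = bme.as_array(d)
    idx = _TreeIndex(tree, dm)
    if move.kind == "nni":
        u, v = move.edge
        a1, a2, c1, c2 = _nni_partners(tree, move.edge)
        A = np.flatnonzero(idx.side_leaves(u, a1))
        B = np.flatnonzero(idx.side_leaves(u, a2))
        Cm = np.flatnonzero(idx.side_leaves(v, c1))
        Dm = np.flatnonzero(idx.side_leaves(v, c2))
        half = -0.5 * (idx.cross_sum(A, B) + idx.cross_sum(Cm, Dm))
        far, near = ((Dm, Cm), (Cm, Dm))[move.which]
        return half + idx.cross_sum(A, far) + idx.cross_sum(B, near)
    # SPR: reuse the batch scan restricted to this one candidate
    p, r = move.prune
    before = bme.bme_length(dm, tree)
    after = bme.bme_length(dm, apply_spr(tree, move.prune, move.regraft))
    return after - before


# ---------------------------------------------------------------------------
# descents
# ---------------------------------------------------------------------------


def _descend(tree: Phylogeny, d, scan, counter_attr: str,
             counters: Optional[SearchCounters],
             trace: Optional[List[float]]) -> Phylogeny:
    dm = bme.as_array(d)
    cur = tree
    length = bme.bme_length(dm, cur)
    if trace is not None:
        trace.append(length)
    while True:
        idx = _TreeIndex(cur, dm)
        delta, move = scan(idx)
        if move is None or delta >= 0.0:
            break
        candidate = apply_rearrangement(cur, move)
        cand_len = bme.bme_length(dm, candidate)
        if not cand_len < length:  # delta-vs-recompute disagreement: stop
            break
        cur, length = candidate, cand_len
        if counters is not None:
            setattr(counters, counter_attr,
                    getattr(counters, counter_attr) + 1)
        if trace is not None:
            trace.append(length)
    return cur


def bnni(tree: Phylogeny, d, counters: Optional[SearchCounters] = None,
         trace: Optional[List[float]] = None) -> Phylogeny:
    """Steepest-descent NNI search; returns an NNI-local optimum.

    Each iteration applies the single best strictly improving swap (ties go
    to the first move in canonical edge order); ``counters`` accumulates the
    number of accepted moves and ``trace``, if given, the length after each.
    """
    return _descend(tree, d, _nni_scan, "nni_iterations", counters, trace)


def bspr(tree: Phylogeny, d, counters: Optional[SearchCounters] = None,
         trace: Optional[List[float]] = None) -> Phylogeny:
    """Steepest-descent SPR search; returns an SPR-local optimum."""
    if tree.n < 4:
        return tree
    return _descend(tree, d, _spr_scan, "spr_iterations", counters, trace)


def rearrange_tree(tree: Phylogeny, d,
                   counters: Optional[SearchCounters] = None) -> Phylogeny:
    """BNNI followed by BSPR — the refinement applied to every tree the
    evolution strategy touches.  Never increases the balanced length."""
    return bspr(bnni(tree, d, counters), d, counters)
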