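"""PHYLIP square distance matrices and Newick trees.

Only the square symmetric PHYLIP dialect is supported (the lower-triangular
variant is not), with relaxed taxon names: any non-whitespace token, not
the classic 10-character fixed width.  Newick reading goes through dendropy
and accepts rooted binary inputs (the degree-2 root is suppressed); Newick
writing emits a canonical, bit-stable form — a trifurcation at the internal
node adjacent to taxon 1, children ordered by the smallest leaf label in
each subtree, no branch lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .bme import DistanceMatrix
from .errors import (LeafSetMismatchError, NewickParseError,
                     PhylipParseError)
from .tree_core import Phylogeny

TextSource = Union[str, io.TextIOBase]


@dataclass(frozen=True)
class TaxonTable:
    """Ordered taxon names; name <-> 1-based internal index bijection."""

    names: Tuple[str, ...]

    def __post_init__(self):
        names = tuple(str(s).strip() for s in self.names)
        if any(not s for s in names):
            raise PhylipParseError("empty taxon name")
        if len(set(names)) != len(names):
            raise PhylipParseError("duplicate taxon names")
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """1-based internal index of ``name``."""
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise LeafSetMismatchError(f"unknown taxon {name!r}") from None


def _read_text(source: TextSource) -> str:
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _natural_key(label: str):
    import re
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in re.split(r"(\d+)", label))


# ---------------------------------------------------------------------------
# PHYLIP distance matrices
# ---------------------------------------------------------------------------


def read_phylip_matrix(source: TextSource) -> DistanceMatrix:
    """Parse a square PHYLIP distance matrix (rows may wrap lines).

    Structure: a taxon-count token, then ``n`` records of one name followed
    by ``n`` values.  Symmetry, non-negativity, and the zero diagonal are
    enforced by :class:`DistanceMatrix` validation.
    """
    tokens = _read_text(source).split()
    if not tokens:
        raise PhylipParseError("empty input")
    try:
        n = int(tokens[0])
    except ValueError:
        raise PhylipParseError(
            f"first token must be the taxon count, got {tokens[0]!r}") from None
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise PhylipParseError(
            f"expected {expected} tokens for {n} taxa, got {len(tokens)}")
    names: List[str] = []
    rows = np.empty((n, n))
    pos = 1
    for i in range(n):
        names.append(tokens[pos])
        pos += 1
        for j in range(n):
            try:
                rows[i, j] = float(tokens[pos])
            except ValueError:
                raise PhylipParseError(
                    f"bad value {tokens[pos]!r} in row {i + 1}") from None
            pos += 1
    return DistanceMatrix(rows, tuple(names))


def write_phylip_matrix(d: DistanceMatrix, sink: io.TextIOBase) -> None:
    """Square PHYLIP with 12-significant-digit values (reader's inverse)."""
    sink.write(f"{d.n}\n")
    width = max(len(s) for s in d.names)
    for name, row in zip(d.names, d.values):
        vals = " ".join(f"{x:.12g}" for x in row)
        sink.write(f"{name:<{width}} {vals}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def newick_string(tree: Phylogeny, names: Union[TaxonTable, Sequence[str],
                                                None] = None) -> str:
    """Canonical Newick of an unrooted binary tree (see module docstring)."""
    if names is None:
        names = TaxonTable(tuple(f"t{i}" for i in range(1, tree.n + 1)))
    elif not isinstance(names, TaxonTable):
        names = TaxonTable(tuple(names))
    if names.n != tree.n:
        raise LeafSetMismatchError(
            f"{names.n} names for a {tree.n}-taxon tree")

    def min_leaf(u: int, parent: int) -> int:
        if u <= tree.n:
            return u
        return min(min_leaf(v, u) for v in tree.adj[u] if v != parent)

    def render(u: int, parent: int) -> str:
        if u <= tree.n:
            return names.names[u - 1]
        children = sorted((v for v in tree.adj[u] if v != parent),
                          key=lambda v: min_leaf(v, u))
        return "(" + ",".join(render(v, u) for v in children) + ")"

    root = tree.adj[1][0]  # internal node adjacent to taxon 1
    children = sorted(tree.adj[root], key=lambda v: min_leaf(v, root))
    return "(" + ",".join(render(v, root) for v in children) + ");"


def write_newick(tree: Phylogeny, names, sink: io.TextIOBase) -> None:
    sink.write(newick_string(tree, names) + "\n")


def read_newick(source: TextSource,
                names: Optional[TaxonTable] = None) -> Phylogeny:
    """Parse a Newick tree into a binary phylogeny.

    Branch lengths are parsed and discarded; a degree-2 root is suppressed.
    With a taxon table, leaves map through it (unknown names are errors);
    without one, taxa are numbered by natural sort of their labels (digit
    runs compare numerically, so t2 precedes t10).  Any polytomy beyond the
    root trifurcation is rejected.
    """
    text = _read_text(source).strip()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise NewickParseError(f"cannot parse Newick: {exc}") from None
    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = []
    for lf in leaves:
        if lf.taxon is None or not lf.taxon.label:
            raise NewickParseError("unnamed leaf")
        labels.append(lf.taxon.label)
    if len(set(labels)) != len(labels):
        raise NewickParseError("duplicate leaf names")
    n = len(labels)
    if n < 3:
        raise NewickParseError(f"need at least 3 leaves, got {n}")
    if names is not None:
        if names.n != n:
            raise LeafSetMismatchError(
                f"tree has {n} leaves, table has {names.n} names")
        leaf_id = {lf: names.index(lbl) for lf, lbl in zip(leaves, labels)}
    else:
        order = {lbl: i + 1
                 for i, lbl in enumerate(sorted(labels, key=_natural_key))}
        leaf_id = {lf: order[lbl] for lf, lbl in zip(leaves, labels)}

    next_internal = n + 1
    node_id: Dict[object, int] = {}
    adj: Dict[int, List[int]] = {}
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            node_id[node] = leaf_id[node]
        else:
            node_id[node] = next_internal
            next_internal += 1
        adj[node_id[node]] = []
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            adj[node_id[node]].append(node_id[child])
            adj[node_id[child]].append(node_id[node])
    root = node_id[dtree.seed_node]
    if len(adj[root]) == 2:  # rooted input: suppress the root
        a, b = adj[root]
        adj[a] = [b if w == root else w for w in adj[a]]
        adj[b] = [a if w == root else w for w in adj[b]]
        del adj[root]
    for u, vs in adj.items():
        if u > n and len(vs) != 3:
            raise NewickParseError(
                f"polytomy: internal node of degree {len(vs)} "
                "(this tool is binary-only)")
        if u <= n and len(vs) != 1:
            raise NewickParseError("leaf with multiple neighbors")
    # relabel internal nodes canonically n+1..2n-2
    internal = sorted(u for u in adj if u > n)
    relabel = {u: n + 1 + i for i, u in enumerate(internal)}
    relabel.update({i: i for i in range(1, n + 1)})
    adj = {relabel[u]: [relabel[v] for v in vs] for u, vs in adj.items()}
    try:
        return Phylogeny(n, adj)
    except Exception as exc:
        raise NewickParseError(str(exc)) from None
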