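"""Neighbour-joining tree construction and deterministic leaf ordering.

The identity matrix is displayed with rows/columns arranged as the leaves
of a rooted neighbour-joining tree built from 1 - identity distances, so
that related sequences sit next to each other.  Only the leaf ORDER feeds
downstream computation; the rooting and ladderizing conventions below exist
to make that order reproducible:

* input taxa are canonicalised to lexicographic order before agglomeration,
  so permuting the input changes nothing;
* Q-matrix ties join the first eligible pair in that canonical ordering;
* the tree is rooted at the final join, splitting the last edge in half;
* children are ladderized by (descending subtree leaf count, ascending
  smallest leaf label).

Negative branch-length estimates are clamped to zero after estimation; they
affect display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .identity import DistanceTable


class TreeError(ValueError):
    """Raised for invalid distance input."""


@dataclass
class TreeNode:
    """Node of a rooted tree; leaves carry a name, edges a length."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    @property
    def leaf_count(self) -> int:
        return len(self.leaves())

    @property
    def min_leaf(self) -> str:
        return min(leaf.name for leaf in self.leaves())


@dataclass
class OrderedTree:
    """Rooted NJ tree plus the leaf order of its planar (ladderized) drawing."""

    root: TreeNode
    leaf_order: list[str]


def _ladderize(node: TreeNode) -> None:
    for child in node.children:
        _ladderize(child)
    node.children.sort(key=lambda c: (-c.leaf_count, c.min_leaf))


def neighbor_joining(dist: DistanceTable) -> OrderedTree:
    """Classical Saitou–Nei NJ with the determinism conventions above.

    Requires a symmetric table with zero diagonal and S >= 2.  For additive
    distances the tree's patristic distances reproduce the input exactly
    (up to round-off).
    """
    ids = list(dist.ids)
    if len(ids) < 2:
        raise TreeError("need at least 2 taxa")
    if len(set(ids)) != len(ids):
        raise TreeError("duplicate taxon labels")
    values = np.asarray(dist.values, dtype=float)
    if np.isnan(values).any():
        raise TreeError("distance table contains NaN")

    # canonicalise taxon order so the result is input-permutation invariant
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    ids = [ids[i] for i in order]
    d = values[np.ix_(order, order)].copy()

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]

    if len(nodes) == 2:
        half = max(d[0, 1] / 2.0, 0.0)
        nodes[0].length = half
        nodes[1].length = half
        root = TreeNode(children=nodes)
    else:
        active = list(range(len(nodes)))  # kept sorted by min leaf label
        while len(active) > 2:
            n = len(active)
            sub = d[np.ix_(active, active)]
            r = sub.sum(axis=1)
            q = (n - 2) * sub - r[:, None] - r[None, :]
            np.fill_diagonal(q, np.inf)
            # first (row-major) minimum in the canonical active ordering
            flat = int(np.argmin(q))
            i, j = divmod(flat, n)
            if i > j:
                i, j = j, i
            ai, aj = active[i], active[j]
            dij = sub[i, j]
            li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
            lj = dij - li
            nodes[ai].length = max(li, 0.0)
            nodes[aj].length = max(lj, 0.0)
            parent = TreeNode(children=[nodes[ai], nodes[aj]])
            nodes.append(parent)
            pk = len(nodes) - 1
            # distances from the new node to every other active node
            d = np.pad(d, ((0, 1), (0, 1)))
            for k in active:
                if k in (ai, aj):
                    continue
                dk = (d[ai, k] + d[aj, k] - dij) / 2.0
                d[pk, k] = d[k, pk] = dk
            remaining = [k for k in active if k not in (ai, aj)]
            # keep the active list ordered by smallest leaf label
            key = parent.min_leaf
            pos = 0
            while pos < len(remaining) and nodes[remaining[pos]].min_leaf < key:
                pos += 1
            active = remaining[:pos] + [pk] + remaining[pos:]
        a, b = active
        half = max(d[a, b] / 2.0, 0.0)
        nodes[a].length = half
        nodes[b].length = half
        root = TreeNode(children=[nodes[a], nodes[b]])

    _ladderize(root)
    return OrderedTree(root, leaf_order(root))


def leaf_order(tree: OrderedTree | TreeNode) -> list[str]:
    """Depth-first left-to-right leaf labels of the ladderized rooted tree."""
    root = tree.root if isinstance(tree, OrderedTree) else tree
    return [leaf.name for leaf in root.leaves()]


def patristic_distances(tree: OrderedTree) -> DistanceTable:
    """Leaf-to-leaf path-length sums on the tree (for additivity checks)."""
    # depth of every leaf below each node, keyed by node identity
    leaf_depth: dict[int, dict[str, float]] = {}

    def collect(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            below = {node.name: 0.0}
        else:
            below = {}
            for child in node.children:
                for name, depth in collect(child).items():
                    below[name] = depth + child.length
        leaf_depth[id(node)] = below
        return below

    collect(tree.root)
    order = leaf_order(tree)
    index = {name: i for i, name in enumerate(order)}
    out = np.zeros((len(order), len(order)))

    def fill(node: TreeNode) -> None:
        kids = node.children
        for x in range(len(kids)):
            for y in range(x + 1, len(kids)):
                for na, da in leaf_depth[id(kids[x])].items():
                    for nb, db in leaf_depth[id(kids[y])].items():
                        dist = da + kids[x].length + db + kids[y].length
                        ia, ib = index[na], index[nb]
                        out[ia, ib] = out[ib, ia] = dist
        for child in kids:
            fill(child)

    fill(tree.root)
    return DistanceTable(order, out)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = set(" \t()[]{}:;,'\"")


def _newick_label(name: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode, with_length: bool) -> str:
    if node.is_leaf:
        body = _newick_label(node.name)
    else:
        body = "(" + ",".join(_newick_node(c, True) for c in node.children) + ")"
    if with_length:
        body += f":{node.length:.6f}"
    return body


def format_newick(tree: OrderedTree) -> str:
    """Standard Newick string with 6-decimal branch lengths."""
    return _newick_node(tree.root, with_length=False) + ";"


def write_newick(tree: OrderedTree, path) -> Path:
    path = Path(path)
    path.write_text(format_newick(tree) + "\n")
    return path
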