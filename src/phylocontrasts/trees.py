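"""Rooted binary phylogenies with branch lengths.

The container used throughout the package is :class:`Phylogeny`, an
array-backed rooted tree in which node ids are assigned by postorder
position.  Postorder ids make per-branch outputs reproducible across runs:
every non-root node owns the branch to its parent, so "branch i" always
means the branch above node i.

Newick and NEXUS parsing is delegated to dendropy; the resulting tree is
validated against the invariants every downstream method assumes (fully
resolved, strictly positive finite branch lengths).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NodeDepthOrder",
    "TreeError",
    "read_tree",
    "path_distance",
    "depth_order",
    "to_newick",
]


class TreeError(ValueError):
    """Raised when a tree violates the package's structural invariants."""


@dataclass(frozen=True)
class NodeDepthOrder:
    """Node ids sorted by root-to-node path distance (time units)."""

    nodes: np.ndarray   # int ids, depth-ascending, ties broken by id
    depths: np.ndarray  # matching root-to-node distances

    def __len__(self) -> int:
        return len(self.nodes)


class Phylogeny:
    """Rooted, fully resolved tree with strictly positive branch lengths.

    Parameters
    ----------
    parent
        ``parent[i]`` is the id of node ``i``'s parent, ``-1`` for the root.
        Ids must be postorder: every child id is smaller than its parent's,
        and the root is the last node.
    lengths
        ``lengths[i]`` is the length of the branch above node ``i`` (time
        units); the root entry is ignored and stored as NaN.
    labels
        Tip labels; ``labels[i]`` is ``None`` for internal nodes.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.intp)
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.labels = list(labels)
        n_nodes = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n_nodes):
            raise TreeError("parent, lengths and labels must have equal length")

        children: list[list[int]] = [[] for _ in range(n_nodes)]
        roots = []
        for i, p in enumerate(self.parent):
            if p == -1:
                roots.append(i)
            else:
                if not 0 <= p < n_nodes:
                    raise TreeError(f"node {i}: parent id {p} out of range")
                if p <= i:
                    raise TreeError(
                        f"node {i}: ids are not postorder (parent {p} <= child)"
                    )
                children[p].append(i)
        if len(roots) != 1 or roots[0] != n_nodes - 1:
            raise TreeError("tree must have exactly one root, with the last id")
        self.root = roots[0]
        self.children = children
        self.lengths[self.root] = np.nan

        self.is_tip = np.array([not c for c in children], dtype=bool)
        for i in range(n_nodes):
            if self.is_tip[i]:
                if self.labels[i] is None:
                    raise TreeError(f"tip {i} has no label")
            elif len(children[i]) != 2:
                raise TreeError(
                    f"node {i} ({self.labels[i] or 'internal'}) has "
                    f"{len(children[i])} children; tree must be fully resolved"
                )
        non_root = np.arange(n_nodes) != self.root
        bad = non_root & ~(np.isfinite(self.lengths) & (self.lengths > 0))
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise TreeError(
                f"branch above node {j} ({self.labels[j] or 'internal'}) has "
                f"non-positive or missing length {self.lengths[j]!r}"
            )
        if len(set(lab for lab in self.labels if lab is not None)) != int(
            self.is_tip.sum()
        ):
            raise TreeError("duplicate tip labels")

        # root-to-node path distances, computed once
        self.depths = np.zeros(n_nodes)
        for i in range(n_nodes - 2, -1, -1):  # preorder = reversed postorder
            self.depths[i] = self.depths[self.parent[i]] + self.lengths[i]
        self._tip_dist: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tips(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.flatnonzero(~self.is_tip)

    @property
    def branches(self) -> np.ndarray:
        """Ids of branch-owning nodes (every node except the root)."""
        return np.flatnonzero(np.arange(self.n_nodes) != self.root)

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def node_of_label(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no tip labelled {label!r}") from None

    # -- distances ---------------------------------------------------------
    def _check_node(self, node: int) -> int:
        node = int(node)
        if not 0 <= node < self.n_nodes:
            raise KeyError(f"unknown node id {node}")
        return node

    def lca(self, u: int, v: int) -> int:
        u, v = self._check_node(u), self._check_node(v)
        while u != v:  # postorder ids increase toward the root
            if u < v:
                u = int(self.parent[u])
            else:
                v = int(self.parent[v])
        return u

    def path_distance(self, u: int, v: int) -> float:
        """Sum of branch lengths on the unique path between two nodes."""
        a = self.lca(u, v)
        return float(self.depths[u] + self.depths[v] - 2.0 * self.depths[a])

    def tip_path_distances(self) -> np.ndarray:
        """(n_nodes, n_tips) matrix of node-to-tip path distances, cached."""
        if self._tip_dist is None:
            tips = self.tips
            d = np.empty((self.n_nodes, len(tips)))
            for j, t in enumerate(tips):
                # walk the root path of tip t once; all other nodes hang off it
                anc_depth = {}
                u = int(t)
                while u != -1:
                    anc_depth[u] = self.depths[u]
                    u = int(self.parent[u])
                for v in range(self.n_nodes):
                    u = v
                    while u not in anc_depth:
                        u = int(self.parent[u])
                    d[v, j] = self.depths[v] + self.depths[t] - 2 * anc_depth[u]
            self._tip_dist = d
        return self._tip_dist


def read_tree(text: str) -> Phylogeny:
    """Parse a Newick or NEXUS tree string into a validated :class:`Phylogeny`.

    NEXUS TRANSLATE blocks are honoured; only the first tree in a file is
    used.  Tip labels are preserved verbatim.  Raises :class:`TreeError` on
    parse failure, polytomies, or missing/zero/negative branch lengths,
    naming the offending node.
    """
    stripped = text.lstrip()
    schema = "nexus" if stripped.lower().startswith("#nexus") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"could not parse {schema} input: {exc}") from exc
    return _from_dendropy(dtree)


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    dnodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    parent, lengths, labels = [], [], []
    for nd in dnodes:
        if nd.parent_node is None:
            parent.append(-1)
            lengths.append(np.nan)
        else:
            parent.append(index[id(nd.parent_node)])
            lengths.append(np.nan if nd.edge.length is None else nd.edge.length)
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            labels.append(lab)
        else:
            labels.append(None)
    return Phylogeny(parent, lengths, labels)


def path_distance(tree: Phylogeny, from_node: int, to_node: int) -> float:
    """Module-level alias of :meth:`Phylogeny.path_distance`."""
    return tree.path_distance(from_node, to_node)


def depth_order(tree: Phylogeny) -> NodeDepthOrder:
    """All node ids ordered by distance from the root (ties by id)."""
    order = np.lexsort((np.arange(tree.n_nodes), tree.depths))
    return NodeDepthOrder(nodes=order, depths=tree.depths[order])


def to_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialize back to Newick with branch lengths."""
    buf = io.StringIO()

    def write(node: int) -> None:
        if tree.is_tip[node]:
            buf.write(tree.labels[node])
        else:
            buf.write("(")
            c1, c2 = tree.children[node]
            write(c1)
            buf.write(",")
            write(c2)
            buf.write(")")
        if node != tree.root:
            buf.write(f":{tree.lengths[node]:.{precision}g}")

    write(tree.root)
    buf.write(";")
    return buf.getvalue()
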