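"""Unrooted edge-weighted phylogenies.

Trees are stored in a rooted array representation (the root is an arbitrary
internal node; for an unrooted binary tree it is a trifurcation), which is
what the pruning likelihood wants.  All comparisons between trees
(bipartitions, Robinson--Foulds, branch scores) treat them as unrooted.

Tip nodes are numbered ``0 .. n_tips-1`` in alphabetical order of their
names; edges are identified by their child node and ordered by child node
id, so an edge-length vector has a fixed, documented layout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Tree", "read_newick", "write_newick"]


class Tree:
    """An edge-weighted unrooted binary phylogeny over named tips.

    Parameters
    ----------
    taxa : sequence of str
        Tip names; stored sorted.  Tips are nodes ``0..n_tips-1``.
    parent : array of int
        Parent node id per node (``-1`` for the root).
    lengths : array of float
        Length of the edge above each node (ignored for the root).

    For ``N`` tips an unrooted binary tree has ``2N-3`` edges; the root is
    a trifurcation, so there are ``2N-2`` nodes.
    """

    def __init__(self, taxa: Sequence[str], parent: Sequence[int],
                 lengths: Sequence[float]):
        self.taxa = tuple(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate tip names")
        if list(self.taxa) != sorted(self.taxa):
            raise ValueError("taxa must be given in sorted order")
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.n_tips = len(self.taxa)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        if np.any(self.lengths[self._edge_nodes()] < 0):
            raise ValueError("edge lengths must be non-negative")
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        # post-order traversal (children before parents)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = order[::-1]

    # ------------------------------------------------------------------ #

    def _edge_nodes(self) -> np.ndarray:
        return np.array([v for v in range(self.n_nodes) if self.parent[v] >= 0])

    @property
    def edge_nodes(self) -> np.ndarray:
        """Child node of each edge, in canonical (node-id) order."""
        return self._edge_nodes()

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def edge_lengths(self) -> np.ndarray:
        """Edge lengths in canonical edge order (see :attr:`edge_nodes`)."""
        return self.lengths[self.edge_nodes].copy()

    def with_edge_lengths(self, lengths: Sequence[float]) -> "Tree":
        """Return a copy with edge lengths replaced (canonical order)."""
        lengths = np.asarray(lengths, dtype=float)
        nodes = self.edge_nodes
        if lengths.shape != (len(nodes),):
            raise ValueError(f"expected {len(nodes)} edge lengths")
        new = self.lengths.copy()
        new[nodes] = lengths
        return Tree(self.taxa, self.parent, new)

    # -- bipartitions --------------------------------------------------- #

    def _tipsets(self) -> dict[int, frozenset[str]]:
        below: dict[int, set[str]] = {v: set() for v in range(self.n_nodes)}
        for v in self.postorder:
            if v < self.n_tips:
                below[v].add(self.taxa[v])
            for c in self.children[v]:
                below[v] |= below[c]
        return {v: frozenset(below[v]) for v in range(self.n_nodes)}

    def bipartitions(self) -> dict[frozenset[str], float]:
        """Map each edge's bipartition to its length.

        A bipartition is represented by the side **not** containing the
        alphabetically first taxon, so the representation is rooting
        independent.  Tip edges are included (their bipartitions are the
        singleton tip sets).
        """
        ref = self.taxa[0]
        all_taxa = frozenset(self.taxa)
        out: dict[frozenset[str], float] = {}
        tipsets = self._tipsets()
        for v in self.edge_nodes:
            side = tipsets[v]
            if ref in side:
                side = all_taxa - side
            out[side] = out.get(side, 0.0) + float(self.lengths[v])
        return out

    def splits(self, nontrivial_only: bool = True) -> set[frozenset[str]]:
        """The set of bipartitions; topology identity ignores edge lengths."""
        s = set(self.bipartitions())
        if nontrivial_only:
            s = {b for b in s if 1 < len(b) < self.n_tips - 1}
        return s

    def same_topology(self, other: "Tree") -> bool:
        if set(self.taxa) != set(other.taxa):
            raise ValueError("tip sets differ")
        return self.splits() == other.splits()

    def rf_distance(self, other: "Tree") -> int:
        """Unrooted Robinson--Foulds distance (symmetric split difference)."""
        if set(self.taxa) != set(other.taxa):
            raise ValueError("tip sets differ")
        return len(self.splits() ^ other.splits())

    # -- rerooting ------------------------------------------------------ #

    def _adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {v: [] for v in range(self.n_nodes)}
        for v in self.edge_nodes:
            p = int(self.parent[v])
            w = float(self.lengths[v])
            adj[v].append((p, w))
            adj[p].append((v, w))
        return adj

    def reroot(self, node: int) -> "Tree":
        """Reroot at an internal node; the unrooted tree is unchanged."""
        if node < self.n_tips:
            raise ValueError("cannot root at a tip")
        adj = self._adjacency()
        parent = np.full(self.n_nodes, -2, dtype=int)
        lengths = np.zeros(self.n_nodes)
        parent[node] = -1
        stack = [node]
        while stack:
            v = stack.pop()
            for u, w in adj[v]:
                if parent[u] == -2:
                    parent[u] = v
                    lengths[u] = w
                    stack.append(u)
        return Tree(self.taxa, parent, lengths)

    # -- newick --------------------------------------------------------- #

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string (branch lengths required on all edges)."""
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      preserve_underscores=True)
        except Exception as e:
            raise ValueError(f"malformed Newick string: {e}") from e
        seed = dtree.seed_node
        # collapse a bifurcating root so the tree is genuinely unrooted
        if len(seed.child_nodes()) == 2 and not all(
                c.is_leaf() for c in seed.child_nodes()):
            a, b = seed.child_nodes()
            keep, drop = (a, b) if not a.is_leaf() else (b, a)
            la = a.edge.length or 0.0
            lb = b.edge.length or 0.0
            seed.remove_child(keep)
            for ch in list(keep.child_nodes()):
                keep.remove_child(ch)
                seed.add_child(ch)
            drop.edge.length = la + lb
        names = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip names in Newick string")
        taxa = sorted(names)
        index = {name: i for i, name in enumerate(taxa)}
        n_tips = len(taxa)
        ids: dict[int, int] = {}
        next_internal = n_tips
        for nd in dtree.preorder_node_iter():
            if nd.is_leaf():
                ids[id(nd)] = index[nd.taxon.label]
            else:
                ids[id(nd)] = next_internal
                next_internal += 1
        n_nodes = next_internal
        parent = np.full(n_nodes, -1, dtype=int)
        lengths = np.zeros(n_nodes)
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is not None:
                v = ids[id(nd)]
                parent[v] = ids[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError("branch lengths are required")
                lengths[v] = float(nd.edge.length)
        return cls(taxa, parent, lengths)

    def newick(self) -> str:
        """Serialise to Newick with 12-significant-digit branch lengths."""

        def render(v: int) -> str:
            if v < self.n_tips:
                return self.taxa[v]
            inner = ",".join(f"{render(c)}:{self.lengths[c]:.12g}"
                             for c in self.children[v])
            return f"({inner})"

        return render(self.root) + ";"

    # ------------------------------------------------------------------ #

    @classmethod
    def from_adjacency(cls, taxa: Sequence[str],
                       edges: Iterable[tuple[object, object, float]]) -> "Tree":
        """Build a tree from an undirected edge list.

        ``edges`` holds ``(u, v, length)`` triples; tip nodes are named by
        their taxon string, internal nodes by any other hashable label.
        The root is chosen as an internal node of degree >= 3.
        """
        taxa = sorted(taxa)
        index: dict[object, int] = {t: i for i, t in enumerate(taxa)}
        adj: dict[object, list[tuple[object, float]]] = {}
        for u, v, w in edges:
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        internal = [u for u in adj if u not in index]
        for u in internal:
            index[u] = len(index)
        n_nodes = len(index)
        root_label = max(internal, key=lambda u: len(adj[u]), default=None)
        if root_label is None:
            raise ValueError("no internal node")
        parent = np.full(n_nodes, -2, dtype=int)
        lengths = np.zeros(n_nodes)
        parent[index[root_label]] = -1
        stack = [root_label]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if parent[index[v]] == -2:
                    parent[index[v]] = index[u]
                    lengths[index[v]] = w
                    stack.append(v)
        return cls(taxa, parent, lengths)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_tips} tips, {self.n_edges} edges)"


def read_newick(text: str) -> Tree:
    """Parse a Newick string with branch lengths into a :class:`Tree`."""
    return Tree.from_newick(text)


def write_newick(tree: Tree) -> str:
    """Serialise a :class:`Tree` to a Newick string."""
    return tree.newick()
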