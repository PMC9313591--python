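"""Array-backed rooted phylogeny used by the trait simulator and shift detector.

The tree is stored as flat parent/branch-length arrays (tips first), which keeps
the Ornstein-Uhlenbeck linear algebra vectorised.  Newick parsing and writing is
delegated to dendropy; :class:`Phylogeny` is a thin numeric view, not a general
tree-manipulation API.

Edges are identified by their child node: edge ``e`` runs from ``parent[e]`` to
node ``e``.  The root has no edge.
"""

from __future__ import annotations

from functools import cached_property

import dendropy
import numpy as np

from .exceptions import InputError


class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels.

    Parameters
    ----------
    parent : (n_nodes,) int array, ``parent[root] == -1``.
    length : (n_nodes,) float array of branch lengths (``length[root]`` ignored, 0).
    tip_labels : sequence of str; tips are nodes ``0 .. n_tips-1``.
    """

    def __init__(self, parent, length, tip_labels):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.tip_labels = list(tip_labels)
        n_nodes = self.parent.size
        if self.length.size != n_nodes:
            raise InputError("parent and length arrays disagree in size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise InputError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise InputError("tip labels must be unique")
        self.n_tips = len(self.tip_labels)
        self.n_nodes = n_nodes
        if np.any(self.length[np.arange(n_nodes) != self.root] < 0):
            raise InputError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        for node in range(n_nodes):
            if node != self.root:
                self.children[self.parent[node]].append(node)
        for tip in range(self.n_tips):
            if self.children[tip]:
                raise InputError(f"node {tip} is labelled as a tip but has children")

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        leaves = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        order = leaves + internals
        index = {id(nd): i for i, nd in enumerate(order)}
        parent = np.full(len(order), -1, dtype=int)
        length = np.zeros(len(order))
        labels = [nd.taxon.label if nd.taxon else f"t{i}" for i, nd in enumerate(leaves)]
        for nd in order:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(parent, length, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        parts = self._newick_node(self.root)
        return parts + ";"

    def _newick_node(self, node: int) -> str:
        if node < self.n_tips:
            core = self.tip_labels[node]
        else:
            core = "(" + ",".join(self._newick_node(c) for c in self.children[node]) + ")"
        if node == self.root:
            return core
        return f"{core}:{self.length[node]:.12g}"

    # ----------------------------------------------------------- structure

    @cached_property
    def preorder(self) -> np.ndarray:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return np.array(order, dtype=int)

    @cached_property
    def postorder(self) -> np.ndarray:
        return self.preorder[::-1].copy()

    @cached_property
    def depths(self) -> np.ndarray:
        """Root-to-node distances (root at depth 0)."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder:
            if node != self.root:
                d[node] = d[self.parent[node]] + self.length[node]
        return d

    @property
    def tip_depths(self) -> np.ndarray:
        return self.depths[: self.n_tips]

    @property
    def height(self) -> float:
        return float(self.tip_depths.max())

    @property
    def edges(self) -> np.ndarray:
        """Edge ids = every node except the root."""
        return np.array([n for n in range(self.n_nodes) if n != self.root], dtype=int)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @cached_property
    def ancestor_matrix(self) -> np.ndarray:
        """Boolean (n_tips, n_nodes): A[i, e] iff edge e lies on the root->tip-i path.

        A node is on its own path, the root is on none (it has no edge).
        """
        A = np.zeros((self.n_tips, self.n_nodes), dtype=bool)
        for tip in range(self.n_tips):
            node = tip
            while node != self.root:
                A[tip, node] = True
                node = self.parent[node]
        return A

    @cached_property
    def tip_sets(self) -> list[frozenset]:
        """Per-node frozenset of descendant tip indices (incl. self for tips)."""
        sets: list[frozenset] = [frozenset()] * self.n_nodes
        for node in self.postorder:
            if node < self.n_tips:
                sets[node] = frozenset([node])
            else:
                acc: set = set()
                for c in self.children[node]:
                    acc |= sets[c]
                sets[node] = frozenset(acc)
        return sets

    @cached_property
    def mrca_depths(self) -> np.ndarray:
        """(n_tips, n_tips) depth of the MRCA of each tip pair."""
        n = self.n_tips
        M = np.zeros((n, n))
        np.fill_diagonal(M, self.tip_depths)
        for node in self.postorder:
            if node < self.n_tips:
                continue
            kids = self.children[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.fromiter(self.tip_sets[kids[a]], dtype=int)
                    ib = np.fromiter(self.tip_sets[kids[b]], dtype=int)
                    M[np.ix_(ia, ib)] = self.depths[node]
                    M[np.ix_(ib, ia)] = self.depths[node]
        return M

    @cached_property
    def patristic_gap(self) -> np.ndarray:
        """D[i, j] = T_i + T_j - 2 * depth(mrca(i, j)); zero diagonal."""
        T = self.tip_depths
        return T[:, None] + T[None, :] - 2.0 * self.mrca_depths

    def edge_label(self, edge: int) -> str:
        """Human-readable edge name: tip label, or mrca(<first>,<last>) for clades."""
        if edge < self.n_tips:
            return self.tip_labels[edge]
        tips = sorted(self.tip_sets[edge])
        return f"mrca({self.tip_labels[tips[0]]},{self.tip_labels[tips[-1]]})"

    def tip_index(self, labels) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.tip_labels)}
        try:
            return np.array([lookup[l] for l in labels], dtype=int)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise InputError(f"tip label {exc.args[0]!r} not in tree") from exc
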