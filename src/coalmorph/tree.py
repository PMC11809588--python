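"""Rooted phylogenetic trees as flat parent-pointer arrays.

The container is deliberately minimal: every node is an integer, the edge
above node ``i`` has length ``lengths[i]``, and leaves carry taxon labels.
This makes the hot loops (coalescent simulation, pruning likelihoods,
placement) cheap, while dendropy is used at the Newick/NEXUS boundary.
Trees are treated as immutable; topology edits return new objects.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import dendropy

LENGTH_UNITS = ("subst_per_site", "coalescent_units", "Ma", "none")

__all__ = ["PhyloTree", "LENGTH_UNITS", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class PhyloTree:
    """A rooted tree with optional non-negative branch lengths.

    Parameters
    ----------
    parent
        Integer array, ``parent[i]`` is the parent node of ``i``; the root
        has parent ``-1``.  Any node order is accepted.
    lengths
        Branch length of the edge above each node (ignored at the root), or
        ``None`` when the tree carries no lengths.  ``nan`` marks an absent
        length on an otherwise measured tree.
    labels
        Per-node taxon labels; leaves must be labelled and unique, internal
        nodes may be ``None``.
    length_unit
        One of ``subst_per_site``, ``coalescent_units``, ``Ma``, ``none``.
    """

    __slots__ = ("parent", "lengths", "labels", "length_unit", "rooted", "_cache")

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float] | None,
        labels: Sequence[str | None],
        length_unit: str = "none",
        rooted: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        n = self.parent.shape[0]
        if len(labels) != n:
            raise TreeError("labels length does not match number of nodes")
        self.labels = list(labels)
        if lengths is None:
            self.lengths = None
        else:
            self.lengths = np.asarray(lengths, dtype=float).copy()
            if self.lengths.shape[0] != n:
                raise TreeError("lengths length does not match number of nodes")
            finite = np.isfinite(self.lengths)
            if np.any(self.lengths[finite] < 0):
                raise TreeError("negative branch length")
        if length_unit not in LENGTH_UNITS:
            raise TreeError(f"unknown length unit {length_unit!r}")
        self.length_unit = length_unit
        self.rooted = rooted
        self._cache: dict = {}
        if np.count_nonzero(self.parent == -1) != 1:
            raise TreeError("tree must have exactly one root")
        seen: set[str] = set()
        for i in self.leaves():
            lab = self.labels[i]
            if lab is None:
                raise TreeError(f"leaf node {i} has no label")
            if lab in seen:
                raise TreeError(f"duplicate leaf label {lab!r}")
            seen.add(lab)

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        if "children" not in self._cache:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._cache["children"] = ch
        return self._cache["children"]

    def is_leaf(self, i: int) -> bool:
        return not self.children()[i]

    def leaves(self) -> np.ndarray:
        if "leaves" not in self._cache:
            ch = self.children()
            self._cache["leaves"] = np.array(
                [i for i in range(self.n_nodes) if not ch[i]], dtype=np.int64
            )
        return self._cache["leaves"]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves()]

    def leaf_index(self, label: str) -> int:
        if "by_label" not in self._cache:
            self._cache["by_label"] = {
                self.labels[i]: int(i) for i in self.leaves()
            }
        try:
            return self._cache["by_label"][label]
        except KeyError:
            raise TreeError(f"no leaf labelled {label!r}") from None

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        if "postorder" not in self._cache:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children()[node])
            self._cache["postorder"] = np.array(order[::-1], dtype=np.int64)
        return self._cache["postorder"]

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def internal_edges(self) -> list[int]:
        """Child-node ids of edges whose child is an internal, non-root node."""
        ch = self.children()
        return [
            i
            for i in range(self.n_nodes)
            if ch[i] and self.parent[i] >= 0
        ]

    def edges(self) -> list[int]:
        """All edges, identified by their child node."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    # ------------------------------------------------------------------
    # lengths
    # ------------------------------------------------------------------
    @property
    def has_lengths(self) -> bool:
        return self.lengths is not None

    def _require_lengths(self) -> np.ndarray:
        if self.lengths is None:
            raise TreeError("tree has no branch lengths")
        return self.lengths

    def total_length(self) -> float:
        L = self._require_lengths()
        mask = self.parent >= 0
        vals = L[mask]
        if np.any(~np.isfinite(vals)):
            raise TreeError("tree has missing branch lengths")
        return float(vals.sum())

    def depths(self) -> np.ndarray:
        """Distance from the root to every node (root depth 0)."""
        L = self._require_lengths()
        d = np.zeros(self.n_nodes)
        for i in self.preorder():
            p = self.parent[i]
            if p >= 0:
                d[i] = d[p] + L[i]
        return d

    def node_heights(self) -> np.ndarray:
        """Height of each node above the deepest leaf under it."""
        L = self._require_lengths()
        h = np.zeros(self.n_nodes)
        for i in self.postorder():
            for c in self.children()[i]:
                h[i] = max(h[i], h[c] + L[c])
        return h

    def mrca(self, i: int, j: int) -> int:
        anc = set()
        a = i
        while a >= 0:
            anc.add(a)
            a = int(self.parent[a])
        a = j
        while a not in anc:
            a = int(self.parent[a])
        return a

    def patristic_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf labels and the symmetric leaf-to-leaf path-length matrix."""
        d = self.depths()
        lv = self.leaves()
        n = len(lv)
        out = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                m = self.mrca(int(lv[a]), int(lv[b]))
                out[a, b] = out[b, a] = d[lv[a]] + d[lv[b]] - 2 * d[m]
        return [self.labels[i] for i in lv], out

    def clade_leafset(self, node: int) -> frozenset:
        """Labels of the leaves under ``node``."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.append(self.labels[n])
            else:
                stack.extend(self.children()[n])
        return frozenset(out)

    def edge_with_clade(self, leafset: frozenset) -> int | None:
        """The edge (child id) whose child clade is exactly ``leafset``."""
        for e in self.edges():
            if self.clade_leafset(e) == leafset:
                return e
        return None

    def edges_adjacent(self, edge_child: int) -> set[int]:
        """Edges sharing an endpoint with the edge above ``edge_child``."""
        p = int(self.parent[edge_child])
        if p < 0:
            raise TreeError("the root has no edge")
        out = set(self.children()[edge_child])
        out.update(c for c in self.children()[p] if c != edge_child)
        if self.parent[p] >= 0:
            out.add(p)
        return out

    # ------------------------------------------------------------------
    # edits (return new trees)
    # ------------------------------------------------------------------
    def with_lengths(self, lengths: np.ndarray, length_unit: str | None = None) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(),
            lengths,
            list(self.labels),
            length_unit or self.length_unit,
            self.rooted,
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(),
            None if self.lengths is None else self.lengths.copy(),
            list(self.labels),
            self.length_unit,
            self.rooted,
        )

    def attach_leaf(
        self,
        edge_child: int,
        label: str,
        pendant_length: float,
        split_fraction: float = 0.5,
    ) -> "PhyloTree":
        """Attach a new labelled leaf onto the edge above ``edge_child``.

        The edge is split at ``split_fraction`` of its length (measured from
        the child end going rootward); the new leaf hangs from the split
        point with branch ``pendant_length``.
        """
        if self.parent[edge_child] < 0:
            raise TreeError("cannot attach on the root edge")
        L = self._require_lengths()
        n = self.n_nodes
        new_parent = np.concatenate([self.parent, [0, 0]])
        new_len = np.concatenate([L, [0.0, 0.0]])
        mid, leaf = n, n + 1
        old_parent = self.parent[edge_child]
        elen = L[edge_child]
        new_parent[mid] = old_parent
        new_parent[edge_child] = mid
        new_parent[leaf] = mid
        new_len[mid] = elen * (1.0 - split_fraction)
        new_len[edge_child] = elen * split_fraction
        new_len[leaf] = pendant_length
        return PhyloTree(
            new_parent,
            new_len,
            list(self.labels) + [None, label],
            self.length_unit,
            self.rooted,
        )

    def drop_leaf(self, label: str) -> "PhyloTree":
        """Remove a leaf, suppressing the unary node it leaves behind."""
        i = self.leaf_index(label)
        keep = np.ones(self.n_nodes, dtype=bool)
        keep[i] = False
        parent = self.parent.copy()
        lengths = None if self.lengths is None else self.lengths.copy()
        p = int(parent[i])
        if p >= 0:
            sibs = [c for c in self.children()[p] if c != i]
            if len(sibs) == 1:
                # suppress unary parent
                keep[p] = False
                gp = int(parent[p])
                parent[sibs[0]] = gp
                if lengths is not None and gp >= 0:
                    lengths[sibs[0]] = lengths[sibs[0]] + lengths[p]
        idx = np.cumsum(keep) - 1
        new_parent = [
            -1 if parent[j] < 0 or not keep[parent[j]] else int(idx[parent[j]])
            for j in range(self.n_nodes)
            if keep[j]
        ]
        new_lengths = None if lengths is None else lengths[keep]
        new_labels = [self.labels[j] for j in range(self.n_nodes) if keep[j]]
        return PhyloTree(new_parent, new_lengths, new_labels, self.length_unit, self.rooted)

    # ------------------------------------------------------------------
    # conversion
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(
        cls, tree: dendropy.Tree, length_unit: str = "none", rooted: bool | None = None
    ) -> "PhyloTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        labels: list[str | None] = [None] * len(nodes)
        any_len = any(
            nd.edge.length is not None for nd in nodes if nd.parent_node is not None
        )
        lengths = np.full(len(nodes), np.nan) if any_len else None
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if lengths is not None and nd.edge.length is not None:
                    lengths[i] = nd.edge.length
            if nd.taxon is not None:
                labels[i] = nd.taxon.label.replace(" ", "_")
            elif nd.is_leaf():
                raise TreeError("leaf without taxon label")
        if rooted is None:
            rooted = tree.is_rooted if tree.is_rooted is not None else True
        return cls(parent, lengths, labels, length_unit=length_unit, rooted=bool(rooted))

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        dnodes = {self.root: tree.seed_node}
        for i in self.preorder():
            i = int(i)
            if i == self.root:
                nd = tree.seed_node
            else:
                nd = dendropy.Node()
                dnodes[int(self.parent[i])].add_child(nd)
                dnodes[i] = nd
                if self.lengths is not None and np.isfinite(self.lengths[i]):
                    nd.edge.length = float(self.lengths[i])
            if self.is_leaf(i):
                nd.taxon = tns.require_taxon(label=self.labels[i])
        tree.is_rooted = self.rooted
        return tree

    def newick(self) -> str:
        tree = self.to_dendropy()
        return tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, s: str, length_unit: str = "none") -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=s, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree, length_unit=length_unit)

    @classmethod
    def from_tskit(cls, ts_tree, pop_labels: Sequence[str], length_unit: str = "coalescent_units") -> "PhyloTree":
        """Convert a (fully coalesced, single-root) tskit tree.

        ``pop_labels[k]`` is the taxon label of sample node ``k``.
        """
        used = [u for u in ts_tree.nodes()]
        used.sort()
        index = {u: i for i, u in enumerate(used)}
        parent = np.full(len(used), -1, dtype=np.int64)
        lengths = np.full(len(used), np.nan)
        labels: list[str | None] = [None] * len(used)
        time = ts_tree.tree_sequence.nodes_time
        for u in used:
            p = ts_tree.parent(u)
            if p != -1:
                parent[index[u]] = index[p]
                lengths[index[u]] = time[p] - time[u]
            if u < len(pop_labels):
                labels[index[u]] = pop_labels[u]
        return cls(parent, lengths, labels, length_unit=length_unit, rooted=True)

    # ------------------------------------------------------------------
    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhyloTree(n_leaves={self.n_leaves}, n_nodes={self.n_nodes}, "
            f"unit={self.length_unit!r})"
        )
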