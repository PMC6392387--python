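"""Rooted, binary, ultrametric timetrees with node ages in Ma.

The topology is fixed throughout an analysis (divergence-time estimation on
a previously inferred tree), so the container is array-based for fast
traversal: tips are indexed ``0..n_tips-1`` in taxon order, internal nodes
``n_tips..2*n_tips-2`` in postorder, with the root last.  All ages are in
million years before present; extant tips sit at age 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["TimeTree", "TreeError"]

#: tolerance (Myr) for the ultrametricity check on parsed trees
ULTRAMETRIC_TOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed trees (polytomies, unrooted input, bad ages)."""


@dataclass
class TimeTree:
    """A rooted binary ultrametric tree with node ages.

    Attributes
    ----------
    taxa:
        Tip labels; tip ``i`` carries ``taxa[i]``.
    parent:
        ``parent[v]`` is the parent index of node ``v``; ``-1`` at the root.
    children:
        ``(n_internal, 2)`` child indices; row ``j`` belongs to internal
        node ``n_tips + j``.
    ages:
        Node ages in Ma, tips at 0, root strictly oldest.
    """

    taxa: list[str]
    parent: np.ndarray
    children: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.children = np.asarray(self.children, dtype=np.int64)
        self.ages = np.asarray(self.ages, dtype=np.float64)
        if len(set(self.taxa)) != len(self.taxa):
            raise TreeError("duplicate taxon labels")
        if self.children.shape != (self.n_tips - 1, 2):
            raise TreeError("tree is not binary")
        self.validate_ages(self.ages)

    # -- basic geometry ----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def postorder_internal(self) -> np.ndarray:
        """Internal node indices, children-before-parents (root last)."""
        return np.arange(self.n_tips, self.n_nodes, dtype=np.int64)

    @property
    def internal_labels(self) -> list[str]:
        """Stable labels for internal nodes, usable across runs on the
        same fixed topology."""
        return [f"node{v}" for v in range(self.n_tips, self.n_nodes)]

    def children_of(self, v: int) -> tuple[int, int]:
        c = self.children[v - self.n_tips]
        return int(c[0]), int(c[1])

    def branch_durations(self, ages: np.ndarray | None = None) -> np.ndarray:
        """Per-node parent-edge durations in Myr (root entry = 0)."""
        a = self.ages if ages is None else ages
        if not hasattr(self, "_parent_or_self"):
            ps = self.parent.copy()
            ps[self.root] = self.root
            self._parent_or_self = ps
        return a[self._parent_or_self] - a

    def validate_ages(self, ages: np.ndarray) -> None:
        if np.any(np.abs(ages[: self.n_tips]) > ULTRAMETRIC_TOL):
            raise TreeError("extant tips must sit at age 0")
        for v in self.postorder_internal:
            c0, c1 = self.children_of(int(v))
            if ages[v] <= max(ages[c0], ages[c1]):
                raise TreeError(
                    f"node {v} (age {ages[v]:g}) not older than its children"
                )

    # -- clade utilities ---------------------------------------------------

    def clade_tips(self) -> list[frozenset[int]]:
        """Tip-index set below every node (tips map to singletons)."""
        sets: list[frozenset[int]] = [frozenset((i,)) for i in range(self.n_tips)]
        for v in self.postorder_internal:
            c0, c1 = self.children_of(int(v))
            sets.append(sets[c0] | sets[c1])
        return sets

    def mrca(self, taxa: set[str] | list[str]) -> int:
        """Most recent common ancestor of a set of tip labels."""
        want = set(taxa)
        unknown = want - set(self.taxa)
        if unknown:
            raise TreeError(f"unknown taxa: {sorted(unknown)}")
        if len(want) < 2:
            raise TreeError("MRCA requires at least two taxa")
        idx = frozenset(self.taxa.index(t) for t in want)
        for v, tips in enumerate(self.clade_tips()):
            if idx <= tips:
                return v
        raise TreeError("unreachable: root covers all tips")  # pragma: no cover

    def with_ages(self, ages: np.ndarray) -> "TimeTree":
        return TimeTree(self.taxa, self.parent, self.children, np.array(ages))

    # -- interchange with dendropy ----------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        dtree = dtree.clone(depth=1)
        seed = dtree.seed_node
        for nd in dtree.preorder_node_iter():
            nch = len(nd.child_nodes())
            if nch not in (0, 2):
                raise TreeError(
                    f"tree must be rooted and binary; node with {nch} children"
                    " found (polytomy or unrooted input)"
                )
        dtree.calc_node_root_distances(return_leaf_distances_only=False)
        height = max(lf.root_distance for lf in dtree.leaf_node_iter())
        taxa: list[str] = []
        index: dict[int, int] = {}
        for lf in dtree.leaf_node_iter():
            index[id(lf)] = len(taxa)
            taxa.append(lf.taxon.label if lf.taxon else str(len(taxa)))
        n_tips = len(taxa)
        parent = np.full(2 * n_tips - 1, -1, dtype=np.int64)
        children = np.zeros((n_tips - 1, 2), dtype=np.int64)
        ages = np.zeros(2 * n_tips - 1)
        nxt = n_tips
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                ages[index[id(nd)]] = height - nd.root_distance
                continue
            index[id(nd)] = nxt
            c0, c1 = nd.child_nodes()
            children[nxt - n_tips] = (index[id(c0)], index[id(c1)])
            parent[index[id(c0)]] = nxt
            parent[index[id(c1)]] = nxt
            ages[nxt] = height - nd.root_distance
            nxt += 1
        if id(seed) in index and index[id(seed)] != 2 * n_tips - 2:
            # postorder of dendropy always visits seed last; guard anyway
            raise TreeError("root is not last in postorder")  # pragma: no cover
        tips_off = np.abs(ages[:n_tips])
        if tips_off.max() > ULTRAMETRIC_TOL:
            raise TreeError(
                f"tree is not ultrametric: tip depths differ by up to "
                f"{tips_off.max():g} Myr (tolerance {ULTRAMETRIC_TOL:g})"
            )
        ages[:n_tips] = 0.0
        return cls(taxa, parent, children, ages)

    def to_dendropy(self, ages: np.ndarray | None = None) -> dendropy.Tree:
        a = self.ages if ages is None else ages
        ns = dendropy.TaxonNamespace(self.taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, t in enumerate(self.taxa):
            nodes[i].taxon = ns.get_taxon(t)
        for v in self.postorder_internal:
            c0, c1 = self.children_of(int(v))
            for c in (c0, c1):
                nodes[c].edge.length = float(a[v] - a[c])
                nodes[v].add_child(nodes[c])
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True
        return tree

    def to_newick(self, ages: np.ndarray | None = None) -> str:
        s = self.to_dendropy(ages).as_string(schema="newick", suppress_rooting=True)
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dtree)
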