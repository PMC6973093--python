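"""Rooted, branch-length-bearing phylogenies.

A :class:`Phylogeny` is a flat-array view of a rooted tree: nodes are numbered
in preorder with the root at index 0, each non-root node owns the branch above
it, and branch lengths are in the time units of the input tree (e.g. Myr).
This layout keeps the per-branch rate-scalar machinery simple: branch ``i``
is node ``i`` for every ``i >= 1``.

Newick parsing and writing are delegated to dendropy; this module adds the
validation the downstream analyses require (unique tip labels, branch lengths
present and non-negative) and the array bookkeeping they rely on.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "read_newick",
    "parse_newick",
    "write_newick",
]


def normalize_label(label: str) -> str:
    """Canonical species-label form: whitespace to underscores, case folded."""
    return "_".join(str(label).strip().split()).casefold()


class Phylogeny:
    """A rooted tree with branch lengths, stored as preorder arrays.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the node index of ``i``'s parent; ``parent[0] == -1``
        (the root). Children must have larger indices than their parent
        (preorder numbering).
    lengths : array of float
        ``lengths[i]`` is the length of the branch above node ``i`` in time
        units. ``lengths[0]`` (the root edge) is retained but ignored by all
        analyses.
    labels : sequence of str or None
        Tip labels; internal nodes may be None. Tip labels must be unique.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        labels: Sequence[str | None],
    ):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        self._validate()
        self._build_derived()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        n = self.parent.shape[0]
        if not (n == self.lengths.shape[0] == len(self.labels)):
            raise ValueError("parent, lengths and labels must have equal size")
        if n < 1 or self.parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if np.any(self.parent[1:] < 0) or np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be numbered in preorder (parent index < child index)")
        if np.any(~np.isfinite(self.lengths[1:])):
            raise ValueError("all branch lengths must be finite; a branch length is missing or NaN")
        if np.any(self.lengths[1:] < 0):
            bad = np.nonzero(self.lengths[1:] < 0)[0] + 1
            raise ValueError(f"negative branch lengths are not allowed (nodes {bad.tolist()})")

    def _build_derived(self) -> None:
        n = self.n_nodes
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            children[self.parent[i]].append(i)
        self.children = children
        self.tip_ids = np.array([i for i in range(n) if not children[i]], dtype=np.intp)
        tip_labels = [self.labels[i] for i in self.tip_ids]
        if any(lab is None for lab in tip_labels):
            raise ValueError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self.tip_labels = tip_labels
        self._tip_index = {lab: k for k, lab in enumerate(tip_labels)}
        self._node_of_label = {lab: int(i) for i, lab in zip(self.tip_ids, tip_labels)}
        # postorder: reverse preorder works because parents precede children
        self.postorder = np.arange(n - 1, -1, -1, dtype=np.intp)
        term = self.lengths[self.tip_ids] == 0
        if np.any(term) and self.n_tips > 1:
            zlabs = [tip_labels[k] for k in np.nonzero(term)[0]]
            warnings.warn(
                "zero-length terminal branches (zero variance / zero path-wise "
                f"rate contribution): {zlabs}",
                stacklevel=3,
            )

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.intp)
        lengths = np.zeros(n, dtype=float)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    who = nd.taxon.label if nd.taxon else f"internal node {i}"
                    raise ValueError(f"missing branch length above {who!r}; branch lengths are required")
                lengths[i] = nd.edge.length
            else:
                lengths[i] = nd.edge.length or 0.0
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.is_leaf():
                raise ValueError("unlabelled tip in tree")
        return cls(parent, lengths, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        tree.seed_node = dnodes[0]
        for i in range(self.n_nodes):
            if i > 0:
                dnodes[self.parent[i]].add_child(dnodes[i])
            dnodes[i].edge.length = float(self.lengths[i])
            if self.labels[i] is not None:
                dnodes[i].taxon = taxa.new_taxon(self.labels[i])
        return tree

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_tips(self) -> int:
        return self.tip_ids.shape[0]

    @property
    def n_branches(self) -> int:
        """Number of true branches (every node except the root)."""
        return self.n_nodes - 1

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node.

        Includes the root edge (usually zero): pruning can fold a shared
        stem into the root edge, and path lengths must survive that.
        """
        depth = np.zeros(self.n_nodes)
        depth[0] = self.lengths[0]
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.lengths[i]
        return depth

    def tip_depths(self) -> dict[str, float]:
        d = self.node_depths()
        return {lab: float(d[i]) for i, lab in zip(self.tip_ids, self.tip_labels)}

    def clade_nodes(self, node: int) -> np.ndarray:
        """All nodes in the subtree rooted at ``node`` (inclusive), preorder."""
        out = [node]
        stack = list(self.children[node])
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return np.array(sorted(out), dtype=np.intp)

    def clade_tip_indices(self, node: int) -> np.ndarray:
        """Positions (in ``tip_labels`` order) of the tips under ``node``."""
        sub = set(self.clade_nodes(node).tolist())
        return np.array(
            [k for k, i in enumerate(self.tip_ids) if int(i) in sub], dtype=np.intp
        )

    def tip_membership(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: tip k descends from (or is) node i."""
        m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        for k, i in enumerate(self.tip_ids):
            m[i, k] = True
        for i in self.postorder:
            if i > 0:
                m[self.parent[i]] |= m[i]
        return m

    def mrca(self, labels: Iterable[str]) -> int:
        """Most recent common ancestor node of the named tips."""
        want = list(labels)
        ids = []
        for lab in want:
            if lab not in self._node_of_label:
                raise KeyError(f"unknown tip label: {lab!r}")
            ids.append(self._node_of_label[lab])
        paths = []
        for i in ids:
            p = []
            while i != -1:
                p.append(i)
                i = int(self.parent[i]) if i != 0 else -1
            paths.append(set(p))
        common = set.intersection(*paths)
        # preorder numbering: ancestors precede descendants, so the deepest
        # common ancestor is the one with the largest index
        return max(common)

    def path_to_root(self, node: int) -> list[int]:
        out = []
        i = node
        while i != 0:
            out.append(i)
            i = int(self.parent[i])
        return out

    def branch_tip_sets(self) -> list[np.ndarray]:
        """For each node i >= 1, the tip positions under the branch above i."""
        m = self.tip_membership()
        return [np.nonzero(m[i])[0] for i in range(self.n_nodes)]

    # -- editing -----------------------------------------------------------

    def with_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        """New tree with the same topology but different branch lengths."""
        return Phylogeny(self.parent.copy(), np.asarray(lengths, float), list(self.labels))

    def scaled_by(self, factors: np.ndarray) -> "Phylogeny":
        """Multiply each branch length by a per-node factor (root factor ignored)."""
        factors = np.asarray(factors, float)
        if factors.shape[0] == self.n_branches:
            factors = np.concatenate([[1.0], factors])
        new = self.lengths * factors
        new[0] = self.lengths[0]
        return self.with_lengths(new)

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Restrict to the named tips, collapsing degree-2 nodes (lengths summed)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if not keep:
            raise ValueError("cannot prune to an empty tip set")
        if keep == set(self.tip_labels):
            return self
        dtree = self.to_dendropy()
        sub = dtree.extract_tree_with_taxa_labels(keep)
        return Phylogeny.from_dendropy(sub)

    # -- IO ----------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if self.is_tip(i):
                core = _quote(self.labels[i])
            else:
                core = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            return f"{core}:{self.lengths[i]:.17g}"

        return rec(0) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny: {self.n_tips} tips, {self.n_nodes - self.n_tips} internal nodes>"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _mrca_by_depth(tree: Phylogeny, labels: Iterable[str]) -> int:
    """MRCA via explicit root-paths; robust regardless of index conventions."""
    paths = []
    for lab in labels:
        node = tree._node_of_label[lab]
        chain = []
        i = node
        while True:
            chain.append(i)
            if i == 0:
                break
            i = int(tree.parent[i])
        paths.append(chain)
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # the MRCA is the common ancestor furthest from the root
    first = paths[0]
    for i in first:
        if i in common:
            return i
    return 0


# In preorder numbering an ancestor always has a smaller index than its
# descendants, so among common ancestors the max index is the deepest: the
# simple implementation in Phylogeny.mrca is correct. Keep the path-based
# version around as the brute-force oracle for tests.
Phylogeny.mrca_brute = _mrca_by_depth  # type: ignore[attr-defined]


def parse_newick(data: str) -> Phylogeny:
    """Parse a newick string (branch lengths required, unique tip labels)."""
    try:
        dtree = dendropy.Tree.get(data=data, schema="newick")
    except Exception as exc:  # dendropy reports line/column in its message
        raise ValueError(f"malformed newick: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def read_newick(path) -> Phylogeny:
    """Read a rooted newick tree with branch lengths from ``path``."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize ``tree`` to newick; optionally write to ``path``."""
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s
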