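"""Rooted phylogenies with branch lengths in substitutions/site.

The :class:`Phylogeny` container is an array-backed rooted tree used by every
other module.  Newick reading/writing is delegated to :mod:`dendropy`; on
ingestion the tree is validated (single root, unique tip labels, branch
lengths present and non-negative) and polytomies are resolved into
zero-length bifurcations with an order stable under tip labels, so that
downstream contrast computations are reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeError", "parse_tree", "write_tree", "nstd"]


class TreeError(ValueError):
    """Raised for malformed or invalid input trees."""


@dataclass
class Phylogeny:
    """Array-backed rooted bifurcating phylogeny.

    Nodes are integers ``0..n_nodes-1``; ``parent[root] == -1``.  ``lengths``
    holds the length of the branch above each node (0 for the root).  Tips
    carry unique labels; internal nodes may be unlabeled.
    """

    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]]
    labels: list[str | None]
    root: int
    postorder: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.postorder is None:
            self.postorder = self._compute_postorder()
        self._label_to_id = {
            lab: i for i, lab in enumerate(self.labels) if lab is not None and not self.children[i]
        }
        self._tip_ids = np.array(
            [i for i in range(len(self.parent)) if not self.children[i]], dtype=int)

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> np.ndarray:
        return self._tip_ids

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def tip_id(self, label: str) -> int:
        try:
            return self._label_to_id[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.array(order[::-1], dtype=int)

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            children=[list(c) for c in self.children],
            labels=list(self.labels),
            root=self.root,
            postorder=self.postorder.copy(),
        )

    # -------------------------------------------------------------- distances
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:
            if node != self.root:
                d[node] = d[self.parent[node]] + self.lengths[node]
        return d

    def tip_distance_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """All pairwise patristic distances between tips.

        Returns ``(tip_ids, D)`` with ``D[i, j]`` the distance between
        ``tip_ids[i]`` and ``tip_ids[j]``.  Computed by a single postorder
        sweep: tips first meeting at node *v* are at distance
        ``depth_i + depth_j - 2 depth_v``.
        """
        tips = self.tip_ids
        pos = {int(t): k for k, t in enumerate(tips)}
        depth = self.depths()
        n = len(tips)
        D = np.zeros((n, n))
        below: dict[int, np.ndarray] = {}
        for node in self.postorder:
            if self.is_tip(node):
                below[node] = np.array([pos[node]], dtype=int)
                continue
            sets = [below.pop(c) for c in self.children[node]]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    ia, ib = sets[a], sets[b]
                    d = depth[tips[ia]][:, None] + depth[tips[ib]][None, :] - 2.0 * depth[node]
                    D[np.ix_(ia, ib)] = d
                    D[np.ix_(ib, ia)] = d.T
            below[node] = np.concatenate(sets)
        return tips, D

    def patristic_distance(self, label_a: str, label_b: str) -> float:
        a, b = self.tip_id(label_a), self.tip_id(label_b)
        depth = self.depths()
        # walk to common ancestor
        anc_a = set()
        x = a
        while x != -1:
            anc_a.add(x)
            x = int(self.parent[x])
        x = b
        while x not in anc_a:
            x = int(self.parent[x])
        mrca = x
        return float(depth[a] + depth[b] - 2.0 * depth[mrca])

    # ---------------------------------------------------------------- newick
    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if self.is_tip(node):
                body = _quote(self.labels[node])
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
                if self.labels[node]:
                    body += _quote(self.labels[node])
            if node == self.root:
                return body
            return f"{body}:{self.lengths[node]:.12g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return fmt(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, newick_text: str, require_lengths: bool = True) -> "Phylogeny":
        return parse_tree(newick_text, require_lengths=require_lengths)


def _quote(label: str | None) -> str:
    if label is None:
        return ""
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_tree(newick_text: str, require_lengths: bool = True) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Branch lengths are required on every non-root edge (``require_lengths``);
    duplicate tip labels are an error.  Polytomies are resolved into
    zero-length bifurcations, deterministically ordered by the smallest tip
    label in each child subtree.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc

    seen: set[str] = set()
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("unlabeled tip in newick input")
        if leaf.taxon.label in seen:
            raise TreeError(f"duplicate tip label: {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    if len(seen) < 2:
        raise TreeError("tree must have at least 2 tips")

    # collect nodes, validate lengths
    droot = dtree.seed_node
    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    labels: list[str | None] = [None] * n
    for nd in dnodes:
        i = index[id(nd)]
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
        if nd is droot:
            continue
        parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is None:
            if require_lengths:
                raise TreeError(
                    f"missing branch length on edge above "
                    f"{labels[i] or 'internal node ' + str(i)}"
                )
            lengths[i] = 0.0
        else:
            if nd.edge.length < 0:
                raise TreeError("negative branch length")
            lengths[i] = float(nd.edge.length)
        children[parent[i]].append(i)

    tree = Phylogeny(parent=parent, lengths=lengths, children=children, labels=labels,
                     root=index[id(droot)])
    return resolve_polytomies(tree)


def write_tree(tree: Phylogeny) -> str:
    return tree.to_newick()


def resolve_polytomies(tree: Phylogeny) -> Phylogeny:
    """Resolve polytomies into zero-length bifurcations (label-stable order)."""
    if all(len(c) in (0, 2) for c in tree.children):
        return tree

    # smallest descendant tip label per node, for deterministic ordering
    min_label: list[str] = [""] * tree.n_nodes
    for node in tree.postorder:
        if tree.is_tip(node):
            min_label[node] = tree.labels[node]
        else:
            min_label[node] = min(min_label[c] for c in tree.children[node])

    parent = list(tree.parent)
    lengths = list(tree.lengths)
    children = [sorted(c, key=lambda x: min_label[x]) for c in tree.children]
    labels = list(tree.labels)

    for node in range(tree.n_nodes):
        while len(children[node]) > 2:
            # fold the two label-smallest children under a new zero-length node
            a = children[node].pop(0)
            b = children[node].pop(0)
            new = len(parent)
            parent.append(node)
            lengths.append(0.0)
            labels.append(None)
            children.append([a, b])
            parent[a] = new
            parent[b] = new
            children[node].insert(0, new)

    return Phylogeny(
        parent=np.array(parent, dtype=int),
        lengths=np.array(lengths, dtype=float),
        children=children,
        labels=labels,
        root=tree.root,
    )


def induced_subtree(tree: Phylogeny, tip_labels) -> Phylogeny:
    """Subtree induced by a set of tips: other tips removed, unifurcations
    suppressed (branch lengths summed), rooted at the MRCA of the set."""
    keep_tips = {tree.tip_id(lab) for lab in tip_labels}
    if len(keep_tips) < 2:
        raise TreeError("induced subtree needs at least 2 tips")

    n_below = np.zeros(tree.n_nodes, dtype=int)
    for node in tree.postorder:
        if tree.is_tip(node):
            n_below[node] = int(node in keep_tips)
        else:
            n_below[node] = sum(n_below[c] for c in tree.children[node])
    total = n_below[tree.root]
    # MRCA: deepest node containing all kept tips
    mrca = tree.root
    while True:
        nxt = [c for c in tree.children[mrca] if n_below[c] == total]
        if not nxt:
            break
        mrca = nxt[0]

    parent: list[int] = []
    lengths: list[float] = []
    children: list[list[int]] = []
    labels: list[str | None] = []

    def build(node: int, extra_len: float, new_parent: int) -> int:
        kept = [c for c in tree.children[node] if n_below[c] > 0]
        if not tree.is_tip(node) and len(kept) == 1:
            # unifurcation: pass through, accumulating length
            return build(kept[0], extra_len + tree.lengths[kept[0]], new_parent)
        idx = len(parent)
        parent.append(new_parent)
        lengths.append(extra_len)
        children.append([])
        labels.append(tree.labels[node])
        if new_parent >= 0:
            children[new_parent].append(idx)
        for c in kept:
            build(c, tree.lengths[c], idx)
        return idx

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        root = build(mrca, 0.0, -1)
    finally:
        sys.setrecursionlimit(old)
    return Phylogeny(
        parent=np.array(parent, dtype=int),
        lengths=np.array(lengths, dtype=float),
        children=children,
        labels=labels,
        root=root,
    )


def nstd(tree: Phylogeny, query_tip: str, reference_tips: list[str] | set[str]) -> float:
    """Nearest-sequenced-taxon distance: minimum patristic distance from
    *query_tip* to any tip in *reference_tips* (0 if the query is itself a
    reference)."""
    refs = list(reference_tips)
    if not refs:
        raise ValueError("empty reference set")
    if query_tip in set(refs):
        return 0.0
    tips, D = tree.tip_distance_matrix()
    pos = {tree.labels[t]: k for k, t in enumerate(tips)}
    q = pos[query_tip]
    idx = [pos[r] for r in refs]
    return float(np.min(D[q, idx]))
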