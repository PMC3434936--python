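"""Area trees: the phylogeny-like object whose tips are floristic areas.

``AreaTree`` wraps a :class:`dendropy.Tree`; dendropy supplies Newick
parsing/serialisation, rerooting, bipartition encoding and Robinson--Foulds
distances. The numeric engines (likelihood, parsimony, mapping) work on a
flattened array representation (:class:`FlatTree`) built from an
``AreaTree`` with a fixed tip order.

Branch lengths are in expected state changes per character. An absent
length is *unset* (``None`` in dendropy, ``nan`` in the flat arrays), never
silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


class RootingTieError(TreeError):
    """Two or more areas tie for the fewest species occurrences."""

    def __init__(self, tied: list[str]):
        self.tied = list(tied)
        super().__init__(
            "Lundberg rooting is ambiguous: areas tied for minimum occurrence: "
            + ", ".join(sorted(tied))
            + "; pick one explicitly"
        )


class AreaTree:
    """Rooted or unrooted tree over areas, with optional branch lengths and
    per-node support percentages (0-100)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_names
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for e in tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise TreeError(f"negative branch length {e.length}")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "AreaTree":
        try:
            t = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls(t)

    def copy(self) -> "AreaTree":
        return AreaTree(self._tree.clone(depth=1))

    # -- basic accessors ------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def has_branch_lengths(self) -> bool:
        return all(
            e.length is not None
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
        )

    def newick(self, *, include_supports: bool = True) -> str:
        t = self._tree
        s = t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_internal_node_labels=not include_supports,
        )
        return s.strip()

    def __str__(self) -> str:
        return self.newick()

    # -- rooting --------------------------------------------------------
    def is_rooted_binary(self) -> bool:
        return len(self._tree.seed_node.child_nodes()) == 2

    def reroot_on_tip(self, tip_name: str) -> "AreaTree":
        """Root on the terminal branch of ``tip_name``, at its midpoint
        (or with unset lengths if the branch has none)."""
        out = self._tree.clone(depth=1)
        leaf = None
        for lf in out.leaf_node_iter():
            if lf.taxon.label == tip_name:
                leaf = lf
                break
        if leaf is None:
            raise TreeError(f"no tip named {tip_name!r}")
        edge = leaf.edge
        if edge.length is None:
            out.reroot_at_edge(edge, update_bipartitions=False)
        else:
            half = edge.length / 2.0
            out.reroot_at_edge(
                edge, length1=half, length2=half, update_bipartitions=False
            )
        out.is_rooted = True
        return AreaTree(out)

    def deroot(self) -> "AreaTree":
        out = self._tree.clone(depth=1)
        out.deroot()
        out.is_rooted = False
        return AreaTree(out)

    def prune_tips(self, names: list[str]) -> "AreaTree":
        out = self._tree.clone(depth=1)
        taxa = [t for t in out.taxon_namespace if t.label in set(names)]
        out.prune_taxa(taxa, suppress_unifurcations=True)
        return AreaTree(out)

    # -- bipartitions ---------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each as the smaller-side tip
        set (ties broken lexicographically)."""
        tips = set(self.tip_names)
        out: set[frozenset[str]] = set()
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            below = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            above = frozenset(tips - below)
            if len(below) < 2 or len(above) < 2:
                continue
            out.add(_canonical_side(below, above))
        return out

    def has_clade(self, tip_set: set[str]) -> bool:
        """True if ``tip_set`` is one side of some bipartition (or a trivial
        split) of the unrooted topology."""
        tips = set(self.tip_names)
        want = _canonical_side(frozenset(tip_set), frozenset(tips - tip_set))
        if len(tip_set) in (1, len(tips) - 1):
            return True
        return want in self.bipartitions()


def _canonical_side(a: frozenset[str], b: frozenset[str]) -> frozenset[str]:
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    return min(a, b, key=lambda s: tuple(sorted(s)))


# ---------------------------------------------------------------------------
# rooting conventions


def lundberg_root(tree: AreaTree, matrix) -> AreaTree:
    """Root the tree a posteriori on the area with the fewest species
    presences (the hypothetical ancestral area).

    A tie for the minimum row sum is an error: the caller must pick one of
    the tied areas and call :meth:`AreaTree.reroot_on_tip` directly.
    """
    sums = matrix.row_sums()
    tips = set(tree.tip_names)
    missing = tips - set(sums)
    if missing:
        raise TreeError(f"tree tips not in matrix: {sorted(missing)}")
    relevant = {a: s for a, s in sums.items() if a in tips}
    smallest = min(relevant.values())
    tied = [a for a, s in relevant.items() if s == smallest]
    if len(tied) > 1:
        raise RootingTieError(tied)
    return tree.reroot_on_tip(tied[0])


# ---------------------------------------------------------------------------
# consensus and comparison


def majority_consensus(trees: list[AreaTree], threshold: float = 0.5) -> AreaTree:
    """Majority-rule consensus; retained bipartitions are annotated with
    their percentage frequency (0-100) as internal node labels."""
    if not trees:
        raise TreeError("no trees to summarise")
    if not 0.5 <= threshold <= 1.0:
        raise TreeError("threshold must be in [0.5, 1]")
    tip_sets = {frozenset(t.tip_names) for t in trees}
    if len(tip_sets) != 1:
        raise TreeError("trees have mismatched tip sets")

    ns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=ns)
    for t in trees:
        tl.append(
            dendropy.Tree.get(
                data=t.newick(include_supports=False),
                schema="newick",
                taxon_namespace=ns,
                preserve_underscores=True,
            )
        )
    cons = tl.consensus(min_freq=threshold)
    cons.is_rooted = False
    # annotate supports by explicit bipartition counting (robust across
    # dendropy versions)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    result = AreaTree(cons)
    n = len(trees)
    tips = set(result.tip_names)
    for node in cons.preorder_node_iter():
        if node.is_leaf() or node is cons.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _canonical_side(below, frozenset(tips - below))
        freq = 100.0 * counts.get(key, 0) / n
        node.label = f"{freq:g}"
    return result


def rf_distance(t1: AreaTree, t2: AreaTree, unrooted: bool = True) -> int:
    """Robinson--Foulds symmetric-difference distance (count of
    bipartitions present in exactly one tree)."""
    if set(t1.tip_names) != set(t2.tip_names):
        raise TreeError("mismatched tip sets")
    if not unrooted:
        # rooted comparison: compare clade sets
        c1 = _clades(t1)
        c2 = _clades(t2)
        return len(c1 ^ c2)
    b1 = t1.bipartitions()
    b2 = t2.bipartitions()
    return len(b1 ^ b2)


def _clades(tree: AreaTree) -> set[frozenset[str]]:
    out = set()
    t = tree.dendropy_tree
    for node in t.preorder_node_iter():
        if node.is_leaf() or node is t.seed_node:
            continue
        out.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


# ---------------------------------------------------------------------------
# flat array representation used by the numeric engines


@dataclass
class FlatTree:
    """Array form of a rooted binary tree.

    Nodes ``0..n_tips-1`` are the tips, in ``tip_names`` order; internal
    nodes follow in postorder with the root last. ``parent[root] == -1``;
    ``lengths[i]`` is the branch above node ``i`` (``nan`` when unset).
    """

    tip_names: list[str]
    parent: np.ndarray          # (n_nodes,) int
    children: list[list[int]]   # per node
    lengths: np.ndarray         # (n_nodes,) float, nan = unset
    postorder: np.ndarray       # (n_nodes,) int, root last

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def tips_below(self, node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)


def flatten(tree: AreaTree, tip_order: list[str] | None = None) -> FlatTree:
    """Build the array representation of a (possibly multifurcating) tree.

    ``tip_order`` fixes the tip index assignment so matrix rows line up; it
    defaults to the tree's own tip order.
    """
    d = tree.dendropy_tree
    leaves = list(d.leaf_node_iter())
    if tip_order is None:
        tip_order = [lf.taxon.label for lf in leaves]
    index = {name: i for i, name in enumerate(tip_order)}
    if set(index) != {lf.taxon.label for lf in leaves}:
        raise TreeError("tip_order does not match the tree's tips")
    n_tips = len(leaves)

    node_ids: dict[int, int] = {}
    next_internal = n_tips
    post: list[int] = []
    for node in d.postorder_node_iter():
        if node.is_leaf():
            nid = index[node.taxon.label]
        else:
            nid = next_internal
            next_internal += 1
        node_ids[id(node)] = nid
        post.append(nid)

    n_nodes = next_internal
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lengths = np.full(n_nodes, np.nan)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for node in d.postorder_node_iter():
        nid = node_ids[id(node)]
        if node.parent_node is not None:
            pid = node_ids[id(node.parent_node)]
            parent[nid] = pid
            children[pid].append(nid)
        if node.edge.length is not None:
            lengths[nid] = node.edge.length
    return FlatTree(list(tip_order), parent, children, lengths,
                    np.array(post, dtype=np.int64))


def unflatten(flat: FlatTree, *, include_lengths: bool = True) -> AreaTree:
    """Inverse of :func:`flatten` (up to branch-length formatting)."""

    def render(node: int) -> str:
        if node < flat.n_tips:
            core = flat.tip_names[node]
        else:
            core = "(" + ",".join(render(c) for c in flat.children[node]) + ")"
        ln = flat.lengths[node]
        if include_lengths and np.isfinite(ln):
            return f"{core}:{ln:.10g}"
        return core

    return AreaTree.from_newick(render(flat.root) + ";")
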