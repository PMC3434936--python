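"""Fitch parsimony on binary characters: tree length, per-character step
decomposition, ensemble consistency/retention indices, and most-parsimonious
ancestral state sets.

Characters are unordered and unweighted. All arithmetic is done on state
*sets* encoded as 2-bit masks (state 0 -> 0b01, state 1 -> 0b10), vectorised
across characters with numpy. Constant characters cost zero steps, which is
the keystone contrast with the likelihood engine: appending all-zero columns
never changes a parsimony tree length but always changes a likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import TaxonAreaMatrix
from .trees import AreaTree, FlatTree, TreeError, flatten


class PolytomyError(TreeError):
    """Fitch length is defined here only for resolved (binary) trees."""


def as_rooted_binary(flat: FlatTree) -> FlatTree:
    """Return an equivalent strictly binary rooted tree.

    A root with three children is the conventional unrooted representation
    and is rebalanced by grouping two of them under a zero-length node; any
    other multifurcation raises :class:`PolytomyError`.
    """
    for node in range(flat.n_tips, flat.n_nodes):
        k = len(flat.children[node])
        if node != flat.root and k != 2:
            raise PolytomyError(
                "tree contains a polytomy; resolve it before scoring"
            )
    rk = len(flat.children[flat.root])
    if rk == 2:
        return flat
    if rk != 3:
        raise PolytomyError(
            "tree contains a polytomy; resolve it before scoring"
        )
    a, b, c = flat.children[flat.root]
    n = flat.n_nodes
    parent = np.append(flat.parent, flat.root)
    lengths = np.append(flat.lengths, 0.0)
    children = [list(ch) for ch in flat.children] + [[b, c]]
    parent[b] = n
    parent[c] = n
    children[flat.root] = [a, n]
    post = [x for x in flat.postorder.tolist() if x != flat.root]
    # insert the new node after both of its children, before the root
    post = post + [n, flat.root]
    return FlatTree(flat.tip_names, parent, children, lengths,
                    np.array(post, dtype=np.int64))


def canonical_flat(flat: FlatTree) -> FlatTree:
    """Canonical rooted-binary representation of an unrooted topology.

    The root is placed on the terminal branch of tip 0 and children are
    ordered by their smallest descendant tip, so every representation of
    the same unrooted tree maps to an identical structure. Branch lengths
    are discarded (the canonical form seeds fresh optimisation); the
    numeric optimisers use this so their output cannot depend on how the
    caller happened to root or rotate the input tree.
    """
    n = flat.n_tips
    if n < 2:
        raise TreeError("need at least 2 tips")
    adj: dict[int, set[int]] = {v: set() for v in range(flat.n_nodes)}
    for v in range(flat.n_nodes):
        p = flat.parent[v]
        if p >= 0:
            adj[v].add(int(p))
            adj[int(p)].add(v)
    # splice every internal node of degree 2 (the rooted representation's
    # root, and any unifurcation left over from pruning); drop internal
    # nodes of degree <= 1
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if v < n:
                continue
            deg = len(adj[v])
            if deg == 2:
                a, b = sorted(adj[v])
                adj[a].discard(v)
                adj[b].discard(v)
                adj[a].add(b)
                adj[b].add(a)
                del adj[v]
                changed = True
            elif deg <= 1:
                for w in adj[v]:
                    adj[w].discard(v)
                del adj[v]
                changed = True

    def build(v: int, parent: int):
        kids = [w for w in adj[v] if w != parent]
        if not kids:
            return v, v
        subs = sorted((build(w, v) for w in kids), key=lambda s: s[0])
        if len(subs) != 2:
            raise PolytomyError(
                "tree contains a polytomy; resolve it before scoring"
            )
        return subs[0][0], (subs[0][1], subs[1][1])

    if n == 2:
        core = 1
    else:
        u = next(iter(adj[0]))
        _, core = build(u, 0)

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(2 * n - 1)]
    post: list[int] = []
    counter = [n]

    def emit(node) -> int:
        if isinstance(node, tuple):
            kids = [emit(k) for k in node]
            nid = counter[0]
            counter[0] += 1
            for k in kids:
                parent[k] = nid
                children[nid].append(k)
            post.append(nid)
            return nid
        post.append(int(node))
        return int(node)

    root_kids = [emit(0), emit(core)]
    root = counter[0]
    for k in root_kids:
        parent[k] = root
        children[root].append(k)
    post.append(root)
    lengths = np.full(2 * n - 1, np.nan)
    return FlatTree(list(flat.tip_names), parent, children, lengths,
                    np.array(post, dtype=np.int64))


def _tip_masks(flat: FlatTree, cells: np.ndarray) -> np.ndarray:
    """(n_nodes, n_chars) uint8 state-set masks, tips filled in."""
    masks = np.zeros((flat.n_nodes, cells.shape[1]), dtype=np.uint8)
    masks[: flat.n_tips] = np.where(cells == 0, 1, 2).astype(np.uint8)
    return masks


def fitch_downpass(flat: FlatTree, cells: np.ndarray):
    """First (postorder) Fitch pass.

    Returns (state-set masks per node, per-character step counts).
    """
    masks = _tip_masks(flat, cells)
    steps = np.zeros(cells.shape[1], dtype=np.int64)
    for node in flat.postorder:
        if node < flat.n_tips:
            continue
        a, b = flat.children[node]
        inter = masks[a] & masks[b]
        union = masks[a] | masks[b]
        empty = inter == 0
        steps += empty
        masks[node] = np.where(empty, union, inter)
    return masks, steps


def fitch_uppass(flat: FlatTree, down: np.ndarray) -> np.ndarray:
    """Second (preorder) pass: per-node sets of states occurring in at
    least one most-parsimonious reconstruction (Swofford & Maddison's MPR
    rule, vectorised across characters)."""
    final = down.copy()
    for node in flat.preorder():
        if node == flat.root or node < flat.n_tips:
            continue
        p = flat.parent[node]
        fp = final[p]
        dv = down[node]
        a, b = flat.children[node]
        inter_children = down[a] & down[b]
        subset = (fp & dv) == fp          # F(p) contained in D(v)
        was_intersection = inter_children != 0
        opt1 = fp
        opt2 = dv | (fp & (down[a] | down[b]))
        opt3 = dv | fp
        final[node] = np.where(
            subset, opt1, np.where(was_intersection, opt2, opt3)
        ).astype(np.uint8)
    return final


@dataclass
class ParsimonyScore:
    """Tree length and homoplasy indices for one tree/matrix pair."""

    length: int
    per_character_steps: np.ndarray    # s_i
    min_steps: np.ndarray              # m_i = 1 if variable else 0
    max_steps: np.ndarray              # g_i = rarer-state tip count
    ci: float
    ri: float
    ci_informative_only: float
    ri_informative_only: float
    warnings: list[str]


def ci_ri(
    steps: np.ndarray, min_steps: np.ndarray, max_steps: np.ndarray
) -> tuple[float, float, list[str]]:
    """Ensemble consistency index sum(m)/S and retention index
    (sum(g) - S) / (sum(g) - sum(m)); the degenerate cases (no homoplasy
    possible) report 1.0 with a warning."""
    warnings: list[str] = []
    S = int(steps.sum())
    sm = int(min_steps.sum())
    sg = int(max_steps.sum())
    if S == 0:
        warnings.append("tree length 0: CI undefined, reported as 1.0")
        ci = 1.0
    else:
        ci = sm / S
    if sg == sm:
        warnings.append("max steps equal min steps: RI undefined, reported as 1.0")
        ri = 1.0
    else:
        ri = (sg - S) / (sg - sm)
    return ci, ri, warnings


def fitch_length(tree: AreaTree, matrix: TaxonAreaMatrix) -> ParsimonyScore:
    """Fitch tree length with per-character decomposition and CI/RI under
    both character-inclusion conventions (all variable characters, and
    parsimony-informative characters only)."""
    tips = set(tree.tip_names)
    if tips != set(matrix.area_names):
        raise TreeError("tree tips do not match matrix areas")
    flat = as_rooted_binary(flatten(tree, tip_order=matrix.area_names))
    return fitch_length_flat(flat, matrix.cells)


def fitch_length_flat(flat: FlatTree, cells: np.ndarray) -> ParsimonyScore:
    _, steps = fitch_downpass(flat, cells)
    n1 = cells.sum(axis=0)
    n0 = cells.shape[0] - n1
    gmax = np.minimum(n0, n1).astype(np.int64)
    mmin = (gmax > 0).astype(np.int64)
    ci, ri, warn = ci_ri(steps, mmin, gmax)
    informative = gmax >= 2
    ci_i, ri_i, _ = ci_ri(steps[informative], mmin[informative], gmax[informative])
    return ParsimonyScore(
        length=int(steps.sum()),
        per_character_steps=steps,
        min_steps=mmin,
        max_steps=gmax,
        ci=ci, ri=ri,
        ci_informative_only=ci_i, ri_informative_only=ri_i,
        warnings=warn,
    )


def fitch_steps(flat: FlatTree, cells: np.ndarray,
                weights: np.ndarray | None = None) -> int:
    """Weighted total tree length (fast path for the heuristic search,
    ``cells`` may be compressed patterns with ``weights`` counts)."""
    _, steps = fitch_downpass(flat, cells)
    if weights is None:
        return int(steps.sum())
    return int((steps * weights).sum())


def edge_change_counts(flat: FlatTree, cells: np.ndarray,
                       weights: np.ndarray | None = None) -> np.ndarray:
    """Per-branch change counts of one most-parsimonious reconstruction
    (accelerated-transformation flavoured: a child keeps the parent's state
    whenever its down-pass set allows it). Used to seed branch lengths."""
    down, _ = fitch_downpass(flat, cells)
    nchar = cells.shape[1]
    w = np.ones(nchar) if weights is None else weights
    state = np.zeros((flat.n_nodes, nchar), dtype=np.uint8)
    changes = np.zeros(flat.n_nodes)
    root = flat.root
    # prefer state 0 at the root when ambiguous (arbitrary, deterministic)
    state[root] = np.where(down[root] & 1, 1, 2)
    for node in flat.preorder():
        if node == root:
            continue
        p = state[flat.parent[node]]
        keep = (down[node] & p) != 0
        chosen = np.where(keep, p, np.where(down[node] & 1, 1, 2))
        state[node] = chosen.astype(np.uint8)
        changes[node] = (w * (chosen != p)).sum()
    return changes


def mp_ancestral_state_sets(
    tree: AreaTree, column: np.ndarray, tip_order: list[str]
) -> dict[int, set[int]]:
    """States at each node occurring in at least one most-parsimonious
    reconstruction of a single binary character.

    Returns a mapping from flat-tree node index (tips ``0..n_tips-1`` in
    ``tip_order``) to the MP state set.
    """
    flat = as_rooted_binary(flatten(tree, tip_order=tip_order))
    cells = np.asarray(column, dtype=np.int8).reshape(-1, 1)
    down, _ = fitch_downpass(flat, cells)
    final = fitch_uppass(flat, down)
    out: dict[int, set[int]] = {}
    for node in range(flat.n_nodes):
        mask = int(final[node, 0])
        out[node] = {s for s in (0, 1) if mask & (1 << s)}
    return out
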