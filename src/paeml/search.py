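"""Heuristic topology search (parsimony or likelihood objective) with
random-addition starting trees, NNI/SPR hill climbing, and the
nonparametric bootstrap over characters.

Search state is a compact rooted-binary topology (tips are matrix row
indices); the rooting is purely representational — both objectives are
rooting-invariant — and results are reported as unrooted topologies.
Likelihood candidates are scored after branch-length optimisation: fully
for small trees, and for larger trees via a parsimony-guided shortlist
(candidates are ranked by likelihood at parsimony-seeded branch lengths
and only the leaders are fully optimised), which keeps survey-scale
searches at 13-14 areas in the minutes range.

All randomness flows from ``SearchConfig.seed`` through one
``numpy.random.Generator``; identical configs give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import TaxonAreaMatrix
from .mk import LikelihoodResult, MkModel, compress_columns, fit as mk_fit, \
    initial_branch_lengths, optimize_on_topology, pattern_likelihoods
from .parsimony import fitch_steps
from .trees import AreaTree, FlatTree, majority_consensus, unflatten


@dataclass
class SearchConfig:
    objective: str = "parsimony"          # "parsimony" | "likelihood"
    n_starts: int = 20
    max_saved: int = 100
    swap: str = "spr"                     # "spr" | "nni"
    bootstrap_replicates: int = 100
    bootstrap_starts: int = 2
    seed: int = 0
    gamma: bool = False
    invariant: bool = False
    n_categories: int = 4
    # likelihood-search speed knobs: candidate topologies are scored with a
    # short coarse optimisation; only the final best tree gets the full fit
    ml_shortlist: int = 8                 # fully optimised candidates per pass
    ml_full_below: int = 7                # tip count under which all are full
    ml_search_tol: float = 1e-4
    ml_search_rounds: int = 4
    ml_search_xatol: float = 1e-4

    def __post_init__(self) -> None:
        if self.objective not in ("parsimony", "likelihood"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.swap not in ("spr", "nni"):
            raise ValueError(f"unknown swap {self.swap!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")


@dataclass
class SearchResult:
    trees: list[AreaTree]          # co-optimal topologies (likelihood: one)
    score: float                   # parsimony: length; likelihood: lnL
    objective: str
    n_optimal: int                 # size of the collected co-optimal set
    fit: LikelihoodResult | None = None


# ---------------------------------------------------------------------------
# compact mutable topology


class _Top:
    """Rooted binary topology over tip ids 0..n-1; internal ids >= n."""

    __slots__ = ("children", "parent", "root", "next_id", "n_tips")

    def __init__(self, n_tips: int):
        self.n_tips = n_tips
        self.children: dict[int, list[int]] = {}
        self.parent: dict[int, int] = {}
        self.root = -1
        self.next_id = n_tips

    def clone(self) -> "_Top":
        t = _Top(self.n_tips)
        t.children = {k: list(v) for k, v in self.children.items()}
        t.parent = dict(self.parent)
        t.root = self.root
        t.next_id = self.next_id
        return t

    @classmethod
    def triplet(cls, a: int, b: int, c: int, n_tips: int) -> "_Top":
        t = cls(n_tips)
        x = t._new()
        r = t._new()
        t.children[x] = [b, c]
        t.children[r] = [a, x]
        t.parent.update({a: r, x: r, b: x, c: x})
        t.root = r
        return t

    def _new(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def edge_nodes(self) -> list[int]:
        """Every node with a parent (= every rooted edge, child-labelled)."""
        return [v for v in self.parent]

    def insert_tip(self, tip: int, edge_child: int) -> None:
        """Attach ``tip`` in the middle of the branch above ``edge_child``."""
        p = self.parent[edge_child]
        m = self._new()
        self.children[m] = [edge_child, tip]
        ch = self.children[p]
        ch[ch.index(edge_child)] = m
        self.parent[m] = p
        self.parent[edge_child] = m
        self.parent[tip] = m

    def sibling(self, v: int) -> int:
        a, b = self.children[self.parent[v]]
        return b if a == v else a

    def swap(self, u: int, w: int) -> None:
        """Exchange two subtrees hanging from different parents."""
        pu, pw = self.parent[u], self.parent[w]
        cu, cw = self.children[pu], self.children[pw]
        cu[cu.index(u)] = w
        cw[cw.index(w)] = u
        self.parent[u], self.parent[w] = pw, pu

    def subtree_nodes(self, v: int) -> set[int]:
        out, stack = set(), [v]
        while stack:
            x = stack.pop()
            out.add(x)
            for c in self.children.get(x, ()):
                stack.append(c)
        return out

    def detach(self, v: int) -> None:
        """Remove the subtree at ``v`` (and its suppressed parent node)."""
        p = self.parent[v]
        s = self.sibling(v)
        del self.parent[v]
        del self.children[p]
        if p == self.root:
            self.parent.pop(s)
            self.root = s
        else:
            g = self.parent.pop(p)
            cg = self.children[g]
            cg[cg.index(p)] = s
            self.parent[s] = g
        # v keeps its own subtree intact, parentless

    def attach(self, v: int, edge_child: int) -> None:
        p = self.parent[edge_child]
        m = self._new()
        self.children[m] = [edge_child, v]
        ch = self.children[p]
        ch[ch.index(edge_child)] = m
        self.parent[m] = p
        self.parent[edge_child] = m
        self.parent[v] = m

    def to_flat(self, tip_names: list[str]) -> FlatTree:
        n_tips = self.n_tips
        post: list[int] = []
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or node < n_tips:
                post.append(node)
                continue
            stack.append((node, True))
            for c in self.children[node]:
                stack.append((c, False))
        mapping: dict[int, int] = {}
        nxt = n_tips
        for node in post:
            if node < n_tips:
                mapping[node] = node
            else:
                mapping[node] = nxt
                nxt += 1
        n_nodes = nxt
        parent = np.full(n_nodes, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for node, p in self.parent.items():
            parent[mapping[node]] = mapping[p]
            children[mapping[p]].append(mapping[node])
        lengths = np.full(n_nodes, np.nan)
        postorder = np.array([mapping[x] for x in post], dtype=np.int64)
        return FlatTree(list(tip_names), parent, children, lengths, postorder)

    def bip_key(self) -> frozenset:
        """Canonical unrooted-topology identity: the set of non-trivial
        bipartitions, each as its smaller tip-id side."""
        n = self.n_tips
        all_tips = frozenset(range(n))
        out = set()
        for v in self.children:
            below = frozenset(x for x in self.subtree_nodes(v) if x < n)
            other = all_tips - below
            if len(below) < 2 or len(other) < 2:
                continue
            side = min(below, other, key=lambda s: (len(s), sorted(s)))
            out.add(side)
        return frozenset(out)


def _nni_neighbors(top: _Top):
    n = top.n_tips
    seen_root_edge = False
    for v in list(top.children):
        if v == top.root:
            continue
        p = top.parent[v]
        if p == top.root:
            # the two root edges are one unrooted edge; treat it once, and
            # only when both ends are internal
            if seen_root_edge:
                continue
            seen_root_edge = True
            s = top.sibling(v)
            if s < n or v < n:
                continue
            a, b = top.children[v]
            c, d = top.children[s]
            for u, w in ((a, c), (a, d)):
                t = top.clone()
                t.swap(u, w)
                yield t
            continue
        s = top.sibling(v)
        a, b = top.children[v]
        for u in (a, b):
            t = top.clone()
            t.swap(s, u)
            yield t


def _spr_neighbors(top: _Top):
    for v in list(top.parent):
        p = top.parent[v]
        s = top.sibling(v)
        pruned = top.clone()
        pruned.detach(v)
        sub = pruned.subtree_nodes(v)
        for w in list(pruned.parent):
            if w in sub or w == s:
                continue
            t = pruned.clone()
            t.attach(v, w)
            yield t


def _neighbors(top: _Top, swap: str):
    return _spr_neighbors(top) if swap == "spr" else _nni_neighbors(top)


# ---------------------------------------------------------------------------
# scoring


class _MPScorer:
    def __init__(self, cells: np.ndarray, tip_names: list[str]):
        self.patterns, _, self.weights = compress_columns(cells)
        self.tip_names = tip_names

    def __call__(self, top: _Top) -> float:
        flat = top.to_flat(self.tip_names)
        return float(fitch_steps(flat, self.patterns, self.weights))


class _MLScorer:
    """Likelihood score of a topology = lnL after branch-length (and shape)
    optimisation; ``cheap`` scores at parsimony-seeded lengths only."""

    def __init__(self, cells, tip_names, config: SearchConfig):
        self.patterns, _, self.weights = compress_columns(cells)
        self.tip_names = tip_names
        self.cfg = config
        self._cheap_cache: dict[frozenset, float] = {}
        self._full_cache: dict[frozenset, float] = {}

    def cheap(self, top: _Top) -> float:
        key = top.bip_key()
        if key in self._cheap_cache:
            return self._cheap_cache[key]
        flat = top.to_flat(self.tip_names)
        lengths = initial_branch_lengths(flat, self.patterns, self.weights)
        model = MkModel(
            gamma_shape=1.0 if self.cfg.gamma else None,
            n_categories=self.cfg.n_categories,
            p_invariant=0.0,
        )
        L = pattern_likelihoods(flat, self.patterns, model, lengths)
        lnl = float((self.weights * np.log(L)).sum())
        self._cheap_cache[key] = lnl
        return lnl

    def full(self, top: _Top) -> float:
        key = top.bip_key()
        if key in self._full_cache:
            return self._full_cache[key]
        # small trees are cheap enough to score near-exactly, which keeps
        # hill climbing honest when the optimum is a near-tie; canonical
        # form makes the score a function of the unrooted topology alone
        from .parsimony import canonical_flat

        small = top.n_tips < self.cfg.ml_full_below
        flat = canonical_flat(top.to_flat(self.tip_names))
        _, _, _, lnl = optimize_on_topology(
            flat, self.patterns, self.weights,
            gamma=self.cfg.gamma, invariant=self.cfg.invariant,
            n_categories=self.cfg.n_categories,
            tol=1e-8 if small else self.cfg.ml_search_tol,
            max_rounds=20 if small else self.cfg.ml_search_rounds,
            xatol=1e-6 if small else self.cfg.ml_search_xatol,
            second_init=small,
        )
        self._full_cache[key] = lnl
        return lnl


# ---------------------------------------------------------------------------
# stepwise addition and hill climbing


def _stepwise_addition(order: np.ndarray, scorer: _MPScorer,
                       rng: np.random.Generator, n_tips: int) -> _Top:
    top = _Top.triplet(int(order[0]), int(order[1]), int(order[2]), n_tips)
    for tip in order[3:]:
        best, best_edges = None, []
        for e in top.edge_nodes():
            cand = top.clone()
            cand.insert_tip(int(tip), e)
            s = scorer(cand)
            if best is None or s < best - 1e-12:
                best, best_edges = s, [e]
            elif s <= best + 1e-12:
                best_edges.append(e)
        e = best_edges[int(rng.integers(len(best_edges)))]
        top.insert_tip(int(tip), e)
    return top


def _hillclimb_mp(top: _Top, scorer: _MPScorer, swap: str):
    cur = scorer(top)
    while True:
        best_nb, best_s = None, cur
        for nb in _neighbors(top, swap):
            s = scorer(nb)
            if s < best_s - 1e-12:
                best_nb, best_s = nb, s
        if best_nb is None:
            return top, cur
        top, cur = best_nb, best_s


def _hillclimb_ml(top: _Top, scorer: _MLScorer, swap: str):
    cfg = scorer.cfg
    cur = scorer.full(top)
    while True:
        neighbors = list(_neighbors(top, swap))
        if top.n_tips < cfg.ml_full_below:
            scored = [(scorer.full(nb), nb) for nb in neighbors]
        else:
            ranked = sorted(
                neighbors, key=lambda nb: -scorer.cheap(nb)
            )[: cfg.ml_shortlist]
            scored = [(scorer.full(nb), nb) for nb in ranked]
        if not scored:
            return top, cur
        best_s, best_nb = max(scored, key=lambda x: x[0])
        if best_s > cur + 1e-9:
            top, cur = best_nb, best_s
        else:
            return top, cur


def _collect_cooptimal(tops: list[_Top], score: float, scorer, swap: str,
                       minimise: bool, max_saved: int) -> list[_Top]:
    """Closure of equally-best topologies reachable through the swap
    neighbourhood (capped at ``max_saved``)."""
    seen: dict[frozenset, _Top] = {}
    queue = list(tops)
    for t in queue:
        seen.setdefault(t.bip_key(), t)
    i = 0
    while i < len(queue) and len(seen) < max_saved:
        t = queue[i]
        i += 1
        for nb in _neighbors(t, swap):
            key = nb.bip_key()
            if key in seen:
                continue
            s = scorer(nb)
            same = abs(s - score) <= 1e-9
            if same:
                seen[key] = nb
                queue.append(nb)
                if len(seen) >= max_saved:
                    break
    return list(seen.values())


# ---------------------------------------------------------------------------
# public entry points


def _enumerate_small(n_tips: int) -> list[_Top]:
    """All unrooted topologies for fewer than 4 tips (there is one)."""
    if n_tips == 2:
        t = _Top(2)
        r = t._new()
        t.children[r] = [0, 1]
        t.parent = {0: r, 1: r}
        t.root = r
        return [t]
    return [_Top.triplet(0, 1, 2, 3)]


def search(matrix: TaxonAreaMatrix, config: SearchConfig) -> SearchResult:
    """Find the best area tree(s) under the configured objective.

    Random-addition starting trees followed by best-improvement hill
    climbing over the NNI or SPR neighbourhood; fewer than 4 areas is a
    trivial search space evaluated exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = matrix.n_areas
    names = matrix.area_names
    if n < 2:
        raise ValueError("need at least 2 areas")
    mp_scorer = _MPScorer(matrix.cells, names)

    if config.objective == "parsimony":
        if n < 4:
            tops = _enumerate_small(n)
            finals = [(tops[0], mp_scorer(tops[0]))]
        else:
            finals = []
            for _ in range(config.n_starts):
                order = rng.permutation(n)
                start = _stepwise_addition(order, mp_scorer, rng, n)
                finals.append(_hillclimb_mp(start, mp_scorer, config.swap))
        best = min(s for _, s in finals)
        best_tops = [t for t, s in finals if abs(s - best) <= 1e-9]
        if n >= 4:
            best_tops = _collect_cooptimal(
                best_tops, best, mp_scorer, config.swap, True, config.max_saved
            )
        else:
            uniq = {t.bip_key(): t for t in best_tops}
            best_tops = list(uniq.values())
        trees = [unflatten(t.to_flat(names), include_lengths=False)
                 for t in best_tops]
        return SearchResult(trees=trees, score=float(best),
                            objective="parsimony", n_optimal=len(trees))

    ml_scorer = _MLScorer(matrix.cells, names, config)
    if n < 4:
        cand = _enumerate_small(n)
        finals = [(cand[0], ml_scorer.full(cand[0]))]
    else:
        finals = []
        for _ in range(config.n_starts):
            order = rng.permutation(n)
            start = _stepwise_addition(order, mp_scorer, rng, n)
            finals.append(_hillclimb_ml(start, ml_scorer, config.swap))
    # fully re-fit the leading candidates: the search scores are coarse,
    # so near-ties between final topologies are resolved at full precision
    uniq: dict[frozenset, tuple[_Top, float]] = {}
    for top, lnl in finals:
        key = top.bip_key()
        if key not in uniq or lnl > uniq[key][1]:
            uniq[key] = (top, lnl)
    leaders = sorted(uniq.values(), key=lambda x: -x[1])[:3]
    fitted = None
    for top, _ in leaders:
        cand = mk_fit(
            unflatten(top.to_flat(names), include_lengths=False), matrix,
            gamma=config.gamma, invariant=config.invariant,
            n_categories=config.n_categories,
        )
        if fitted is None or cand.log_likelihood > fitted.log_likelihood:
            fitted = cand
    return SearchResult(
        trees=[fitted.tree], score=fitted.log_likelihood,
        objective="likelihood", n_optimal=1, fit=fitted,
    )


def bootstrap(matrix: TaxonAreaMatrix, config: SearchConfig,
              best_tree: AreaTree | None = None) -> tuple[AreaTree, dict]:
    """Nonparametric bootstrap over characters (species columns resampled
    with replacement, same column count per pseudo-matrix).

    Returns the best tree from the full search annotated with bipartition
    support percentages, plus the support table keyed by the smaller tip
    side of each bipartition. Trivial splits are not reported.
    """
    if config.bootstrap_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(config.seed)
    if best_tree is None:
        best_tree = search(matrix, config).trees[0]

    rep_cfg = replace(
        config,
        n_starts=max(1, config.bootstrap_starts),
        max_saved=1,
    )
    counts: dict[frozenset, int] = {}
    B = config.bootstrap_replicates
    for b in range(B):
        cols = rng.integers(0, matrix.n_species, size=matrix.n_species)
        pseudo = TaxonAreaMatrix(
            matrix.area_names,
            [f"bs{j}" for j in range(matrix.n_species)],
            matrix.cells[:, cols],
            provenance=f"bootstrap replicate {b}",
        )
        rep_cfg_b = replace(rep_cfg, seed=int(rng.integers(2**31 - 1)))
        rep_tree = search(pseudo, rep_cfg_b).trees[0]
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    supports = {bp: 100.0 * c / B for bp, c in counts.items()}
    annotated = best_tree.copy()
    d = annotated.dendropy_tree
    tips = set(annotated.tip_names)
    from .trees import _canonical_side
    for node in d.preorder_node_iter():
        if node.is_leaf() or node is d.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) < 2 or len(tips - below) < 2:
            continue
        key = _canonical_side(below, frozenset(tips - below))
        node.label = f"{supports.get(key, 0.0):g}"
    return annotated, supports
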