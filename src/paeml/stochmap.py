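"""Stochastic character mapping of individual species histories on a fixed
area tree.

A species history is one full realisation of the binary chain over the
whole tree: states at every node plus the exact change points along every
branch, drawn from the posterior given the observed presences at the tips.
Sampling is joint ancestral-state simulation (root from its conditional
posterior, descendants top-down) followed by endpoint-conditioned path
sampling on every branch. Gains (0 -> 1) read as dispersal into an area's
ancestry, losses (1 -> 0) as local extinction; the package reports counts
by direction and leaves the biogeographic labels to the user.

Path sampling is a hybrid: forward simulation with rejection on short
branches (conditioning the first event when the endpoints disagree), and
uniformisation elsewhere. For the symmetric binary chain the uniformised
jump matrix is a deterministic flip, so the uniformisation draw reduces to
a parity-constrained Poisson count with uniform event times — exact and
rejection-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import TaxonAreaMatrix
from .mk import MkModel, posterior_mean_rates
from .parsimony import mp_ancestral_state_sets
from .trees import AreaTree, FlatTree, TreeError, flatten

Segments = list[tuple[int, float]]


class ImpossiblePathError(ValueError):
    """Endpoints disagree on a zero-length branch."""


@dataclass
class CharacterHistory:
    """One sampled piecewise-constant history of one species."""

    species: str
    node_states: dict[int, int]          # flat node index -> state
    segments: dict[int, Segments]        # non-root node index -> branch path

    def n_changes(self) -> int:
        return sum(len(s) - 1 for s in self.segments.values())


@dataclass
class MapSummary:
    """Monte-Carlo averages over ``n_samples`` histories."""

    species: str
    n_samples: int
    seed: int
    node_posterior_presence: np.ndarray   # (n_nodes,)
    branch_occupancy: np.ndarray          # expected time in state 1, (n_nodes,)
    branch_gains: np.ndarray              # expected 0->1 changes per branch
    branch_losses: np.ndarray             # expected 1->0 changes per branch
    flat: FlatTree = field(repr=False, default=None)

    def to_frame(self):
        import pandas as pd

        flat = self.flat
        labels = [
            flat.tip_names[i] if i < flat.n_tips
            else "{" + ",".join(flat.tip_names[t] for t in flat.tips_below(i)) + "}"
            for i in range(flat.n_nodes)
        ]
        return pd.DataFrame(
            {
                "node": labels,
                "branch_length": flat.lengths,
                "posterior_presence": self.node_posterior_presence,
                "expected_occupancy": self.branch_occupancy,
                "expected_gains": self.branch_gains,
                "expected_losses": self.branch_losses,
            }
        )


# ---------------------------------------------------------------------------
# conditional partials and joint ancestral sampling


def _branch_probs(t: float, rate: float) -> tuple[float, float]:
    e = float(np.exp(-2.0 * rate * t))
    return 0.5 * (1.0 + e), 0.5 * (1.0 - e)


def _partials(flat: FlatTree, column: np.ndarray, rate: float) -> np.ndarray:
    """(n_nodes, 2) conditional likelihoods of the subtree below each node."""
    part = np.empty((flat.n_nodes, 2))
    for node in flat.postorder:
        if node < flat.n_tips:
            s = int(column[node])
            part[node] = (1.0 - s, float(s))
            continue
        acc = np.ones(2)
        for c in flat.children[node]:
            t = flat.lengths[c]
            if not np.isfinite(t):
                raise TreeError("unset branch length")
            ps, pd = _branch_probs(t, rate)
            P = np.array([[ps, pd], [pd, ps]])
            acc = acc * (P @ part[c])
        part[node] = acc
    return part


def node_marginal_posteriors(
    flat: FlatTree, column: np.ndarray, rate: float = 1.0
) -> np.ndarray:
    """Exact marginal posterior presence probability at every node (the
    pruning-based oracle the sampled frequencies must converge to)."""
    part = _partials(flat, column, rate)
    up = np.empty((flat.n_nodes, 2))     # likelihood of everything except
    up[flat.root] = (0.5, 0.5)           # the subtree below the node
    for node in flat.preorder():
        if node == flat.root:
            continue
        p = flat.parent[node]
        sib_acc = up[p].copy()
        for c in flat.children[p]:
            if c == node:
                continue
            ps, pd = _branch_probs(flat.lengths[c], rate)
            P = np.array([[ps, pd], [pd, ps]])
            sib_acc = sib_acc * (P @ part[c])
        ps, pd = _branch_probs(flat.lengths[node], rate)
        P = np.array([[ps, pd], [pd, ps]])
        up[node] = P.T @ sib_acc
    post = up * part
    return post[:, 1] / post.sum(axis=1)


def sample_ancestral_states(
    flat: FlatTree,
    column: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    n_samples: int = 1,
) -> np.ndarray:
    """Jointly sample node states from their posterior: root from the
    conditional root posterior, descendants top-down. Returns an
    (n_samples, n_nodes) int8 array (tip states are the observed data)."""
    part = _partials(flat, column, rate)
    states = np.empty((n_samples, flat.n_nodes), dtype=np.int8)
    w = 0.5 * part[flat.root]
    p1 = w[1] / w.sum()
    states[:, flat.root] = rng.random(n_samples) < p1
    for node in flat.preorder():
        if node == flat.root:
            continue
        if node < flat.n_tips:
            states[:, node] = int(column[node])
            continue
        ps, pd = _branch_probs(flat.lengths[node], rate)
        parent_states = states[:, flat.parent[node]]
        # P(parent -> 1) * partial_1 vs P(parent -> 0) * partial_0
        w1 = np.where(parent_states == 1, ps, pd) * part[node, 1]
        w0 = np.where(parent_states == 0, ps, pd) * part[node, 0]
        states[:, node] = rng.random(n_samples) < w1 / (w0 + w1)
    return states


# ---------------------------------------------------------------------------
# endpoint-conditioned path sampling on a single branch

_REJECTION_CAP = 1000


def _forward_times(t: float, rate: float, rng, first: float | None) -> list[float]:
    """Event times of a forward simulation on [0, t]; ``first`` forces the
    first event time (already drawn), else the chain starts fresh."""
    times: list[float] = []
    x = 0.0
    if first is not None:
        times.append(first)
        x = first
    while True:
        x += rng.exponential(1.0 / rate)
        if x >= t:
            return times
        times.append(x)


def _segments_from_times(s0: int, t: float, times: list[float]) -> Segments:
    segs: Segments = []
    prev = 0.0
    state = s0
    for x in times:
        segs.append((state, x - prev))
        prev = x
        state = 1 - state
    segs.append((state, t - prev))
    return segs


def _parity_poisson(lam: float, odd: bool, rng: np.random.Generator) -> int:
    """Draw from Poisson(lam) conditioned on parity."""
    # cumulative over the allowed terms; cutoff where the tail is negligible
    nmax = max(10, int(lam + 12.0 * np.sqrt(lam + 1.0)))
    ns = np.arange(1 if odd else 0, nmax + 1, 2)
    logw = ns * np.log(lam) - lam - np.cumsum(
        np.log(np.maximum(np.arange(nmax + 1), 1))
    )[ns]
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return int(rng.choice(ns, p=w))


def sample_branch_history(
    state_start: int,
    state_end: int,
    t: float,
    rate: float,
    rng: np.random.Generator,
) -> Segments:
    """One path of the symmetric binary chain on a branch of length ``t``,
    conditioned on both endpoints."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0.0:
        if state_start != state_end:
            raise ImpossiblePathError(
                "endpoints differ on a zero-length branch"
            )
        return [(state_start, 0.0)]
    lam = rate * t
    if lam <= 4.0:
        for _ in range(_REJECTION_CAP):
            if state_start == state_end:
                times = _forward_times(t, rate, rng, None)
            else:
                # endpoints differ: the first event is forced; draw it from
                # the truncated exponential on [0, t]
                u = rng.random()
                first = -np.log(1.0 - u * (1.0 - np.exp(-lam))) / rate
                times = _forward_times(t, rate, rng, first)
            if (len(times) % 2 == 1) == (state_start != state_end):
                return _segments_from_times(state_start, t, times)
    # uniformisation: for the symmetric chain every uniformised event is a
    # real flip, so the count is parity-constrained Poisson and the times
    # are order statistics of uniforms
    odd = state_start != state_end
    n = _parity_poisson(lam, odd, rng)
    times = sorted(rng.random(n) * t)
    return _segments_from_times(state_start, t, list(times))


# ---------------------------------------------------------------------------
# whole-tree mapping


def map_character(
    tree: AreaTree,
    matrix: TaxonAreaMatrix,
    species: str,
    model: MkModel | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    uniform_rate: bool = False,
    keep_histories: bool = True,
) -> tuple[list[CharacterHistory], MapSummary]:
    """Sample ``n_samples`` full histories of one species on the area tree
    and aggregate them.

    The mapping rate is the character's posterior-mean rate under the
    fitted mixture model (``uniform_rate=True`` forces rate 1).
    """
    if species not in matrix.species_names:
        raise KeyError(f"unknown species {species!r}")
    model = model or MkModel()
    if set(tree.tip_names) != set(matrix.area_names):
        raise TreeError("tree tips do not match matrix areas")
    flat = flatten(tree, tip_order=matrix.area_names)
    column = matrix.column(species)
    if uniform_rate:
        rate = 1.0
    else:
        rate = float(
            posterior_mean_rates(tree, matrix, model)[
                matrix.species_names.index(species)
            ]
        )
        rate = max(rate, 1e-8)
    rng = np.random.default_rng(seed)

    states = sample_ancestral_states(flat, column, rate, rng, n_samples)
    n_nodes = flat.n_nodes
    occupancy = np.zeros(n_nodes)
    gains = np.zeros(n_nodes)
    losses = np.zeros(n_nodes)
    histories: list[CharacterHistory] = []
    non_root = [v for v in range(n_nodes) if v != flat.root]
    for k in range(n_samples):
        segs_all: dict[int, Segments] = {}
        for v in non_root:
            s0 = int(states[k, flat.parent[v]])
            s1 = int(states[k, v])
            segs = sample_branch_history(s0, s1, float(flat.lengths[v]), rate, rng)
            segs_all[v] = segs
            occupancy[v] += sum(d for st, d in segs if st == 1)
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == 0 and b == 1:
                    gains[v] += 1
                else:
                    losses[v] += 1
        if keep_histories:
            histories.append(
                CharacterHistory(
                    species,
                    {v: int(states[k, v]) for v in range(n_nodes)},
                    segs_all,
                )
            )
    summary = MapSummary(
        species=species,
        n_samples=n_samples,
        seed=seed,
        node_posterior_presence=states.mean(axis=0),
        branch_occupancy=occupancy / n_samples,
        branch_gains=gains / n_samples,
        branch_losses=losses / n_samples,
        flat=flat,
    )
    return histories, summary


def mp_ancestral_states(
    tree: AreaTree, matrix: TaxonAreaMatrix, species: str
) -> dict[int, set[int]]:
    """Most-parsimonious ancestral state sets for one species: the point
    reconstruction the stochastic maps are contrasted with. Keys are flat
    node indices (tips first, in matrix area order)."""
    if species not in matrix.species_names:
        raise KeyError(f"unknown species {species!r}")
    return mp_ancestral_state_sets(
        tree, matrix.column(species), matrix.area_names
    )
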