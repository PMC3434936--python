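"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive: likelihoods by explicit enumeration
of ancestral-state assignments with matrix exponentials, parsimony by
enumeration of labelings, topology search by enumeration of all unrooted
topologies. Nothing imports the engines it validates beyond the shared
data containers.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from paeml.trees import AreaTree, FlatTree, flatten


def transition_matrix_expm(t: float, rate: float = 1.0) -> np.ndarray:
    """2-state symmetric transition probabilities via scipy's matrix
    exponential (oracle for the closed form)."""
    Q = rate * np.array([[-1.0, 1.0], [1.0, -1.0]])
    return expm(Q * t)


def brute_force_likelihood(
    flat: FlatTree, column: np.ndarray, rates: np.ndarray | None = None,
    p_invariant: float = 0.0,
) -> float:
    """Likelihood of one character by summation over every assignment of
    states to internal nodes, mixed over rate categories."""
    rates = np.array([1.0]) if rates is None else rates
    internal = [n for n in range(flat.n_tips, flat.n_nodes)]
    total_mix = 0.0
    for r in rates:
        total = 0.0
        for assign in itertools.product((0, 1), repeat=len(internal)):
            state = {n: int(column[n]) for n in range(flat.n_tips)}
            state.update(dict(zip(internal, assign)))
            p = 0.5  # uniform root prior
            for node in range(flat.n_nodes):
                if node == flat.root:
                    continue
                P = transition_matrix_expm(float(flat.lengths[node]), float(r))
                p *= P[state[flat.parent[node]], state[node]]
            total += p
        total_mix += total / len(rates)
    if p_invariant > 0.0:
        const0 = all(column[i] == 0 for i in range(flat.n_tips))
        const1 = all(column[i] == 1 for i in range(flat.n_tips))
        total_mix = (1 - p_invariant) * total_mix + p_invariant * 0.5 * (
            const0 + const1
        )
    return total_mix


def brute_force_log_likelihood(tree: AreaTree, cells: np.ndarray,
                               tip_order: list[str],
                               rates: np.ndarray | None = None) -> float:
    flat = flatten(tree, tip_order=tip_order)
    return float(sum(
        np.log(brute_force_likelihood(flat, cells[:, j], rates))
        for j in range(cells.shape[1])
    ))


# ---------------------------------------------------------------------------
# parsimony by labeling enumeration


def enumerate_parsimony(
    flat: FlatTree, column: np.ndarray
) -> tuple[int, dict[int, set[int]]]:
    """Minimal change count and, per node, the set of states appearing in
    at least one minimal labeling."""
    internal = [n for n in range(flat.n_tips, flat.n_nodes)]
    best = None
    best_sets: dict[int, set[int]] = {}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = {n: int(column[n]) for n in range(flat.n_tips)}
        state.update(dict(zip(internal, assign)))
        changes = sum(
            state[node] != state[flat.parent[node]]
            for node in range(flat.n_nodes) if node != flat.root
        )
        if best is None or changes < best:
            best = changes
            best_sets = {n: {state[n]} for n in range(flat.n_nodes)}
        elif changes == best:
            for n in range(flat.n_nodes):
                best_sets[n].add(state[n])
    return best, best_sets


def enumerate_fitch_length(flat: FlatTree, cells: np.ndarray) -> int:
    return sum(
        enumerate_parsimony(flat, cells[:, j])[0] for j in range(cells.shape[1])
    )


# ---------------------------------------------------------------------------
# all unrooted topologies


def all_unrooted_topologies(labels: list[str]) -> list[AreaTree]:
    """Every unrooted binary topology over the labels, built by recursive
    edge insertion on nested-tuple trees (1, 3, 15, 105 ... trees)."""
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def insert_everywhere(subtree, leaf):
        # yields versions of `subtree` with `leaf` attached on each edge
        yield (subtree, leaf)
        if isinstance(subtree, tuple):
            a, b = subtree
            for a2 in insert_everywhere(a, leaf):
                yield (a2, b)
            for b2 in insert_everywhere(b, leaf):
                yield (a, b2)

    # represent the unrooted tree rooted at labels[0]'s branch
    cores = [labels[1] if len(labels) == 2 else (labels[1], labels[2])]
    for leaf in labels[3:]:
        cores = [c2 for c in cores for c2 in insert_everywhere(c, leaf)]

    def render(x) -> str:
        if isinstance(x, tuple):
            return "(" + render(x[0]) + "," + render(x[1]) + ")"
        return x

    return [
        AreaTree.from_newick(f"({labels[0]},{render(c)});") for c in cores
    ]
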