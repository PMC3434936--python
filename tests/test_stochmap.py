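"""Stochastic character mapping: analytic path probabilities, posterior
agreement, parity invariants, SIMMAP serialisation."""

import numpy as np
import pytest

from paeml import (
    AreaTree,
    ImpossiblePathError,
    MkModel,
    TaxonAreaMatrix,
    map_character,
    mp_ancestral_states,
    node_marginal_posteriors,
    read_simmap,
    sample_ancestral_states,
    sample_branch_history,
    write_simmap,
)
from paeml.trees import flatten
from conftest import random_matrix, random_tree


class TestBranchPathSampling:
    def test_zero_branch_equal_endpoints(self):
        rng = np.random.default_rng(0)
        assert sample_branch_history(1, 1, 0.0, 1.0, rng) == [(1, 0.0)]

    def test_zero_branch_unequal_endpoints_impossible(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ImpossiblePathError):
            sample_branch_history(0, 1, 0.0, 1.0, rng)

    def test_parity_follows_endpoints(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            segs = sample_branch_history(0, 1, 0.8, 1.5, rng)
            assert (len(segs) - 1) % 2 == 1
            segs = sample_branch_history(1, 1, 0.8, 1.5, rng)
            assert (len(segs) - 1) % 2 == 0

    def test_segments_partition_branch(self):
        rng = np.random.default_rng(2)
        for t, rate in [(0.3, 1.0), (2.0, 0.7), (6.0, 1.2)]:
            segs = sample_branch_history(0, 0, t, rate, rng)
            assert sum(d for _, d in segs) == pytest.approx(t, abs=1e-9)
            for (a, _), (b, _) in zip(segs, segs[1:]):
                assert a != b

    def test_zero_change_probability_analytic(self):
        # P(no change | 0 -> 0, t=1, rate=1) = e^-1 / (0.5 (1 + e^-2))
        rng = np.random.default_rng(3)
        n = 20_000
        zero = sum(
            len(sample_branch_history(0, 0, 1.0, 1.0, rng)) == 1
            for _ in range(n)
        )
        p = np.exp(-1) / (0.5 * (1 + np.exp(-2)))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(zero / n - p) < 3 * se

    def test_uniformisation_regime_matches_analytic(self):
        # rate*t > 4 exercises the uniformisation path
        rng = np.random.default_rng(4)
        t, rate, n = 5.0, 1.0, 20_000
        zero = sum(
            len(sample_branch_history(0, 0, t, rate, rng)) == 1
            for _ in range(n)
        )
        p = np.exp(-rate * t) / (0.5 * (1 + np.exp(-2 * rate * t)))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(zero / n - p) < 3 * se + 1e-4


class TestAncestralSampling:
    def test_constant_presence_near_zero_branches(self):
        t = AreaTree.from_newick("((A:1e-6,B:1e-6):1e-6,(C:1e-6,D:1e-6):1e-6);")
        flat = flatten(t)
        states = sample_ancestral_states(
            flat, np.ones(4), 1.0, np.random.default_rng(5), 2000
        )
        assert states.mean(axis=0).min() > 0.99

    def test_single_branch_posterior_analytic(self):
        # two tips both 0: P(root=0) from the closed-form posterior
        t = AreaTree.from_newick("(A:0.4,B:0.6);")
        flat = flatten(t)
        col = np.array([0, 0])
        n = 50_000
        states = sample_ancestral_states(
            flat, col, 1.0, np.random.default_rng(6), n
        )
        pa = 0.5 * (1 + np.exp(-0.8))
        pb = 0.5 * (1 + np.exp(-1.2))
        qa, qb = 1 - pa, 1 - pb
        post0 = pa * pb / (pa * pb + qa * qb)
        emp = 1 - states[:, flat.root].mean()
        se = np.sqrt(post0 * (1 - post0) / n)
        assert abs(emp - post0) < 3 * se

    def test_sampled_frequencies_match_pruning_marginals(self):
        rng = np.random.default_rng(7)
        labels = list("ABCDEF")
        tree = random_tree(rng, labels)
        flat = flatten(tree)
        col = rng.integers(0, 2, size=6)
        post = node_marginal_posteriors(flat, col, 1.0)
        states = sample_ancestral_states(
            flat, col, 1.0, np.random.default_rng(8), 10_000
        )
        assert np.abs(states.mean(axis=0) - post).max() < 0.02

    def test_determinism(self):
        t = AreaTree.from_newick("((A:0.3,B:0.2):0.1,(C:0.4,D:0.1):0.2);")
        flat = flatten(t)
        col = np.array([0, 1, 1, 0])
        s1 = sample_ancestral_states(flat, col, 1.0,
                                     np.random.default_rng(9), 100)
        s2 = sample_ancestral_states(flat, col, 1.0,
                                     np.random.default_rng(9), 100)
        assert np.array_equal(s1, s2)


class TestMapCharacter:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(10)
        labels = list("ABCDEF")
        tree = random_tree(rng, labels, 0.1, 0.5)
        m = random_matrix(rng, 6, 10, names=labels)
        return tree, m

    def test_tip_states_reproduce_observed_column(self, setup):
        tree, m = setup
        hist, _ = map_character(tree, m, "s3", n_samples=50, seed=11)
        col = m.column("s3")
        flat = flatten(tree, tip_order=m.area_names)
        for h in hist:
            for i in range(flat.n_tips):
                assert h.node_states[i] == col[i]
            # branch path endpoints agree with node states
            for v, segs in h.segments.items():
                assert segs[0][0] == h.node_states[flat.parent[v]]
                assert segs[-1][0] == h.node_states[v]

    def test_summary_reproducible_from_seed(self, setup):
        tree, m = setup
        _, s1 = map_character(tree, m, "s0", n_samples=60, seed=12)
        _, s2 = map_character(tree, m, "s0", n_samples=60, seed=12)
        assert np.array_equal(s1.node_posterior_presence,
                              s2.node_posterior_presence)
        assert np.array_equal(s1.branch_gains, s2.branch_gains)

    def test_node_frequencies_match_pruning_posteriors(self, setup):
        tree, m = setup
        _, summary = map_character(
            tree, m, "s5", n_samples=10_000, seed=13, uniform_rate=True
        )
        flat = summary.flat
        post = node_marginal_posteriors(flat, m.column("s5"), 1.0)
        assert np.abs(summary.node_posterior_presence - post).max() < 0.02

    def test_endemic_pair_gains_concentrate_on_stem(self):
        # a species present only in two sister areas: the expected gain
        # mass should sit on the path subtending that pair
        tree = AreaTree.from_newick(
            "((A:0.2,B:0.2):0.2,((C:0.1,D:0.1):0.2,E:0.3):0.1);"
        )
        m = TaxonAreaMatrix(
            list("ABCDE"), ["end"], [[0], [0], [1], [1], [0]]
        )
        _, summary = map_character(tree, m, "end", n_samples=4000, seed=14,
                                   uniform_rate=True)
        flat = summary.flat
        cd_stem = next(
            v for v in range(flat.n_tips, flat.n_nodes)
            if sorted(flat.tips_below(v)) == [2, 3]
        )
        other_mass = summary.branch_gains.sum() - summary.branch_gains[cd_stem]
        assert summary.branch_gains[cd_stem] > other_mass

    def test_expected_changes_scale_with_branch_length(self):
        # unconditional: E[changes] on a branch = rate * t for the
        # symmetric chain; with both endpoints free this is recovered by
        # mapping a 2-tip tree with an uninformative... instead check the
        # conditional expectation on a single branch analytically:
        # E[N | 0 -> 0, t, r] for small t concentrates on 0 and 2
        rng = np.random.default_rng(15)
        t, rate, n = 1.0, 1.0, 30_000
        counts = [
            len(sample_branch_history(0, 0, t, rate, rng)) - 1
            for _ in range(n)
        ]
        lam = rate * t
        # analytic: N parity-even Poisson(lam) weighted -> E[N | even]
        ns = np.arange(0, 60, 2)
        w = np.exp(ns * np.log(lam) - lam
                   - np.cumsum(np.log(np.maximum(np.arange(60), 1)))[ns])
        expect = (ns * w).sum() / w.sum()
        assert np.mean(counts) == pytest.approx(expect, abs=0.02)

    def test_unknown_species_rejected(self, setup):
        tree, m = setup
        with pytest.raises(KeyError):
            map_character(tree, m, "nope", n_samples=5, seed=1)


class TestMPComparator:
    def test_matches_module_level_wrapper(self):
        tree = AreaTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = TaxonAreaMatrix(list("ABCD"), ["s"], [[1], [1], [0], [0]])
        sets = mp_ancestral_states(tree, m, "s")
        assert sets[0] == {1} and sets[3] == {0}


class TestSimmapIO:
    def test_round_trip(self, tmp_path):
        tree = AreaTree.from_newick("((A:0.5,B:1):0.25,C:2);")
        flat = flatten(tree)
        rng = np.random.default_rng(16)
        segments = {}
        for v in range(flat.n_nodes):
            if v == flat.root:
                continue
            segments[v] = sample_branch_history(
                0, 0, float(flat.lengths[v]), 2.0, rng
            )
        p = tmp_path / "map.tre"
        write_simmap(flat, segments, p)
        tree2, segs2 = read_simmap(p)
        for v, segs in segments.items():
            key = frozenset(flat.tip_names[t] for t in flat.tips_below(v))
            got = segs2[key]
            assert len(got) == len(segs)
            for (s1, d1), (s2, d2) in zip(segs, got):
                assert s1 == s2 and d1 == pytest.approx(d2, rel=1e-9)

    def test_single_change_annotation(self):
        tree = AreaTree.from_newick("(A:1,B:1);")
        flat = flatten(tree)
        segments = {0: [(0, 0.25), (1, 0.75)], 1: [(1, 1.0)]}
        out = write_simmap(flat, segments)
        assert "{0,0.25:1,0.75}" in out

    def test_bad_durations_rejected(self):
        from paeml import SimmapError

        tree = AreaTree.from_newick("(A:1,B:1);")
        flat = flatten(tree)
        with pytest.raises(SimmapError, match="sum"):
            write_simmap(flat, {0: [(0, 0.5)], 1: [(1, 1.0)]})
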