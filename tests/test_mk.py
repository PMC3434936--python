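"""Likelihood engine: closed forms, pruning vs enumeration, mixtures and
optimisation behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paeml import (
    AreaTree,
    MkModel,
    TaxonAreaMatrix,
    fit,
    gamma_category_rates,
    log_likelihood,
    transition_probability,
)
from paeml.trees import flatten
from paeml.simulate import SimulationConfig, simulate_matrix
from conftest import random_matrix, random_tree
from oracles import brute_force_log_likelihood, transition_matrix_expm


class TestTransitionProbability:
    def test_zero_branch_is_identity(self):
        assert np.allclose(transition_probability(0.0), np.eye(2))

    def test_long_branch_reaches_stationarity(self):
        assert np.allclose(transition_probability(1e6), 0.5, atol=1e-12)

    @pytest.mark.parametrize("t,rate", [(0.5, 1.0), (0.1, 3.0), (2.0, 0.25)])
    def test_matches_matrix_exponential(self, t, rate):
        P = transition_probability(t, rate)
        assert np.allclose(P, transition_matrix_expm(t, rate), atol=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert P[0, 0] >= 0.5

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(-0.1)


class TestLogLikelihoodClosedForms:
    def test_constant_character_zero_lengths(self):
        t = AreaTree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        m = TaxonAreaMatrix(list("ABCD"), ["s1"], [[0], [0], [0], [0]])
        res = log_likelihood(t, m)
        assert res.log_likelihood == pytest.approx(np.log(0.5), abs=1e-12)

    def test_two_tip_closed_form(self):
        t = AreaTree.from_newick("(A:0.3,B:0.2);")
        m = TaxonAreaMatrix(["A", "B"], ["s1"], [[0], [1]])
        res = log_likelihood(t, m)
        expected = 0.5 * 0.5 * (1 - np.exp(-1.0))  # total path 0.5
        assert expected == pytest.approx(0.1580302, abs=1e-7)
        assert res.log_likelihood == pytest.approx(np.log(expected), abs=1e-10)
        assert res.log_likelihood == pytest.approx(-1.8449695, abs=1e-6)

    def test_per_character_terms_sum_to_total(self, quartet_tree, quartet_matrix):
        res = log_likelihood(quartet_tree, quartet_matrix)
        assert res.per_character_log_likelihoods.sum() == pytest.approx(
            res.log_likelihood
        )
        assert (np.exp(res.per_character_log_likelihoods) <= 1.0).all()


class TestPruningAgainstEnumeration:
    @pytest.mark.parametrize("n_tips", [3, 4, 5])
    def test_random_instances(self, n_tips):
        rng = np.random.default_rng(100 + n_tips)
        labels = [chr(ord("A") + i) for i in range(n_tips)]
        for _ in range(8):
            tree = random_tree(rng, labels)
            m = random_matrix(rng, n_tips, 6, names=labels)
            got = log_likelihood(tree, m).log_likelihood
            want = brute_force_log_likelihood(tree, m.cells, labels)
            assert got == pytest.approx(want, abs=1e-10)

    def test_gamma_mixture_against_enumeration(self):
        rng = np.random.default_rng(7)
        labels = list("ABCDE")
        tree = random_tree(rng, labels)
        m = random_matrix(rng, 5, 8, names=labels)
        model = MkModel(gamma_shape=0.6)
        got = log_likelihood(tree, m, model).log_likelihood
        want = brute_force_log_likelihood(
            tree, m.cells, labels, rates=gamma_category_rates(0.6, 4)
        )
        assert got == pytest.approx(want, abs=1e-10)


class TestModelInvariants:
    def test_rerooting_invariance(self):
        rng = np.random.default_rng(11)
        labels = list("ABCDEF")
        tree = random_tree(rng, labels)
        m = random_matrix(rng, 6, 30, names=labels)
        base = log_likelihood(tree, m).log_likelihood
        for tip in labels:
            rerooted = tree.reroot_on_tip(tip)
            assert log_likelihood(rerooted, m).log_likelihood == pytest.approx(
                base, abs=1e-10
            )

    def test_huge_alpha_converges_to_homogeneous(self):
        rng = np.random.default_rng(13)
        labels = list("ABCDE")
        tree = random_tree(rng, labels)
        m = random_matrix(rng, 5, 20, names=labels)
        plain = log_likelihood(tree, m).log_likelihood
        near = log_likelihood(tree, m, MkModel(gamma_shape=1e8)).log_likelihood
        assert abs(near - plain) < 1e-6

    def test_duplicating_characters_doubles_lnl(self, quartet_tree, quartet_matrix):
        doubled = TaxonAreaMatrix(
            quartet_matrix.area_names,
            quartet_matrix.species_names
            + [s + "_dup" for s in quartet_matrix.species_names],
            np.hstack([quartet_matrix.cells, quartet_matrix.cells]),
        )
        l1 = log_likelihood(quartet_tree, quartet_matrix).log_likelihood
        l2 = log_likelihood(quartet_tree, doubled).log_likelihood
        assert l2 == pytest.approx(2 * l1, abs=1e-9)

    def test_allzero_character_additivity(self, quartet_tree, quartet_matrix):
        plus = TaxonAreaMatrix(
            quartet_matrix.area_names,
            quartet_matrix.species_names + ["ghost"],
            np.hstack([quartet_matrix.cells,
                       np.zeros((4, 1), dtype=int)]),
        )
        base = log_likelihood(quartet_tree, quartet_matrix)
        aug = log_likelihood(quartet_tree, plus)
        delta = aug.log_likelihood - base.log_likelihood
        assert delta == pytest.approx(
            aug.per_character_log_likelihoods[-1], abs=1e-10
        )
        assert delta < 0  # a log-probability

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_mixture_bounds(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCD")
        tree = random_tree(rng, labels)
        m = random_matrix(rng, 4, 10, names=labels)
        plain = log_likelihood(tree, m, MkModel(gamma_shape=0.8))
        mixed = log_likelihood(
            tree, m, MkModel(gamma_shape=0.8, p_invariant=0.3)
        )
        # per-character likelihoods remain probabilities
        assert (np.exp(mixed.per_character_log_likelihoods) <= 1.0).all()
        assert np.isfinite(mixed.log_likelihood)
        assert mixed.log_likelihood != plain.log_likelihood


class TestFit:
    def test_fit_improves_on_initial_lengths(self, quartet_matrix):
        topo = AreaTree.from_newick("((A,B),(C,D));")
        res = fit(topo, quartet_matrix)
        start = AreaTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        assert res.log_likelihood >= log_likelihood(
            start, quartet_matrix
        ).log_likelihood

    def test_all_constant_matrix_hits_lower_bound(self):
        topo = AreaTree.from_newick("((A,B),(C,D));")
        m = TaxonAreaMatrix(list("ABCD"), ["s1", "s2"],
                            np.zeros((4, 2), dtype=int))
        with pytest.warns(UserWarning, match="lower bound"):
            res = fit(topo, m)
        lengths = [
            e.length for e in res.tree.dendropy_tree.preorder_edge_iter()
            if e.length is not None
        ]
        assert max(lengths) <= 1e-5

    def test_fit_invariant_to_input_rooting(self):
        rng = np.random.default_rng(55)
        labels = list("ABCDEF")
        tree = random_tree(rng, labels)
        m = random_matrix(rng, 6, 25, names=labels)
        base = fit(tree, m).log_likelihood
        for tip in ("C", "F"):
            assert fit(tree.reroot_on_tip(tip), m).log_likelihood == base

    def test_fit_accepts_pruned_trees(self):
        # pruning can leave representational unifurcations; fit must
        # canonicalise them away
        rng = np.random.default_rng(56)
        labels = list("ABCDEF")
        tree = random_tree(rng, labels)
        pruned = tree.prune_tips(["A"])
        m = random_matrix(rng, 5, 10, names=labels[1:])
        res = fit(pruned, m)
        assert np.isfinite(res.log_likelihood)

    def test_deterministic(self, quartet_matrix):
        topo = AreaTree.from_newick("((A,B),(C,D));")
        r1 = fit(topo, quartet_matrix, gamma=True)
        r2 = fit(topo, quartet_matrix, gamma=True)
        assert r1.log_likelihood == r2.log_likelihood
        assert r1.gamma_shape == r2.gamma_shape


class TestGammaDiscretisation:
    def test_category_rates_have_unit_mean(self):
        for alpha in (0.1, 0.5, 1.0, 5.0):
            r = gamma_category_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0, abs=1e-12)
            assert (np.diff(r) > 0).all()

    def test_class_means_match_monte_carlo(self):
        alpha, k = 0.5, 4
        r = gamma_category_rates(alpha, k)
        rng = np.random.default_rng(0)
        draws = np.sort(rng.gamma(alpha, 1 / alpha, size=400_000))
        mc = draws.reshape(k, -1).mean(axis=1)
        assert np.allclose(r, mc, rtol=0.02)
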