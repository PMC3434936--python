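"""Heuristic search and bootstrap: exhaustive-oracle equivalence on small
instances, determinism, and support behaviour."""

import numpy as np
import pytest

from paeml import (
    SearchConfig,
    TaxonAreaMatrix,
    bootstrap,
    fit,
    fitch_length,
    log_likelihood,
    rf_distance,
    search,
)
from conftest import random_matrix
from oracles import all_unrooted_topologies


class TestParsimonySearch:
    def test_four_areas_equals_exhaustive(self):
        rng = np.random.default_rng(5)
        labels = list("ABCD")
        for _ in range(10):
            m = random_matrix(rng, 4, 12, names=labels)
            res = search(m, SearchConfig(objective="parsimony", n_starts=3,
                                         seed=1))
            oracle = min(
                fitch_length(t, m).length
                for t in all_unrooted_topologies(labels)
            )
            assert res.score == oracle

    def test_six_areas_equals_exhaustive(self):
        rng = np.random.default_rng(9)
        labels = list("ABCDEF")
        tops = all_unrooted_topologies(labels)
        for _ in range(10):
            m = random_matrix(rng, 6, 15, names=labels)
            res = search(m, SearchConfig(objective="parsimony", n_starts=5,
                                         seed=2))
            oracle = min(fitch_length(t, m).length for t in tops)
            assert res.score == oracle

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng, 7, 30)
        cfg = SearchConfig(objective="parsimony", n_starts=4, seed=77)
        r1 = search(m, cfg)
        r2 = search(m, cfg)
        assert r1.score == r2.score
        assert [t.newick() for t in r1.trees] == [t.newick() for t in r2.trees]

    def test_reported_score_matches_rescoring(self):
        rng = np.random.default_rng(15)
        m = random_matrix(rng, 6, 20)
        res = search(m, SearchConfig(objective="parsimony", n_starts=3, seed=3))
        for t in res.trees:
            assert fitch_length(t, m).length == res.score


class TestLikelihoodSearch:
    def test_five_areas_equals_exhaustive(self):
        rng = np.random.default_rng(21)
        labels = list("ABCDE")
        tops = all_unrooted_topologies(labels)
        for _ in range(3):
            m = random_matrix(rng, 5, 15, names=labels)
            res = search(m, SearchConfig(objective="likelihood", n_starts=3,
                                         seed=4))
            oracle = max(fit(t, m).log_likelihood for t in tops)
            assert res.score == pytest.approx(oracle, abs=1e-5)

    def test_spr_not_worse_than_nni(self):
        rng = np.random.default_rng(27)
        m = random_matrix(rng, 7, 25)
        nni = search(m, SearchConfig(objective="parsimony", swap="nni",
                                     n_starts=3, seed=5))
        spr = search(m, SearchConfig(objective="parsimony", swap="spr",
                                     n_starts=3, seed=5))
        assert spr.score <= nni.score

    def test_reported_lnl_matches_refit(self):
        rng = np.random.default_rng(33)
        m = random_matrix(rng, 5, 12)
        res = search(m, SearchConfig(objective="likelihood", n_starts=2,
                                     seed=6))
        refit = log_likelihood(res.trees[0], m)
        assert refit.log_likelihood == pytest.approx(res.score, abs=1e-6)


class TestBootstrap:
    def test_perfect_signal_gives_full_support(self):
        # 50 copies of a character set that cleanly defines one topology
        base = np.array([
            [1, 1, 0],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 1],
        ])
        cells = np.tile(base, (1, 50))
        m = TaxonAreaMatrix(
            list("ABCDE"), [f"s{j}" for j in range(cells.shape[1])], cells
        )
        cfg = SearchConfig(objective="parsimony", n_starts=3,
                           bootstrap_replicates=20, seed=8)
        tree, supports = bootstrap(m, cfg)
        assert supports
        assert all(v == 100.0 for v in supports.values())

    def test_trivial_splits_absent(self):
        rng = np.random.default_rng(35)
        m = random_matrix(rng, 5, 40)
        cfg = SearchConfig(objective="parsimony", n_starts=2,
                           bootstrap_replicates=10, seed=9)
        _, supports = bootstrap(m, cfg)
        for bp in supports:
            assert 2 <= len(bp) <= m.n_areas - 2

    def test_determinism(self):
        rng = np.random.default_rng(37)
        m = random_matrix(rng, 5, 30)
        cfg = SearchConfig(objective="parsimony", n_starts=2,
                           bootstrap_replicates=10, seed=11)
        t1, s1 = bootstrap(m, cfg)
        t2, s2 = bootstrap(m, cfg)
        assert s1 == s2 and t1.newick() == t2.newick()
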