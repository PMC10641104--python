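"""Evolution-strategy operators and the full search loop."""

import numpy as np
import pytest

from phyloes import (DistanceMatrix, ESConfig, Individual, TreeCode,
                     all_codes, bme_length, decode, encode, generate_tree,
                     individual_replacement, matched_budget_comparison,
                     random_code, rf_distance, run_phyloes, run_ri,
                     truncation_select)
from phyloes.errors import ConfigError
from phyloes.simulate import SyntheticSpec, random_additive_matrix

from conftest import euclidean_matrix


def make_ind(code, length):
    return Individual(code, decode(code), length)


class TestESConfig:
    def test_default_schedule(self):
        cfg = ESConfig()
        assert [cfg.size_at(g) for g in (0, 4, 5, 24, 25, 100)] == \
            [64, 64, 32, 32, 16, 16]

    def test_invalid_configs(self):
        with pytest.raises(ConfigError):
            ESConfig(maxiter=0)
        with pytest.raises(ConfigError):
            ESConfig(tol=-1e-9)
        with pytest.raises(ConfigError):
            ESConfig(schedule=((16, 5), (32, None)))  # increasing sizes
        with pytest.raises(ConfigError):
            ESConfig(schedule=((16, 5),))  # no open-ended entry


class TestGenerateTree:
    def test_identical_parents_reproduce_exactly(self, rng):
        code = TreeCode(5, (3, 5))
        pop = [make_ind(code, 1.0)] * 4
        for _ in range(10):
            assert generate_tree(pop, rng) == code

    def test_degenerate_component(self, rng):
        pop = [make_ind(TreeCode(5, (1, 3)), 1.0),
               make_ind(TreeCode(5, (1, 5)), 2.0)]
        for _ in range(20):
            assert generate_tree(pop, rng).h[0] == 1

    def test_componentwise_uniform_sampling(self):
        rng = np.random.default_rng(8)
        pop = [make_ind(TreeCode(5, (1, 3)), 1.0),
               make_ind(TreeCode(5, (3, 5)), 2.0)]
        counts = {}
        draws = 40000
        for _ in range(draws):
            h = generate_tree(pop, rng).h
            counts[h] = counts.get(h, 0) + 1
        expected_support = {(1, 3), (1, 5), (3, 3), (3, 5)}
        assert set(counts) == expected_support
        # each combination ~ Binomial(draws, 1/4); 3 sigma band
        sigma = np.sqrt(draws * 0.25 * 0.75)
        for h in expected_support:
            assert abs(counts[h] - draws / 4) < 3 * sigma

    def test_empty_population(self, rng):
        with pytest.raises(ConfigError):
            generate_tree([], rng)


class TestTruncationSelect:
    def test_keeps_smallest(self):
        pool = [make_ind(TreeCode(4, (h,)), L)
                for h, L in [(1, 3.0), (2, 1.0), (3, 2.0)]]
        chosen = truncation_select(pool, 2)
        assert [ind.length for ind in chosen] == [1.0, 2.0]

    def test_identity_when_mu_equals_size(self):
        pool = [make_ind(TreeCode(4, (h,)), float(h)) for h in (1, 2, 3)]
        assert [i.length for i in truncation_select(pool, 3)] == [1, 2, 3]

    def test_stable_tie_break(self):
        pool = [make_ind(TreeCode(4, (h,)), 1.0) for h in (1, 2, 3)]
        chosen = truncation_select(pool, 2)
        assert [ind.code.h for ind in chosen] == [(1,), (2,)]

    def test_invalid_mu(self):
        with pytest.raises(ConfigError):
            truncation_select([make_ind(TreeCode(4, (1,)), 1.0)], 0)


class TestIndividualReplacement:
    def test_duplicate_worst_replaced_by_second_worst(self):
        pop = [make_ind(TreeCode(4, (1,)), 5.0),
               make_ind(TreeCode(4, (2,)), 5.0),
               make_ind(TreeCode(4, (3,)), 4.0)]
        out = individual_replacement(pop)
        assert sorted(ind.length for ind in out) == [4.0, 4.0, 5.0]
        assert [ind.length for ind in out] == [5.0, 4.0, 4.0]
        # the copy shares the second-worst's code
        assert out[1].code == pop[2].code

    def test_unique_worst_unchanged(self):
        pop = [make_ind(TreeCode(4, (h,)), L)
               for h, L in [(1, 5.0), (2, 4.0), (3, 3.0)]]
        assert individual_replacement(pop) == pop

    def test_all_equal_unchanged(self):
        pop = [make_ind(TreeCode(4, (h,)), 2.0) for h in (1, 2, 3)]
        assert individual_replacement(pop) == pop


class TestRunPhyloes:
    def test_n4_returns_global_optimum(self):
        d = euclidean_matrix(4, 0)
        tree, stats = run_phyloes(d, ESConfig(seed=0))
        best = min(bme_length(d, decode(TreeCode(4, (h,)))) for h in (1, 2, 3))
        assert stats.best_length == pytest.approx(best, abs=0)
        assert stats.stop_reason == "convergence"

    def test_n3_star_immediately(self):
        d = euclidean_matrix(3, 1)
        tree, stats = run_phyloes(d)
        assert tree.edges() == [(1, 4), (2, 4), (3, 4)]
        assert stats.trees_generated == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_n6_matches_exhaustive(self, seed):
        d = euclidean_matrix(6, 50 + seed)
        _, stats = run_phyloes(d, ESConfig(seed=seed))
        exhaustive = min(bme_length(d, decode(c)) for c in all_codes(6))
        assert stats.best_length == pytest.approx(exhaustive, abs=1e-12)

    def test_additive_n20_recovers_generating_tree(self):
        d, gen = random_additive_matrix(SyntheticSpec(n=20, seed=7))
        tree, stats = run_phyloes(d, ESConfig(seed=7))
        assert rf_distance(tree, gen) == 0

    def test_determinism(self):
        d, _ = random_additive_matrix(SyntheticSpec(n=10, seed=5))
        t1, s1 = run_phyloes(d, ESConfig(seed=3))
        t2, s2 = run_phyloes(d, ESConfig(seed=3))
        assert s1.to_json() == s2.to_json()
        assert rf_distance(t1, t2) == 0

    def test_monotone_best_and_stop_reason(self):
        from phyloes import perturb_matrix
        d, _ = random_additive_matrix(SyntheticSpec(n=12, seed=8))
        d = perturb_matrix(d, 0.3, 8)
        _, stats = run_phyloes(d, ESConfig(seed=8))
        bests = [g.best_length for g in stats.generations]
        assert all(b <= a + 1e-15 for a, b in zip(bests, bests[1:]))
        trees = [g.trees_total for g in stats.generations]
        assert all(b >= a for a, b in zip(trees, trees[1:]))
        assert stats.stop_reason in {"convergence", "tolerance", "maxiter"}

    def test_global_optimum_recovery_n7(self):
        # stochastic: the exhaustive optimum is found in >= 9/10 seeds
        d = euclidean_matrix(7, 123)
        exhaustive = min(bme_length(d, decode(c)) for c in all_codes(7))
        hits = sum(
            abs(run_phyloes(d, ESConfig(seed=s))[1].best_length - exhaustive)
            < 1e-12 for s in range(10))
        assert hits >= 9


class TestRunRI:
    def test_budget_one_is_single_restart(self):
        d = euclidean_matrix(8, 9)
        tree, stats = run_ri(d, budget=1, seed=2)
        assert stats.trees_generated == 1
        assert stats.best_length == pytest.approx(bme_length(d, tree))

    def test_mostly_finds_exhaustive_optimum_n6(self):
        d = euclidean_matrix(6, 33)
        exhaustive = min(bme_length(d, decode(c)) for c in all_codes(6))
        hits = sum(abs(run_ri(d, budget=20, seed=s)[1].best_length
                       - exhaustive) < 1e-12 for s in range(5))
        assert hits >= 4
        for s in range(5):
            assert run_ri(d, 20, s)[1].best_length >= exhaustive - 1e-12

    def test_invalid_budget(self):
        with pytest.raises(ConfigError):
            run_ri(euclidean_matrix(5, 0), budget=0)


def test_matched_budget_comparison_harness():
    from phyloes import perturb_matrix
    d, _ = random_additive_matrix(SyntheticSpec(n=10, seed=4))
    d = perturb_matrix(d, 0.2, 4)
    summary = matched_budget_comparison(d, seeds=[0, 1])
    assert len(summary["runs"]) == 2
    for row in summary["runs"]:
        assert row["trees"] >= 1
        assert row["rf_es_vs_ri"] % 2 == 0
    assert summary["es_mean_length"] > 0
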