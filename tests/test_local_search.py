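"""NNI/SPR neighborhoods and the BNNI/BSPR descents."""

import numpy as np
import pytest

from phyloes import (TreeCode, all_codes, bme_length, bnni, bspr, decode,
                     nni_neighbors, random_code, rearrange_tree, rf_distance,
                     same_topology, splits, spr_moves)
from phyloes.errors import InvalidTreeError
from phyloes.local_search import (Rearrangement, SearchCounters,
                                  apply_rearrangement, neighbor_length_delta)
from phyloes.simulate import SyntheticSpec, random_additive_matrix

from conftest import euclidean_matrix, random_tree


def topology_key(tree):
    return frozenset(splits(tree))


class TestNNINeighborhood:
    def test_quartet_gives_other_two_topologies(self):
        tree = decode(TreeCode(4, (1,)))
        (edge,) = tree.internal_edges()
        keys = {topology_key(t) for t in nni_neighbors(tree, edge)}
        others = {topology_key(decode(TreeCode(4, (h,)))) for h in (2, 3)}
        assert keys == others

    def test_rejects_external_edge(self):
        tree = decode(TreeCode(4, (1,)))
        with pytest.raises(InvalidTreeError):
            nni_neighbors(tree, (1, 5))

    def test_neighbors_at_rf_two(self):
        tree = random_tree(5, 0)
        for edge in tree.internal_edges():
            for nb in nni_neighbors(tree, edge):
                nb.validate()
                assert rf_distance(tree, nb) == 2

    @pytest.mark.parametrize("n,seed", [(5, 1), (8, 2), (12, 3), (20, 4)])
    def test_cardinality_two_per_edge(self, n, seed):
        tree = random_tree(n, seed)
        edges = tree.internal_edges()
        assert len(edges) == n - 3
        total = sum(len(nni_neighbors(tree, e)) for e in edges)
        assert total == 2 * (n - 3)


class TestSPRNeighborhood:
    def test_quartet_equals_nni_neighborhood(self):
        tree = decode(TreeCode(4, (1,)))
        spr_keys = {topology_key(apply_rearrangement(tree, mv))
                    for mv in spr_moves(tree)}
        (edge,) = tree.internal_edges()
        nni_keys = {topology_key(t) for t in nni_neighbors(tree, edge)}
        assert spr_keys == nni_keys

    def test_closure_and_novelty(self):
        tree = random_tree(7, 5)
        for mv in spr_moves(tree):
            nb = apply_rearrangement(tree, mv)
            nb.validate()
            assert not same_topology(nb, tree)

    def test_superset_of_nni(self):
        tree = random_tree(6, 9)
        nni_keys = {topology_key(t) for e in tree.internal_edges()
                    for t in nni_neighbors(tree, e)}
        spr_keys = {topology_key(apply_rearrangement(tree, mv))
                    for mv in spr_moves(tree)}
        assert nni_keys < spr_keys


class TestDeltaFormulas:
    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (8, 2), (11, 3)])
    def test_nni_delta_equals_recomputation(self, n, seed):
        tree = random_tree(n, seed)
        d = euclidean_matrix(n, seed).values
        base = bme_length(d, tree)
        for edge in tree.internal_edges():
            for which in (0, 1):
                mv = Rearrangement("nni", edge=edge, which=which)
                direct = bme_length(d, apply_rearrangement(tree, mv)) - base
                assert neighbor_length_delta(tree, d, mv) == \
                    pytest.approx(direct, abs=1e-10)

    @pytest.mark.parametrize("n,seed", [(5, 4), (7, 5), (9, 6)])
    def test_spr_scan_matches_exhaustive_minimum(self, n, seed):
        from phyloes.local_search import _TreeIndex, _spr_scan
        tree = random_tree(n, seed)
        d = euclidean_matrix(n, seed).values
        base = bme_length(d, tree)
        best_delta, best_move = _spr_scan(_TreeIndex(tree, d))
        direct = [bme_length(d, apply_rearrangement(tree, mv)) - base
                  for mv in spr_moves(tree)]
        assert best_delta == pytest.approx(min(min(direct), 0.0), abs=1e-10)
        if best_move is not None:
            applied = bme_length(
                d, apply_rearrangement(tree, best_move)) - base
            assert applied == pytest.approx(best_delta, abs=1e-10)


class TestDescents:
    def test_quartet_additive_recovers_truth(self):
        # additive d from ((1,2),(3,4)); start at ((1,3),(2,4))
        d = np.array([[0, 2, 3, 3], [2, 0, 3, 3],
                      [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float)
        truth = decode(TreeCode(4, (3,)))
        lengths = {h: bme_length(d, decode(TreeCode(4, (h,))))
                   for h in (1, 2, 3)}
        assert min(lengths, key=lengths.get) == 3
        start = decode(TreeCode(4, (1,)))
        assert same_topology(bnni(start, d), truth)

    def test_local_optimum_unchanged(self):
        d, gen = random_additive_matrix(SyntheticSpec(n=8, seed=0))
        opt = rearrange_tree(random_tree(8, 1), d)
        counters = SearchCounters()
        again = bnni(opt, d, counters)
        assert counters.nni_iterations == 0
        assert same_topology(again, opt)
        counters2 = SearchCounters()
        assert same_topology(bspr(opt, d, counters2), opt)
        assert counters2.spr_iterations == 0

    @pytest.mark.parametrize("n,seed", [(8, 10), (12, 11)])
    def test_descent_trace_strictly_decreasing(self, n, seed):
        d = euclidean_matrix(n, seed)
        trace = []
        tree = bnni(random_tree(n, seed), d, trace=trace)
        tree = bspr(tree, d, trace=trace)
        diffs = np.diff(trace)
        # within each descent every accepted move strictly improves; the
        # hand-off from bnni to bspr repeats the same length
        assert all(x < 0 or x == 0 for x in diffs)
        assert sum(x == 0 for x in diffs) <= 1
        assert bme_length(d, tree) == pytest.approx(min(trace), abs=0)

    @pytest.mark.parametrize("n,seed", [(8, 20), (12, 21)])
    def test_returned_tree_is_local_optimum(self, n, seed):
        d = euclidean_matrix(n, seed)
        opt = rearrange_tree(random_tree(n, seed), d)
        L = bme_length(d, opt)
        for edge in opt.internal_edges():
            for nb in nni_neighbors(opt, edge):
                assert bme_length(d, nb) >= L - 1e-10
        for mv in spr_moves(opt):
            assert bme_length(d, apply_rearrangement(opt, mv)) >= L - 1e-10

    def test_bspr_can_beat_nni_optimum(self):
        # hunt a NNI-optimal but not SPR-optimal instance at n=7
        found = False
        for seed in range(60):
            d, _ = random_additive_matrix(SyntheticSpec(n=7, seed=seed))
            from phyloes import perturb_matrix
            d = perturb_matrix(d, 0.4, seed)
            start = random_tree(7, seed + 1000)
            nni_opt = bnni(start, d)
            improved = bspr(nni_opt, d)
            if bme_length(d, improved) < bme_length(d, nni_opt) - 1e-12:
                found = True
                break
        assert found

    def test_multistart_reaches_global_optimum_n6(self):
        d = euclidean_matrix(6, 42)
        exhaustive = min(bme_length(d, decode(c)) for c in all_codes(6))
        best = min(bme_length(d, rearrange_tree(random_tree(6, s), d))
                   for s in range(20))
        assert best == pytest.approx(exhaustive, abs=1e-12)

    def test_rearrange_never_increases_length(self):
        d = euclidean_matrix(10, 77)
        for seed in range(5):
            start = random_tree(10, seed)
            assert bme_length(d, rearrange_tree(start, d)) <= \
                bme_length(d, start) + 1e-15
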