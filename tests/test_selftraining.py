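import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from putsc import dtw_distance, generate_boundary_scenario, make_pu_split
from putsc.selftraining import (
    LabelingTrace,
    PUDataset,
    finalize,
    pu_pairwise_matrix,
    run_pipeline,
    scc,
    st_average_rank,
    st_rank,
    theoretical_speedup,
)


def naive_st_order(pl, u):
    """Reference 1NN self-training that recomputes every DTW from scratch."""
    pl, u = list(pl), list(u)
    remaining = list(range(len(u)))
    order, info = [], []
    while remaining:
        best, best_d = None, np.inf
        for x in remaining:
            d = min(dtw_distance(u[x], p) for p in pl)
            if d < best_d:
                best, best_d = x, d
        order.append(best)
        info.append(best_d)
        remaining.remove(best)
        pl.append(u[best])
    return order, info


class TestStRank:
    def test_singleton_pool(self):
        trace = st_rank(PUDataset(pl=[[0.0, 0.0]], u=[[3.0, 3.0]]))
        assert trace.order.tolist() == [0]
        assert trace.info[0] == pytest.approx(18.0)

    def test_nearest_first_with_updated_labeled_set(self):
        """(1,1) joins first; (10,10) is then scored against it, not the seed."""
        trace = st_rank(PUDataset(pl=[[0, 0]], u=[[10, 10], [1, 1]]))
        assert trace.order.tolist() == [1, 0]
        assert trace.info.tolist() == [2.0, 162.0]

    def test_order_is_a_permutation_of_the_pool(self, rng):
        data = PUDataset(
            pl=[rng.normal(size=5) for _ in range(2)],
            u=[rng.normal(size=5) for _ in range(9)],
        )
        trace = st_rank(data)
        assert sorted(trace.order.tolist()) == list(range(9))

    def test_matches_cache_free_reference(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = PUDataset(
                pl=[rng.normal(size=6) for _ in range(2)],
                u=[rng.normal(size=6) for _ in range(7)],
            )
            trace = st_rank(data, pu_pairwise_matrix(data))
            order, info = naive_st_order(data.pl, data.u)
            assert trace.order.tolist() == order
            assert np.allclose(trace.info, info)

    def test_wrong_matrix_shape_rejected(self):
        data = PUDataset(pl=[[0.0]], u=[[1.0]])
        with pytest.raises(ValueError):
            st_rank(data, np.zeros((3, 3)))


class TestStAverageRank:
    def test_singleton_pool_any_averager(self):
        for averager in ("dba", "euclidean"):
            data = PUDataset(pl=[[0.0, 0.0]], u=[[1.0, 1.0]])
            trace = st_average_rank(data, averager=averager)
            assert trace.order.tolist() == [0]

    def test_euclidean_center_drives_selection(self):
        """Center of {(0,0),(4,4)} is (2,2): (1,1) is closer to it than (10,10)."""
        data = PUDataset(pl=[[0, 0], [4, 4]], u=[[10, 10], [1, 1]])
        trace = st_average_rank(data, averager="euclidean")
        assert trace.order.tolist() == [1, 0]
        # info follows the distance to the nearest labeled series
        assert trace.info[0] == pytest.approx(2.0)

    def test_center_distance_info_variant(self):
        data = PUDataset(pl=[[0, 0], [4, 4]], u=[[10, 10], [1, 1]])
        trace = st_average_rank(data, averager="euclidean", center_distance_info=True)
        assert trace.info[0] == pytest.approx(2.0)  # DTW((1,1),(2,2))
        assert trace.info[1] == pytest.approx(dtw_distance([10, 10], [5 / 3, 5 / 3]))

    def test_identical_seeds_make_average_and_nearest_selection_coincide(self, rng):
        s = rng.normal(size=6)
        data = PUDataset(pl=[s, s.copy(), s.copy()], u=[rng.normal(size=6) for _ in range(5)])
        D = pu_pairwise_matrix(data)
        first_avg = st_average_rank(data, averager="dba", distances=D).order[0]
        first_nn = st_rank(data, D).order[0]
        assert first_avg == first_nn

    def test_singleton_labeled_set_coincides_with_nearest_neighbor_start(self, rng):
        data = PUDataset(pl=[rng.normal(size=6)], u=[rng.normal(size=6) for _ in range(5)])
        D = pu_pairwise_matrix(data)
        assert (
            st_average_rank(data, averager="dba", dba_iterations=1, distances=D).order[0]
            == st_rank(data, D).order[0]
        )

    def test_euclidean_averager_propagates_unequal_length_error(self):
        data = PUDataset(pl=[[0, 0], [1, 2, 3]], u=[[1, 1]])
        with pytest.raises(ValueError):
            st_average_rank(data, averager="euclidean")

    def test_deterministic_given_master_seed(self, rng):
        data = PUDataset(
            pl=[rng.normal(size=6) for _ in range(3)],
            u=[rng.normal(size=6) for _ in range(6)],
        )
        a = st_average_rank(data, master_seed=99)
        b = st_average_rank(data, master_seed=99)
        assert a.order.tolist() == b.order.tolist()
        assert np.array_equal(a.info, b.info)


class TestScc:
    def test_hand_worked_jump_sequence(self):
        """info (1,1,1,9): flat prefixes give 0/0 := 0; the jump at the last
        iteration scores 8 / Std(1,1,1,9) * 1/4 = 0.5 with sample Std 4."""
        res = scc([1, 1, 1, 9])
        assert np.isnan(res.values[0])
        assert res.values[1] == 0.0 and res.values[2] == 0.0
        assert res.values[3] == pytest.approx(0.5)
        assert res.argmax_iteration == 4 and res.stop == 3

    def test_constant_info_stops_immediately(self):
        res = scc([3.0, 3.0, 3.0, 3.0, 3.0])
        assert np.all(res.values[1:] == 0.0)
        assert res.argmax_iteration == 2 and res.stop == 1

    def test_jump_always_has_positive_std(self):
        """Std(info(1..i)) includes info(i), so any nonzero jump has a
        positive denominator: the statistic stays finite on real traces."""
        res = scc([2.0, 2.0, 5.0, 4.0])
        assert np.all(np.isfinite(res.values[1:]))
        assert res.values[2] == pytest.approx(3 / np.std([2, 2, 5], ddof=1) * 2 / 4)

    def test_population_std_flavor(self):
        res = scc([1, 1, 1, 9], std_flavor="population")
        # population Std(1,1,1,9) = sqrt(12) ~ 3.464
        assert res.values[3] == pytest.approx(8 / np.sqrt(12) * 0.25)

    def test_older_minus2_rule(self):
        assert scc([1, 1, 1, 9], stop_rule="minus2").stop == 2

    def test_argmax_tie_prefers_smallest_iteration(self):
        # all-zero statistic values tie; the earliest iteration wins
        res = scc([4.0, 4.0, 4.0])
        assert res.argmax_iteration == 2 and res.stop == 1

    def test_stop_always_in_valid_range(self, rng):
        for _ in range(100):
            info = rng.exponential(size=rng.integers(2, 30))
            res = scc(info)
            assert 1 <= res.stop <= len(info) - 1

    def test_too_short_info_rejected(self):
        with pytest.raises(ValueError):
            scc([1.0])


class TestFinalize:
    def _trace(self, order):
        return LabelingTrace(np.array(order), np.zeros(len(order)))

    def test_full_stop_leaves_no_negatives(self):
        res = finalize(self._trace([2, 0, 1]), 3, ["seedA"], pool=list("xyz"))
        assert res.negative == [] and len(res.positive) == 4

    def test_zero_stop_keeps_only_seeds(self):
        res = finalize(self._trace([2, 0, 1]), 0, ["seedA"], pool=list("xyz"))
        assert res.positive == ["seedA"] and len(res.negative) == 3

    def test_worked_pool_of_eleven_with_stop_four(self):
        """3 seeds, 11 pool members, stop 4: 7 positives and 7 negatives."""
        res = finalize(self._trace(list(range(11))), 4, ["a", "b", "c"], pool=list(range(11)))
        assert len(res.positive) == 7 and len(res.negative) == 7

    def test_out_of_range_stop_rejected(self):
        with pytest.raises(ValueError):
            finalize(self._trace([0, 1]), 3, [])

    @settings(max_examples=100, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=30),
        pl_n=st.integers(min_value=1, max_value=5),
        data=st.data(),
    )
    def test_partition_conserves_every_instance(self, n, pl_n, data):
        """positive and negative always partition seeds + pool exactly."""
        stop = data.draw(st.integers(min_value=0, max_value=n))
        order = data.draw(st.permutations(list(range(n))))
        pool = [f"u{i}" for i in range(n)]
        seeds = [f"p{i}" for i in range(pl_n)]
        res = finalize(self._trace(list(order)), stop, seeds, pool=pool)
        assert sorted(res.positive + res.negative) == sorted(seeds + pool)
        assert len(res.negative) == n - stop
        assert set(res.positive) & set(res.negative) == set()


class TestBoundaryScenarioBehaviour:
    def test_first_selection_contrast_under_boundary_seeding(self):
        """With an adjacent decoy negative, the 1NN rule's first pick is a
        negative in at least half of 20 initializations while the
        barycenter rule's first pick is a positive."""
        st_first, avg_first = [], []
        for seed in range(20):
            ds = generate_boundary_scenario(seed=seed)
            split = make_pu_split(ds, seed=1000 + seed, boundary_seed=True)
            D = pu_pairwise_matrix(split)
            st_first.append(split.truth[st_rank(split, D).order[0]])
            avg_first.append(
                split.truth[st_average_rank(split, distances=D, master_seed=seed).order[0]]
            )
        assert np.mean(np.array(st_first) == 0) >= 0.5
        assert np.mean(np.array(avg_first) == 1) >= 0.5


class TestPipeline:
    def test_unknown_method_rejected(self, rng):
        data = PUDataset(pl=[rng.normal(size=4)], u=[rng.normal(size=4) for _ in range(3)])
        with pytest.raises(ValueError):
            run_pipeline(data, "st-mdl")

    def test_predicted_labels_match_trace_cut(self, rng):
        data = PUDataset(
            pl=[rng.normal(size=5) for _ in range(2)],
            u=[rng.normal(size=5) for _ in range(8)],
        )
        res = run_pipeline(data, "st-scc")
        stop = res.scc_result.stop
        assert res.predicted.sum() == stop
        assert set(np.flatnonzero(res.predicted)) == set(res.trace.order[:stop])
        assert len(res.labeling.positive) == 2 + stop


def test_theoretical_speedup_is_iterations_plus_one():
    """Recomputing an I-pass barycenter every labeling step costs (I+1)x the
    table-driven 1NN loop; at the default I = 15 the ratio is 16."""
    assert theoretical_speedup(15) == 16
    assert theoretical_speedup(1) == 2
    with pytest.raises(ValueError):
        theoretical_speedup(0)
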