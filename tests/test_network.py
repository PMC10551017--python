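"""Pearson connectivity: matrix correctness, pair calls, stratification, ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurograft import (
    CorrelationResult,
    InsufficientDataError,
    LabelingError,
    PreprocessParams,
    ProcessedTraceSet,
    RawTraceSet,
    build_network,
    call_correlated_pairs,
    pair_fractions,
    pearson_matrix,
    preprocess,
    similarity_matrix_ordering,
    simulate_traces,
    SimConfig,
)
from oracles import pearson_bf


def _pts(arrays, compartments=None, degenerate=()):
    """Wrap plain arrays as a ProcessedTraceSet for correlation-stage tests."""
    return ProcessedTraceSet(
        traces={i: np.asarray(a, dtype=float) for i, a in enumerate(arrays)},
        params=PreprocessParams(),
        degenerate_rois=frozenset(degenerate),
        compartment_of=compartments or {i: "host" for i in range(len(arrays))},
    )


class TestPearsonMatrix:
    def test_identical_traces_r_one(self):
        x = np.random.default_rng(0).random(30)
        res = pearson_matrix(_pts([x, x.copy()]))
        assert res.r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_exact_anticorrelation(self):
        x = np.random.default_rng(1).random(30)
        res = pearson_matrix(_pts([x, 1.0 - x]))
        assert res.r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_four_point_closed_form(self):
        res = pearson_matrix(_pts([[0, 1, 2, 3], [0, 1, 1, 2]]))
        assert res.r[0, 1] == pytest.approx(3 / np.sqrt(10), rel=1e-12)

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(100):
            t = int(rng.integers(4, 51))
            x, y = rng.random(t), rng.random(t)
            res = pearson_matrix(_pts([x, y]))
            assert res.r[0, 1] == pytest.approx(
                pearson_bf(list(x), list(y)), rel=1e-12, abs=1e-12
            )

    @given(
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=-50.0, max_value=50.0),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        g = np.random.default_rng(seed)
        x, y = g.random(25), g.random(25)
        r0 = pearson_matrix(_pts([x, y])).r[0, 1]
        r1 = pearson_matrix(_pts([a * x + b, y])).r[0, 1]
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_degenerate_rois_omitted(self):
        g = np.random.default_rng(2)
        res = pearson_matrix(_pts([g.random(20), np.zeros(20), g.random(20)], degenerate=[1]))
        assert res.roi_ids == [0, 2]

    def test_fewer_than_two_usable_raises(self):
        with pytest.raises(InsufficientDataError):
            pearson_matrix(_pts([np.zeros(20), np.random.default_rng(0).random(20)], degenerate=[0]))


class TestCallCorrelatedPairs:
    def _result(self, r01, r02, r12):
        r = np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
        return CorrelationResult(roi_ids=[0, 1, 2], r=r)

    def test_all_zero_gives_empty_set(self):
        assert call_correlated_pairs(self._result(0.0, 0.0, 0.0)) == frozenset()

    def test_threshold_is_strict(self):
        assert call_correlated_pairs(self._result(0.1, 0.0, 0.0)) == frozenset()
        assert call_correlated_pairs(self._result(0.1 + 1e-12, 0.0, 0.0)) == {(0, 1)}

    def test_negative_correlations_never_qualify(self):
        assert call_correlated_pairs(self._result(0.5, 0.05, -0.8)) == {(0, 1)}


class TestPairFractions:
    def test_forced_counting_example(self):
        # 3 host ROIs mutually correlated, 2 implant ROIs correlated to nothing
        r = np.eye(5)
        r[np.ix_([0, 1, 2], [0, 1, 2])] = 1.0
        res = CorrelationResult(roi_ids=[0, 1, 2, 3, 4], r=r)
        call_correlated_pairs(res)
        comp = {0: "host", 1: "host", 2: "host", 3: "implant", 4: "implant"}
        rep = pair_fractions(res, comp)
        assert rep.classes["host-host"] == {
            "n_possible": 3, "n_correlated": 3, "fraction_pct": 100.0}
        assert rep.classes["host-implant"]["n_possible"] == 6
        assert rep.classes["host-implant"]["fraction_pct"] == 0.0
        assert rep.classes["implant-implant"] == {
            "n_possible": 1, "n_correlated": 0, "fraction_pct": 0.0}

    def test_everything_correlated_every_class_100(self):
        r = np.ones((4, 4))
        res = CorrelationResult(roi_ids=[0, 1, 2, 3], r=r)
        call_correlated_pairs(res)
        rep = pair_fractions(res, {0: "host", 1: "host", 2: "implant", 3: "implant"})
        assert all(v["fraction_pct"] == 100.0 for v in rep.classes.values())

    def test_possible_pairs_sum_to_n_choose_2_random_labelings(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            r = np.eye(n)
            res = CorrelationResult(roi_ids=list(range(n)), r=r)
            call_correlated_pairs(res)
            labels = {i: str(rng.choice(["host", "implant"])) for i in range(n)}
            rep = pair_fractions(res, labels)
            total = sum(v["n_possible"] for v in rep.classes.values())
            assert total == n * (n - 1) // 2
            assert all(0.0 <= v["fraction_pct"] <= 100.0 for v in rep.classes.values())

    def test_missing_label_raises(self):
        res = CorrelationResult(roi_ids=[0, 1], r=np.eye(2))
        call_correlated_pairs(res)
        with pytest.raises(LabelingError):
            pair_fractions(res, {0: "host"})

    def test_layer_labels_supported(self):
        res = CorrelationResult(roi_ids=[0, 1, 2], r=np.eye(3))
        call_correlated_pairs(res)
        rep = pair_fractions(res, {0: "upper", 1: "deep", 2: "deep"})
        assert set(rep.classes) == {"upper-upper", "deep-upper", "deep-deep"}


class TestSimilarityOrdering:
    def test_noise_free_communities_block_diagonal(self):
        cfg = SimConfig(
            n_host=4, n_implant=2, n_frames=150,
            communities=[((0, 1, 4), 0.08), ((2, 3), 0.06)],
            background_event_rate=0.0, noise_sd=0.0, seed=5,
        )
        raw, truth = simulate_traces(cfg)
        processed = preprocess(raw)
        res = pearson_matrix(processed)
        order, mat = similarity_matrix_ordering(res)
        # members of each planted community are contiguous in the ordering
        for cid in (0, 1):
            members = {k for k, c in truth.community_of.items() if c == cid}
            pos = sorted(order.index(m) for m in members if m in order)
            assert pos == list(range(pos[0], pos[0] + len(pos)))
        # the reordered block of the first community is all ones
        first = [order[i] for i in range(3)]
        if set(first) <= set(truth.community_of):
            np.testing.assert_allclose(mat[:3, :3], 1.0, atol=1e-10)

    def test_permutation_is_a_permutation(self, random_raw):
        res = pearson_matrix(preprocess(random_raw))
        order, mat = similarity_matrix_ordering(res)
        assert sorted(order) == sorted(res.roi_ids)
        assert mat.shape == res.r.shape

    def test_planted_three_communities_contiguity(self):
        """At moderate noise, >= 90% of community members sit adjacent to a
        same-community member in the ordering."""
        cfg = SimConfig(
            n_host=18, n_implant=12, n_frames=300,
            communities=[(tuple(range(0, 6)), 0.08),
                         (tuple(range(6, 12)), 0.08),
                         (tuple(range(18, 24)), 0.08)],
            background_event_rate=0.02, noise_sd=4.0, seed=21,
        )
        raw, truth = simulate_traces(cfg)
        res = pearson_matrix(preprocess(raw))
        order, _ = similarity_matrix_ordering(res)
        members = [k for k in order if k in truth.community_of]
        ok = 0
        for k in members:
            i = order.index(k)
            neighbours = [order[j] for j in (i - 1, i + 1) if 0 <= j < len(order)]
            if any(truth.community_of.get(nb) == truth.community_of[k] for nb in neighbours):
                ok += 1
        assert ok / len(members) >= 0.9


class TestBuildNetwork:
    def test_empty_pairs_edgeless_graph(self):
        res = CorrelationResult(roi_ids=[0, 1, 2], r=np.eye(3))
        call_correlated_pairs(res)
        g = build_network(res, {i: (float(i), 0.0) for i in range(3)})
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_fully_correlated_complete_graph(self):
        res = CorrelationResult(roi_ids=[0, 1, 2, 3], r=np.ones((4, 4)))
        call_correlated_pairs(res)
        g = build_network(res, {i: (0.0, float(i)) for i in range(4)})
        assert g.number_of_edges() == 6

    def test_edge_count_matches_pair_calls(self, planted_raw):
        _, raw, _ = planted_raw
        processed = preprocess(raw)
        res = pearson_matrix(processed)
        pairs = call_correlated_pairs(res)
        g = build_network(res, processed.centroid_of, processed.compartment_of)
        assert g.number_of_edges() == len(pairs)
        for i, j, data in g.edges(data=True):
            assert data["r"] > 0.1
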