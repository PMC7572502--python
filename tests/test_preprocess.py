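import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from metabostate.preprocess import (
    combine_datasets,
    drop_replicates,
    floor_and_log,
    one_vs_one_splits,
    percentile_normalize,
    prevalence_filter,
)
from metabostate.tables import ValidationError
from tests.conftest import make_table


class TestFloorAndLog:
    @pytest.mark.parametrize("raw,expected", [(0.0, 0.0), (0.3, 0.0), (1.0, 0.0), (1024.0, 10.0)])
    def test_examples(self, raw, expected):
        t = make_table([[raw], [2.0], [4.0]], [0, 0, 1])
        assert floor_and_log(t).values[0, 0] == pytest.approx(expected)

    def test_negative_raises(self):
        t = make_table([[-1.0], [2.0]], [0, 1])
        with pytest.raises(ValidationError, match="non-negative"):
            floor_and_log(t)

    def test_single_application_enforced(self):
        # reapplying would re-floor logged values; the provenance flag blocks it
        t = make_table([[0.5], [8.0]], [0, 1])
        once = floor_and_log(t)
        with pytest.raises(ValidationError, match="already applied"):
            floor_and_log(once)


class TestPercentileNormalize:
    def test_mean_rank_examples(self):
        # controls (log) 1..4; queries 2.5 -> 50, 5 -> 100, 0 -> 0
        vals = [[1.0], [2.0], [3.0], [4.0], [2.5], [5.0], [0.0]]
        t = make_table(vals, [0, 0, 0, 0, 1, 1, 1])
        out = percentile_normalize(t, per_batch=False)
        assert out.values[4, 0] == pytest.approx(50.0)
        assert out.values[5, 0] == pytest.approx(100.0)
        assert out.values[6, 0] == pytest.approx(0.0)

    def test_all_tied_controls(self):
        t = make_table([[3.0], [3.0], [3.0], [3.0]], [0, 0, 0, 1])
        out = percentile_normalize(t, per_batch=False)
        assert out.values[3, 0] == pytest.approx(50.0)

    def test_control_self_mean_is_50(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(size=(20, 5)), [0] * 12 + [1] * 8)
        out = percentile_normalize(t, per_batch=False)
        ctrl = out.values[np.asarray(t.labels) == 0]
        assert np.allclose(ctrl.mean(axis=0), 50.0, atol=1e-9)

    # integer-valued intensities keep the monotone transforms injective in
    # float arithmetic (e.g. 3x+7 collapses ulp-scale differences otherwise)
    @settings(max_examples=25, deadline=None)
    @given(hnp.arrays(np.float64, (9, 3), elements=st.integers(1, 10**6).map(float)))
    def test_rank_invariance_and_bounds(self, raw):
        labels = [0, 0, 0, 0, 1, 1, 1, 1, 1]
        base = percentile_normalize(make_table(raw, labels), per_batch=False)
        # strictly increasing transforms leave the output bit-identical
        for f in (lambda x: np.log1p(x), lambda x: 3.0 * x + 7.0):
            trans = percentile_normalize(make_table(f(raw), labels), per_batch=False)
            assert np.array_equal(base.values, trans.values)
        assert base.values.min() >= 0.0 and base.values.max() <= 100.0

    def test_per_batch_independent(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(10, 1, size=(12, 2))
        raw[6:] += 100.0  # huge batch offset
        labels = [0, 0, 0, 1, 1, 1] * 2
        batches = ["A"] * 6 + ["B"] * 6
        out = percentile_normalize(make_table(raw, labels, batches=batches))
        # batch offset removed: distribution of percentiles comparable across batches
        assert abs(out.values[:6].mean() - out.values[6:].mean()) < 25.0

    def test_batch_without_controls_raises(self):
        t = make_table([[1.0], [2.0], [3.0], [4.0]], [0, 0, 1, 1], batches=["A", "A", "B", "B"])
        with pytest.raises(ValidationError, match="B"):
            percentile_normalize(t)


class TestPrevalenceFilter:
    def test_rare_feature_dropped(self):
        vals = np.ones((100, 2))
        vals[1:, 0] = 0.0  # feature 0 detected in 1/100 samples
        t = make_table(vals, [0] * 50 + [1] * 50)
        out = prevalence_filter(t, 0.05)
        assert list(out.feature_ids) == ["F0001"]

    def test_common_feature_kept(self):
        vals = np.zeros((100, 1))
        vals[:6, 0] = 5.0
        t = make_table(vals, [0] * 50 + [1] * 50)
        assert prevalence_filter(t, 0.05).n_features == 1

    def test_zero_threshold_drops_only_all_missing(self):
        vals = np.zeros((10, 2))
        vals[0, 1] = 2.0
        t = make_table(vals, [0] * 5 + [1] * 5)
        out = prevalence_filter(t, 0.0)
        assert list(out.feature_ids) == ["F0001"]


class TestCombineDatasets:
    def test_concatenates_features_over_shared_samples(self):
        rng = np.random.default_rng(0)
        a = make_table(rng.normal(size=(50, 10)), [0] * 25 + [1] * 25)
        b = make_table(rng.normal(size=(50, 20)), [0] * 25 + [1] * 25)
        out = combine_datasets([a, b], names=["pos", "neg"])
        assert out.values.shape == (50, 30)
        assert out.feature_ids[0].startswith("pos:")
        assert out.feature_ids[-1].startswith("neg:")

    def test_single_table_identity_values(self):
        a = make_table(np.arange(8.0).reshape(4, 2), [0, 0, 1, 1])
        out = combine_datasets([a])
        assert np.array_equal(np.sort(out.values, axis=0), np.sort(a.values, axis=0))

    def test_label_conflict_raises(self):
        a = make_table([[1.0], [2.0]], [0, 1])
        b = make_table([[1.0], [2.0]], [1, 0])
        with pytest.raises(ValidationError, match="conflicting labels"):
            combine_datasets([a, b])

    def test_combine_commutes_with_one_vs_one(self):
        rng = np.random.default_rng(3)
        labels = [0] * 4 + [1] * 4 + [2] * 4
        a = make_table(rng.normal(size=(12, 3)), labels)
        b = make_table(rng.normal(size=(12, 5)), labels)
        combined_then_split = one_vs_one_splits(combine_datasets([a, b]))
        split_then_combined = [
            combine_datasets(list(pair))
            for pair in zip(one_vs_one_splits(a), one_vs_one_splits(b))
        ]
        for t1, t2 in zip(combined_then_split, split_then_combined):
            assert np.array_equal(t1.labels, t2.labels)
            assert np.allclose(t1.values, t2.values)


class TestOneVsOne:
    @pytest.mark.parametrize("k,expected", [(3, 3), (5, 10)])
    def test_pair_count(self, k, expected):
        labels = np.repeat(np.arange(k), 4)
        t = make_table(np.random.default_rng(0).normal(size=(4 * k, 2)), labels)
        assert len(one_vs_one_splits(t)) == expected

    def test_binary_passthrough_and_relabeling(self):
        t = make_table(np.ones((6, 1)), [0, 0, 0, 1, 1, 1])
        assert one_vs_one_splits(t) == [t]
        t3 = make_table(np.ones((9, 1)), [1, 1, 1, 2, 2, 2, 3, 3, 3])
        for sub in one_vs_one_splits(t3):
            assert set(sub.labels) == {0, 1}

    def test_single_class_raises(self):
        t = make_table(np.ones((3, 1)), [1, 1, 1])
        with pytest.raises(ValidationError, match="2 classes"):
            one_vs_one_splits(t)


class TestDropReplicates:
    def test_first_by_sorted_id_kept(self):
        t = make_table(np.arange(8.0).reshape(4, 2), [0, 0, 1, 1])
        rep = {"S0000": "a", "S0001": "a", "S0002": "a", "S0003": "b"}
        out = drop_replicates(t, rep)
        assert list(out.sample_ids) == ["S0000", "S0003"]
        assert np.array_equal(out.values, drop_replicates(t, rep).values)

    def test_identity_when_all_distinct(self):
        t = make_table(np.ones((3, 1)), [0, 0, 1])
        rep = {s: s for s in t.sample_ids}
        assert list(drop_replicates(t, rep).sample_ids) == list(t.sample_ids)

    def test_uncovered_sample_raises(self):
        t = make_table(np.ones((2, 1)), [0, 1])
        with pytest.raises(ValidationError, match="missing"):
            drop_replicates(t, {"S0000": "a"})
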