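import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations
from scipy.stats import rankdata

from metabostate.adducts import ExplanationMap
from metabostate.stats import (
    RegimeSpec,
    apply_regime,
    bh_fdr,
    enrichment_factor,
    mwu_test,
    select_feature_ids,
    significance_on_training_fold,
    significance_table,
)
from metabostate.tables import ValidationError
from tests.conftest import make_table


def bh_oracle(p):
    """Step-up BH from first principles: q_i = min_{j>=rank(i)} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


def mwu_exact_oracle(x, y):
    """Two-sided exact MW-U by full enumeration of rank assignments."""
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    us = np.array([
        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        for idx in combinations(range(n1 + n2), n1)
    ])
    return u_obs, float(np.mean(np.abs(us - center) >= abs(u_obs - center) - 1e-12))


class TestMWU:
    def test_extreme_arrangement_exact(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_symmetry_two_sided(self):
        x, y = [1.0, 5.0, 2.0], [3.0, 8.0, 9.0, 0.5]
        assert mwu_test(x, y)[1] == pytest.approx(mwu_test(y, x)[1])

    def test_all_tied_p_one(self):
        _, p = mwu_test([2.0] * 10, [2.0] * 10)
        assert p == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError, match="non-empty"):
            mwu_test([], [1.0])

    @pytest.mark.parametrize("n1", range(1, 7))
    @pytest.mark.parametrize("n2", range(1, 7))
    def test_exact_branch_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            u, p = mwu_test(x, y)
            u_or, p_or = mwu_exact_oracle(x, y)
            assert u == pytest.approx(u_or)
            assert p == pytest.approx(p_or, abs=1e-12)


class TestBHFDR:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.005, 0.04, 0.8], [0.015, 0.06, 0.8]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_examples(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            bh_fdr([0.2, 1.5])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    def test_matches_step_up_oracle(self, p):
        assert np.max(np.abs(bh_fdr(p) - bh_oracle(p))) <= 1e-12

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=50))
    def test_adding_smaller_p_never_raises_q(self, p):
        q_before = bh_fdr(p)
        q_after = bh_fdr(list(p) + [min(p) / 2])[: len(p)]
        assert np.all(q_after <= q_before + 1e-12)


class TestEnrichment:
    @pytest.mark.parametrize(
        "x,y,expected",
        [([1, 2, 3], [1, 2, 3], 1.0), ([1, 2], [2, 4], 2.0), ([1, 3], [2, 6], 2.0)],
    )
    def test_ratio(self, x, y, expected):
        assert enrichment_factor(x, y) == pytest.approx(expected)

    def test_zero_control_mean_flagged_nan(self):
        assert np.isnan(enrichment_factor([0.0, 0.0], [1.0, 2.0]))


class TestSignificanceTable:
    def test_single_feature_q_equals_exact_p(self):
        # m = 1: BH correction is the identity; perfect separation
        t = make_table([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]], [0, 0, 0, 1, 1, 1])
        sig = significance_on_training_fold(t)
        assert sig["q_value"].iloc[0] == pytest.approx(sig["p_value"].iloc[0])
        assert sig["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_constant_feature_q_one(self):
        vals = np.column_stack([np.ones(20), np.random.default_rng(0).normal(size=20)])
        sig = significance_table(vals, [0] * 10 + [1] * 10, ["c", "n"])
        assert sig.loc["c", "q_value"] == pytest.approx(1.0)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.normal(size=(30, 40)), [0] * 15 + [1] * 15)
        sig = significance_on_training_fold(t)
        assert np.all(sig["q_value"] >= sig["p_value"] - 1e-15)
        assert np.array_equal(sig["significant"], sig["q_value"] < 0.05)

    def test_global_null_rarely_discovers(self):
        # BH controls the FDR: under a global null, any discovery is rare
        rng = np.random.default_rng(2)
        n_any = 0
        reps = 40
        for _ in range(reps):
            vals = rng.normal(size=(40, 50))
            sig = significance_table(vals, [0] * 20 + [1] * 20, range(50))
            n_any += sig["significant"].any()
        assert n_any / reps <= 0.15

    def test_single_class_raises(self):
        t = make_table(np.ones((4, 2)), [1, 1, 1, 1])
        with pytest.raises(ValidationError, match="two classes"):
            significance_on_training_fold(t)


class TestRegimes:
    @pytest.fixture
    def sig_fixture(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(40, 10))
        vals[20:, :3] += 4.0  # 3 clearly shifted features
        t = make_table(vals, [0] * 20 + [1] * 20)
        sig = significance_on_training_fold(t)
        assert set(sig.index[sig["significant"]]) == {"F0000", "F0001", "F0002"}
        return t, sig

    def test_topk_caps_at_available(self, sig_fixture):
        # fewer significant features than k: all of them are used
        t, sig = sig_fixture
        out = apply_regime(t, sig, RegimeSpec("top_k_significant", k=5))
        assert out.n_features == 3

    def test_partition(self, sig_fixture):
        t, sig = sig_fixture
        kept_sig = set(select_feature_ids(sig, RegimeSpec("significant_only")))
        kept_non = set(select_feature_ids(sig, RegimeSpec("nonsignificant_only")))
        assert kept_sig | kept_non == set(t.feature_ids)
        assert not kept_sig & kept_non

    def test_empty_results_are_legal(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(size=(20, 5)), [0] * 10 + [1] * 10)
        sig = significance_on_training_fold(t)
        assert not sig["significant"].any()
        assert apply_regime(t, sig, RegimeSpec("significant_only")).n_features == 0

    def test_satellite_removal_subsets_nonsignificant(self, sig_fixture):
        t, sig = sig_fixture
        nonsig_ids = select_feature_ids(sig, RegimeSpec("nonsignificant_only"))
        emap = ExplanationMap(links=(("F0000", str(nonsig_ids[0]), "1x13C"),))
        spec = RegimeSpec("nonsignificant_no_satellites", explanation_map=emap)
        kept = set(select_feature_ids(sig, spec))
        assert kept == set(nonsig_ids) - {str(nonsig_ids[0])}

    @pytest.mark.parametrize(
        "kwargs", [{"kind": "top_k_significant"}, {"kind": "nonsignificant_no_satellites"},
                   {"kind": "bogus"}, {"kind": "all", "explanation_map": ExplanationMap(links=())}],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValidationError):
            RegimeSpec(**kwargs)

    def test_misaligned_significance_raises(self, sig_fixture):
        t, sig = sig_fixture
        with pytest.raises(ValidationError, match="aligned"):
            apply_regime(t.select_features(t.feature_ids[:5]), sig, RegimeSpec("all"))
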