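"""Unit and property tests for the weighted step-up procedures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wfdr import (
    EndpointTable,
    WeightScheme,
    hwf_test,
    normalize_weights,
    wbh_adjust,
    weighted_simes,
    wfdr_realized,
)

from conftest import bh_oracle, random_table, simes_loop_oracle


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

class TestEndpointTable:
    def test_counts_and_masks(self, posaconazole):
        assert posaconazole.n_primary == 1
        assert posaconazole.n_secondary == 6
        assert posaconazole.m == 7
        assert posaconazole.primary_mask.sum() == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_values=[0.5, 1.5], weights=[1, 1]),  # p out of range
            dict(p_values=[0.5, 0.5], weights=[-1, 1]),  # negative weight
            dict(p_values=[0.5, 0.5], weights=[0, 0]),  # all-zero weights
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EndpointTable(
                ids=("a", "b"), levels=("primary", "secondary"), **kwargs
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            EndpointTable(
                ids=("a", "a"),
                levels=("primary", "secondary"),
                p_values=[0.1, 0.2],
                weights=[1, 1],
            )

    def test_weight_scheme_ratios(self, posaconazole):
        ws = WeightScheme.from_table(posaconazole)
        assert ws.R == 3.0
        assert ws.R_prime == pytest.approx(3.0 / 6.0)  # R/S for P=1, equal ws


class TestNormalizeWeights:
    def test_posaconazole_relative_weights(self, posaconazole):
        norm = normalize_weights(posaconazole)
        assert norm.weights.sum() == pytest.approx(7.0, rel=1e-12)
        # as fractions of the level-1 total: intersection 6/9, primary 3/9
        w_p = posaconazole.weights[posaconazole.primary_mask][0]
        w_star = posaconazole.weights[posaconazole.secondary_mask].sum()
        assert w_star / (w_star + w_p) == pytest.approx(6 / 9)
        assert w_p / (w_star + w_p) == pytest.approx(3 / 9)

    def test_equal_weights_become_unity(self):
        t = EndpointTable.from_pvalues([0.1], [0.2, 0.3], R=1)
        t2 = EndpointTable(t.ids, t.levels, t.p_values, t.weights * 7.3)
        norm = normalize_weights(t2)
        assert np.allclose(norm.weights, 1.0)

    def test_sum_equals_m(self):
        t = EndpointTable(
            ids=("a", "b", "c"),
            levels=("primary", "secondary", "secondary"),
            p_values=[0.1, 0.2, 0.3],
            weights=[2.0, 1.0, 1.0],
        )
        norm = normalize_weights(t)
        assert np.allclose(norm.weights, [1.5, 0.75, 0.75])


# ---------------------------------------------------------------------------
# weighted Simes
# ---------------------------------------------------------------------------

class TestWeightedSimes:
    def test_posaconazole_intersection(self, posaconazole):
        sec = posaconazole.secondary_mask
        p_star = weighted_simes(
            posaconazole.p_values[sec], posaconazole.weights[sec]
        )
        assert p_star == pytest.approx(0.006)  # attained at rank 1: 0.001*6/1

    def test_single_pvalue_is_identity(self):
        assert weighted_simes([0.37], [2.5]) == pytest.approx(0.37)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_equal_weights_match_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(200):
            p = rng.random(n)
            assert weighted_simes(p, np.ones(n)) == pytest.approx(
                simes_loop_oracle(p)
            )

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_invariance(self, data):
        n = data.draw(st.integers(2, 10))
        p = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        )
        w = data.draw(
            st.lists(st.floats(0.1, 10, allow_nan=False), min_size=n, max_size=n)
        )
        perm = data.draw(st.permutations(range(n)))
        a = weighted_simes(p, w)
        b = weighted_simes([p[i] for i in perm], [w[i] for i in perm])
        assert a == pytest.approx(b)
        assert 0 <= a <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_simes([], [])


# ---------------------------------------------------------------------------
# weighted BH
# ---------------------------------------------------------------------------

class TestWbhAdjust:
    def test_posaconazole_rejections_and_thresholds(self, posaconazole):
        out = wbh_adjust(posaconazole, q=0.05)
        assert sorted(out.rejected_ids) == ["S1", "S2", "S3"]
        assert out.k == 3
        # the sorted prefix is pure secondary, so critical values are 0.05*i/9
        f = out.frame.set_index("id")
        for i, sid in enumerate(["S1", "S2", "S3"], start=1):
            assert f.loc[sid, "threshold"] == pytest.approx(0.05 * i / 9)

    def test_single_hypothesis_reduces_to_level(self):
        t = EndpointTable(("a",), ("primary",), [0.05], [1.0])
        assert wbh_adjust(t, 0.05).n_rejected == 1  # p == q is rejected
        t2 = EndpointTable(("a",), ("primary",), [0.050001], [1.0])
        assert wbh_adjust(t2, 0.05).n_rejected == 0

    def test_equal_weights_equal_textbook_bh(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = rng.integers(1, 51)
            t = random_table(rng, m, equal_weights=True)
            mine = wbh_adjust(t, 0.05).frame["rejected"].to_numpy()
            assert np.array_equal(mine, bh_oracle(t.p_values, 0.05))

    def test_stepup_set_property(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = random_table(rng, int(rng.integers(2, 30)))
            out = wbh_adjust(t, 0.1)
            rej = out.frame["rejected"].to_numpy()
            if rej.any():
                pk = t.p_values[rej].max()
                assert np.array_equal(rej, t.p_values <= pk)

    def test_monotone_in_q_and_p(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = random_table(rng, 15)
            small = wbh_adjust(t, 0.02).frame["rejected"].to_numpy()
            large = wbh_adjust(t, 0.10).frame["rejected"].to_numpy()
            assert not np.any(small & ~large)  # enlarging q never shrinks
            # decreasing one p-value never shrinks the rejection set
            i = rng.integers(t.m)
            p2 = t.p_values.copy()
            p2[i] *= 0.5
            t2 = EndpointTable(t.ids, t.levels, p2, t.weights)
            shrunk = wbh_adjust(t2, 0.10).frame["rejected"].to_numpy()
            assert not np.any(large & ~shrunk)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        for c in (0.01, 3.0, 1e4):
            t = random_table(rng, 12)
            t2 = EndpointTable(t.ids, t.levels, t.p_values, t.weights * c)
            a = wbh_adjust(t, 0.05).frame["rejected"].to_numpy()
            b = wbh_adjust(t2, 0.05).frame["rejected"].to_numpy()
            assert np.array_equal(a, b)

    def test_tied_pvalues_share_fate(self):
        t = EndpointTable(
            ids=("a", "b", "c", "d"),
            levels=("primary",) + ("secondary",) * 3,
            p_values=[0.01, 0.01, 0.01, 0.9],
            weights=[1.0, 1.0, 1.0, 1.0],
        )
        rej = wbh_adjust(t, 0.05).frame["rejected"]
        assert rej.tolist() == [True, True, True, False]

    def test_zero_weight_hypothesis_can_ride_along(self):
        # a zero-weight hypothesis adds nothing to thresholds but is
        # rejected when a later cumulative threshold covers its p-value
        t = EndpointTable(
            ids=("z", "a", "b"),
            levels=("secondary",) * 3,
            p_values=[0.001, 0.002, 0.003],
            weights=[0.0, 1.0, 1.0],
        )
        out = wbh_adjust(t, 0.05)
        assert out.frame["rejected"].all()

    def test_invalid_q(self, posaconazole):
        with pytest.raises(ValueError):
            wbh_adjust(posaconazole, 0.0)


# ---------------------------------------------------------------------------
# hierarchical procedure
# ---------------------------------------------------------------------------

class TestHwfTest:
    def test_posaconazole_worked_example(self, posaconazole):
        out = hwf_test(posaconazole, alpha=0.0317)
        inter = out.intersection
        assert inter.p_star == pytest.approx(0.006)
        assert inter.threshold == pytest.approx(0.0317 * 6 / 9)
        assert inter.rejected
        f = out.frame.set_index("id")
        assert not f.loc["P1", "rejected"]  # 0.07 > alpha
        assert out.n_rejected_secondary() == 3  # p <= 0.0317*3/6

    def test_natalizumab_worked_example(self, natalizumab_synthetic):
        out = hwf_test(natalizumab_synthetic, alpha=0.0257)
        assert out.intersection.p_star == pytest.approx(0.0015725)
        assert out.intersection.rejected
        assert not out.frame.set_index("id").loc["P1", "rejected"]
        assert out.n_rejected_secondary() == 12

    def test_all_pvalues_one_rejects_nothing(self):
        t = EndpointTable.from_pvalues([1.0], [1.0, 1.0, 1.0], R=2)
        for alpha in (0.01, 0.2, 0.99):
            assert hwf_test(t, alpha).n_rejected == 0

    def test_gating_secondaries_require_open_gate(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            t = random_table(rng, int(rng.integers(3, 12)))
            out = hwf_test(t, 0.05)
            sec_rej = out.n_rejected_secondary()
            if not out.intersection.rejected:
                assert sec_rej == 0

    def test_requires_secondary(self):
        t = EndpointTable(("a",), ("primary",), [0.01], [1.0])
        with pytest.raises(ValueError, match="secondary"):
            hwf_test(t, 0.05)

    def test_intersection_not_counted_as_discovery(self, posaconazole):
        out = hwf_test(posaconazole, alpha=0.0317)
        assert set(out.frame["id"]) == set(posaconazole.ids)
        assert out.n_rejected == out.n_rejected_secondary()  # primary not rejected

    def test_scale_invariance(self, posaconazole):
        t2 = EndpointTable(
            posaconazole.ids,
            posaconazole.levels,
            posaconazole.p_values,
            posaconazole.weights * 17.0,
        )
        a = hwf_test(posaconazole, 0.0317).frame["rejected"]
        b = hwf_test(t2, 0.0317).frame["rejected"]
        assert a.tolist() == b.tolist()


# ---------------------------------------------------------------------------
# realized wFDR
# ---------------------------------------------------------------------------

class TestWfdrRealized:
    def test_no_rejections_zero(self):
        t = EndpointTable.from_pvalues([0.9], [0.9], R=1)
        out = wbh_adjust(t, 0.05)
        assert wfdr_realized(out, {"P1": True, "S1": True}) == 0.0

    def test_weighted_proportion(self):
        t = EndpointTable(
            ids=("a", "b"),
            levels=("primary", "secondary"),
            p_values=[0.001, 0.001],
            weights=[2.0, 1.0],
        )
        out = wbh_adjust(t, 0.05)
        assert out.n_rejected == 2
        assert wfdr_realized(out, {"a": True, "b": False}) == pytest.approx(2 / 3)

    def test_all_false_rejections_zero_error(self):
        t = EndpointTable.from_pvalues([0.001], [0.001, 0.002], R=2)
        out = wbh_adjust(t, 0.05)
        assert out.n_rejected == 3
        truth = {i: False for i in t.ids}
        assert wfdr_realized(out, truth) == 0.0

    def test_mismatched_ids_error(self):
        t = EndpointTable.from_pvalues([0.5], [0.5], R=1)
        out = wbh_adjust(t, 0.05)
        with pytest.raises(ValueError, match="missing"):
            wfdr_realized(out, {"P1": True})
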