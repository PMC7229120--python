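"""Registration, coding labels, stay-active accounting, rate matching,
spatial correlations and lag-wise testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import splitscope as sc
from splitscope import longitudinal as lng
from splitscope import placecells as pc
from splitscope._util import RegistrationError


def _roi(xy, ori=None):
    xy = np.asarray(xy, dtype=float)
    ori = np.zeros(len(xy)) if ori is None else np.asarray(ori, dtype=float)
    return pd.DataFrame({"neuron_id": np.arange(len(xy)),
                         "x_um": xy[:, 0], "y_um": xy[:, 1],
                         "orientation_deg": ori})


class TestRegistration:
    def test_identity_tables_identity_mapping(self):
        roi = _roi([[10, 10], [50, 50], [90, 10]], [10, 100, 170])
        reg = lng.register_sessions(roi, roi)
        assert len(reg.matches) == 3
        assert np.allclose(reg.matches["distance_um"], 0.0)
        assert list(reg.matches["idx_a"]) == list(reg.matches["idx_b"])

    def test_translation_beyond_ceiling_no_matches(self):
        roi_a = _roi([[10, 10], [50, 50]])
        roi_b = _roi([[30, 10], [70, 50]])       # shifted 20 um
        reg = lng.register_sessions(roi_a, roi_b, max_dist_um=5.0)
        assert len(reg.matches) == 0

    def test_scale_mismatch_raises(self):
        roi_a = _roi([[10, 10]])
        roi_b = _roi([[10, 10]])
        roi_a.attrs["scale"] = "um"
        roi_b.attrs["scale"] = "px"
        with pytest.raises(RegistrationError):
            lng.register_sessions(roi_a, roi_b)

    def test_jittered_recovery_against_ground_truth(self):
        """Jitter far below nearest-neighbor spacing: >= 99% correct."""
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 600, size=(250, 2))
        roi_a = _roi(base + rng.normal(0, 1.0, base.shape))
        roi_b = _roi(base + rng.normal(0, 1.0, base.shape))
        reg = lng.register_sessions(roi_a, roi_b)
        correct = (reg.matches["idx_a"] == reg.matches["idx_b"]).mean()
        assert len(reg.matches) >= 0.97 * 250
        assert correct >= 0.99

    def test_mapping_one_to_one(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 200, size=(80, 2))
        reg = lng.register_sessions(_roi(base), _roi(base + rng.normal(0, 1, base.shape)))
        assert reg.matches["idx_a"].is_unique
        assert reg.matches["idx_b"].is_unique


class TestRegistrationQc:
    def test_preserved_orientations_pass(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 400, size=(60, 2))
        ori = rng.uniform(0, 180, 60)
        roi_a = _roi(base, ori)
        roi_b = _roi(base + rng.normal(0, 1, base.shape),
                     np.mod(ori + rng.normal(0, 3, 60), 180))
        reg = lng.register_sessions(roi_a, roi_b)
        reg = lng.registration_qc(reg, roi_a, roi_b, n_shuffles=1000, seed=1)
        assert reg.qc_verdict == "pass"
        assert reg.qc_report["p"] < 0.05

    def test_random_matching_fails(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0, 400, size=(60, 2))
        roi_a = _roi(base, rng.uniform(0, 180, 60))
        roi_b = _roi(base + rng.normal(0, 1, base.shape),
                     rng.uniform(0, 180, 60))    # unrelated orientations
        reg = lng.register_sessions(roi_a, roi_b)
        reg = lng.registration_qc(reg, roi_a, roi_b, n_shuffles=1000, seed=2)
        assert reg.qc_verdict == "fail"

    def test_too_few_matches_indeterminate(self):
        roi = _roi([[10, 10], [60, 60]])
        reg = lng.register_sessions(roi, roi)
        reg = lng.registration_qc(reg, roi, roi, seed=3)
        assert reg.qc_verdict == "indeterminate"


class TestCodingLabels:
    def test_rule_order(self):
        labels = lng.assign_coding_labels(
            splitter_flags=[True, False, False, False, False],
            place_flags=[True, True, True, False, False],
            stem_active=[True, True, False, True, False])
        assert list(labels) == ["splitter", "stem_pc", "arm_pc",
                                "stem_npc", "arm_npc"]

    def test_partition_over_random_flags(self):
        rng = np.random.default_rng(7)
        s, p, a = (rng.random(200) < 0.2, rng.random(200) < 0.5,
                   rng.random(200) < 0.5)
        labels = lng.assign_coding_labels(s, p, a)
        assert labels.isin(lng.LABELS).all()
        assert (labels[s] == "splitter").all()


class TestStayActive:
    def _registry(self, matched_a, n=20):
        m = pd.DataFrame({"idx_a": matched_a, "idx_b": matched_a,
                          "distance_um": 0.0, "d_orientation_deg": 0.0})
        return lng.NeuronRegistry(m, n, n)

    def test_probability_arithmetic(self):
        # 10 splitters, 7 matched -> 0.7
        labels = pd.Series(["splitter"] * 10 + ["arm_pc"] * 10)
        reg = self._registry(list(range(7)) + list(range(10, 14)))
        table = lng.stay_active_probability(reg, labels, np.full(20, 10), 1)
        row = table[table["class"] == "splitter"].iloc[0]
        assert row["probability"] == pytest.approx(0.7)
        assert row["included"]

    def test_small_class_excluded(self):
        labels = pd.Series(["splitter"] * 3 + ["arm_pc"] * 10)
        reg = self._registry(list(range(13)), n=13)
        table = lng.stay_active_probability(reg, labels, np.full(13, 10), 1)
        assert not table[table["class"] == "splitter"]["included"].iloc[0]

    def test_low_event_neurons_not_in_base(self):
        labels = pd.Series(["splitter"] * 10)
        events = np.r_[np.full(5, 10), np.full(5, 4)]   # 5 below threshold
        reg = self._registry(list(range(10)), n=10)
        table = lng.stay_active_probability(reg, labels, events, 1)
        assert table.iloc[0]["n_class_session1"] == 5


class TestEventRateMatch:
    def test_worked_greedy_trace(self):
        # rates {1,2,3} vs reference mean 2.5 -> drop the 1, stop at mean 2.5
        out = lng.event_rate_match({"splitter": [2.5, 2.5],
                                    "arm_pc": [1.0, 2.0, 3.0]})
        assert list(out["arm_pc"]) == [False, True, True]

    def test_already_above_no_drops(self):
        out = lng.event_rate_match({"splitter": [1.0, 2.0],
                                    "arm_pc": [5.0, 6.0]})
        assert out["arm_pc"].all()

    def test_equal_rates_no_drops(self):
        out = lng.event_rate_match({"splitter": [2.0, 2.0],
                                    "arm_pc": [2.0, 2.0],
                                    "stem_pc": [2.0]})
        assert all(mask.all() for mask in out.values())

    def test_unmatchable_class_empties(self):
        out = lng.event_rate_match({"splitter": [10.0], "arm_pc": [1.0, 2.0]})
        assert not out["arm_pc"].any()

    @given(st.lists(st.floats(0.1, 50), min_size=1, max_size=12),
           st.lists(st.floats(0.1, 50), min_size=1, max_size=12))
    def test_postcondition_property(self, ref, other):
        out = lng.event_rate_match({"splitter": ref, "arm_pc": other})
        assert out["splitter"].all()        # reference never dropped
        kept = np.asarray(other)[out["arm_pc"]]
        if kept.size:
            assert (kept.mean() >= np.mean(ref) - 1e-9
                    or out["arm_pc"].all())


class TestSpatialCorrelation:
    def _map(self, rate, visited=None):
        rate = np.asarray(rate, dtype=float)
        visited = np.ones_like(rate, bool) if visited is None else visited
        return pc.SmoothedMap(rate, visited, 1.0,
                              np.arange(rate.shape[1] + 1.0),
                              np.arange(rate.shape[0] + 1.0))

    def test_identical_maps_rho_one(self):
        rng = np.random.default_rng(8)
        m = self._map(rng.random((4, 5)))
        reg = TestStayActive()._registry([0], n=1)
        df = lng.spatial_correlation_across_sessions({0: m}, {0: m}, reg)
        assert df["rho"].iloc[0] == pytest.approx(1.0)

    def test_monotone_rescaling_invariant(self):
        rng = np.random.default_rng(9)
        rate = rng.random((4, 5))
        m1 = self._map(rate)
        m2 = self._map(rate ** 3 * 7.0)
        reg = TestStayActive()._registry([0], n=1)
        df = lng.spatial_correlation_across_sessions({0: m1}, {0: m2}, reg)
        assert df["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(10)
        reg = TestStayActive()._registry(list(range(80)), n=80)
        ma = {i: self._map(rng.random((6, 6))) for i in range(80)}
        mb = {i: self._map(rng.random((6, 6))) for i in range(80)}
        df = lng.spatial_correlation_across_sessions(ma, mb, reg)
        assert abs(df["rho"].mean()) < 0.08

    def test_few_mutual_bins_skipped(self):
        visited = np.zeros((4, 5), bool)
        visited[0, :3] = True
        m1 = self._map(np.random.default_rng(1).random((4, 5)), visited)
        m2 = self._map(np.random.default_rng(2).random((4, 5)))
        reg = TestStayActive()._registry([0], n=1)
        df = lng.spatial_correlation_across_sessions({0: m1}, {0: m2}, reg)
        assert np.isnan(df["rho"].iloc[0])
        assert "mutually visited" in df["reason"].iloc[0]


class TestLagComparison:
    def test_identical_samples_not_significant(self):
        pairs = pd.DataFrame({"day_lag": [1] * 8,
                              "splitter_value": [0.5] * 8,
                              "other_value": [0.5] * 8})
        out = lng.lag_comparison_test(pairs)
        assert not out["significant"].any()
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_uniformly_greater_significant_after_correction(self):
        rng = np.random.default_rng(11)
        rows = []
        for lag in (1, 2, 3):
            for _ in range(20):
                b = rng.uniform(0.3, 0.5)
                rows.append({"day_lag": lag, "splitter_value": b + 0.25,
                             "other_value": b})
        out = lng.lag_comparison_test(pd.DataFrame(rows))
        assert out["significant"].all()

    def test_family_is_tested_lags_only(self):
        rows = ([{"day_lag": 1, "splitter_value": 0.9, "other_value": 0.2}] * 6
                + [{"day_lag": 30, "splitter_value": 0.9, "other_value": 0.2}] * 6
                + [{"day_lag": 2, "splitter_value": 0.5, "other_value": 0.4}] * 3)
        out = lng.lag_comparison_test(pd.DataFrame(rows), n_lags=15)
        assert not out.loc[out["day_lag"] == 30, "tested"].iloc[0]   # beyond family
        assert not out.loc[out["day_lag"] == 2, "tested"].iloc[0]    # too few pairs
        assert out["tested"].sum() == 1

    def test_sign_test_option(self):
        pairs = pd.DataFrame({"day_lag": [1] * 10,
                              "splitter_value": np.linspace(0.6, 0.9, 10),
                              "other_value": np.linspace(0.2, 0.5, 10)})
        out = lng.lag_comparison_test(pairs, test="sign")
        assert out["p"].iloc[0] == pytest.approx(0.5 ** 10, rel=1e-6)
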