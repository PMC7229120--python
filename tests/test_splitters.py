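"""Tuning-curve arithmetic, permutation test (vs enumeration oracle),
splitter criteria, trajectory metrics, ANOVA confound check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import splitscope as sc
from splitscope import behavior as beh, splitters as spl
from splitscope._util import InsufficientDataError, InsufficientTrialsError
from conftest import make_stem_session


class TestTuningCurves:
    def test_single_bin_rate_arithmetic(self):
        # 1 bin, 1 L trial with 2 active frames in 0.5 s occupancy -> 4 /s
        counts = np.zeros((1, 2, 1))
        counts[0, 0, 0] = 2          # left trial
        raster, trace, trials, geom = make_stem_session(
            counts, ["L", "R"], occupancy_frames=10, fps=20.0)
        tun = spl.stem_tuning_curves(raster, trace, trials, geometry=geom)
        assert tun.tc_left[0, 0] == pytest.approx(4.0)
        assert tun.tc_right[0, 0] == pytest.approx(0.0)

    def test_zero_event_neuron_zero_curves(self):
        counts = np.zeros((1, 4, 3))
        raster, trace, trials, geom = make_stem_session(
            counts, ["L", "R", "L", "R"], occupancy_frames=2)
        tun = spl.stem_tuning_curves(raster, trace, trials, geometry=geom)
        assert np.all(tun.tc_left == 0) and np.all(tun.tc_right == 0)

    def test_occupancy_scaling_halves_rates(self):
        counts = np.ones((1, 4, 2))
        r1 = make_stem_session(counts, list("LRLR"), occupancy_frames=2)
        r2 = make_stem_session(counts, list("LRLR"), occupancy_frames=4)
        t1 = spl.stem_tuning_curves(r1[0], r1[1], r1[2], geometry=r1[3])
        t2 = spl.stem_tuning_curves(r2[0], r2[1], r2[2], geometry=r2[3])
        assert np.allclose(t2.tc_left, 0.5 * t1.tc_left)
        assert np.allclose(t2.tc_right, 0.5 * t1.tc_right)

    def test_single_direction_raises(self):
        counts = np.zeros((1, 3, 2))
        raster, trace, trials, geom = make_stem_session(
            counts, ["L", "L", "L"], occupancy_frames=2)
        trials["correct"] = True
        with pytest.raises(InsufficientTrialsError):
            spl.stem_tuning_curves(raster, trace, trials, geometry=geom)


class TestPermutationTest:
    def test_identical_rasters_never_significant(self):
        # all trials identical -> real difference 0 everywhere, ties count
        # against significance
        counts = np.tile(np.array([1, 0, 2]), (1, 6, 1))
        raster, trace, trials, geom = make_stem_session(
            counts, list("LRLRLR"), occupancy_frames=3)
        tun = spl.stem_tuning_curves(raster, trace, trials, geometry=geom)
        sig, rel = spl.permutation_test(tun, n_shuffles=200, seed=1)
        assert np.all(rel == 0.0)
        assert not sig.any()

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo p-values on 3L+3R instances agree with brute-force
        enumeration of all 20 label assignments within |dp| < 0.04."""
        rng = np.random.default_rng(42)
        counts = rng.poisson(1.2, size=(4, 6, 4)).astype(float)
        raster, trace, trials, geom = make_stem_session(
            counts, list("LLLRRR"), occupancy_frames=4)
        tun = spl.stem_tuning_curves(raster, trace, trials, geometry=geom)
        _, rel = spl.permutation_test(tun, n_shuffles=1000, seed=2)
        for n in range(4):
            exact = spl.exhaustive_permutation_reliability(tun, neuron=n)
            assert np.all(np.abs(rel[n] - exact) < 0.04)

    def test_too_few_trials_raises(self):
        counts = np.zeros((1, 3, 2))
        raster, trace, trials, geom = make_stem_session(
            counts, ["L", "R", "R"], occupancy_frames=2)
        tun = spl.stem_tuning_curves(raster, trace, trials, geometry=geom)
        with pytest.raises(InsufficientTrialsError):
            spl.permutation_test(tun, n_shuffles=10, seed=0)


class TestClassifier:
    @pytest.mark.parametrize("n_sig, n_trials, expected", [
        (3, 5, True),        # both thresholds met
        (2, 20, False),      # too few significant bins
        (10, 4, False),      # too few stem-event trials
    ])
    def test_threshold_rule(self, n_sig, n_trials, expected):
        mask = np.zeros((1, 12), dtype=bool)
        mask[0, :n_sig] = True
        assert spl.classify_splitter(mask, [n_trials]) is expected


class TestMetrics:
    @pytest.mark.parametrize("tc_l, tc_r, expected", [
        ([2.0, 1.0], [2.0, 1.0], 0.0),       # identical non-zero curves
        ([1.0, 0.0], [0.0, 1.0], 1.0),       # disjoint support
        ([2.0, 1.0], [1.0, 1.0], 0.2),       # worked value 1/5
    ])
    def test_discriminability_worked_values(self, tc_l, tc_r, expected):
        assert spl.discriminability(tc_l, tc_r) == pytest.approx(expected)

    def test_discriminability_all_zero_sentinel(self):
        assert np.isnan(spl.discriminability([0.0, 0.0], [0.0, 0.0]))

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_discriminability_scale_invariant(self, scale):
        tc_l = np.array([1.0, 3.0, 0.5])
        tc_r = np.array([2.0, 0.0, 0.5])
        d0 = spl.discriminability(tc_l, tc_r)
        d1 = spl.discriminability(scale * tc_l, scale * tc_r)
        assert d1 == pytest.approx(d0)
        assert 0.0 <= d1 <= 1.0

    def test_reliability_summary(self):
        mean, peak = spl.reliability_summary([0.2, 1.0, 0.6])
        assert mean == pytest.approx(0.6)
        assert peak == pytest.approx(1.0)
        assert spl.reliability_summary([0.0, 0.0]) == (0.0, 0.0)

    @pytest.mark.parametrize("tc_l, tc_r, expected", [
        ([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], 0.0),     # identical ranks
        ([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], 2.0),     # reversed ranks
        ([1.0, 2.0, 3.0], [2.0, 1.0, 3.0], 0.5),     # hand-computed rho=0.5
    ])
    def test_one_minus_rho(self, tc_l, tc_r, expected):
        assert spl.tuning_correlation_metric(tc_l, tc_r) == pytest.approx(expected)

    def test_one_minus_rho_constant_curve_sentinel(self):
        assert np.isnan(spl.tuning_correlation_metric([1, 1, 1], [1, 2, 3]))

    def test_splitting_extent_uses_valid_bins(self):
        sig = np.array([[True, True, False, False]])
        valid = np.array([True, True, True, False])
        assert spl.splitting_extent(sig, valid) == pytest.approx(2 / 3)


class TestDiscriminabilityMonotonicity:
    def test_increases_with_modulation_ratio(self, geometry):
        """Mean splitter discriminability grows with the generator's
        modulation ratio (checked in expectation over ratios 1, 2, 4)."""
        means = []
        for ratio in (1.0, 2.0, 4.0):
            cfg = sc.SynthConfig(n_neurons=40, frac_splitter=1.0,
                                 frac_stem_pc=0, frac_arm_pc=0,
                                 modulation_ratio=ratio, n_trials=40,
                                 error_rate=0.0, seed=31)
            (b,), _ = sc.generate_experiment(cfg)
            trace = beh.label_sections(
                beh.align_behavior_to_imaging(b.behavior, b.raster.frame_times),
                geometry)
            trials = beh.parse_trials(trace, geometry)
            tun = spl.stem_tuning_curves(b.raster, trace, trials)
            d = spl.discriminability(tun.tc_left, tun.tc_right, tun.valid)
            means.append(np.nanmean(d))
        assert means[0] < means[1] < means[2]


class TestAnovaCheck:
    def _biased_session(self, seed):
        cfg = sc.SynthConfig(n_neurons=1, n_trials=60, error_rate=0.0,
                             lateral_turn_bias_cm=1.5, frac_splitter=0,
                             frac_stem_pc=1.0, frac_arm_pc=0, seed=seed)
        (b,), _ = sc.generate_experiment(cfg)
        geom = sc.MazeGeometry()
        trace = beh.label_sections(
            beh.align_behavior_to_imaging(b.behavior, b.raster.frame_times), geom)
        trials = beh.parse_trials(trace, geom)
        return b, trace, trials, geom

    def test_lateral_confound_not_confirmed(self):
        """A neuron driven purely by lateral position looks trajectory-
        dependent to the permutation test (lateral position covaries with
        turn) but the ANOVA with lateral as covariate rejects it."""
        b, trace, trials, geom = self._biased_session(seed=41)
        rng = np.random.default_rng(7)
        lat = trace["lateral_position"].to_numpy()
        on_stem = trace["section"].to_numpy() == "stem"
        p = np.clip(0.25 * (lat + 2.5) / 5.0, 0.0, 0.9) * on_stem
        events = (rng.random(len(trace)) < p).astype(np.uint8)
        confirmed, table, _ = spl.anova_covariate_check(
            events, trace, trials, 20.0, geometry=geom)
        assert not confirmed

    def test_genuine_splitter_confirmed(self):
        b, trace, trials, geom = self._biased_session(seed=43)
        rng = np.random.default_rng(8)
        on_stem = trace["section"].to_numpy() == "stem"
        is_left_frame = np.zeros(len(trace), dtype=bool)
        for _, tr in trials.iterrows():
            if tr["turn"] == "L":
                is_left_frame[tr["start"]:tr["end"] + 1] = True
        p = np.where(is_left_frame, 0.35, 0.05) * on_stem
        events = (rng.random(len(trace)) < p).astype(np.uint8)
        confirmed, _, _ = spl.anova_covariate_check(
            events, trace, trials, 20.0, geometry=geom)
        assert confirmed

    def test_constant_covariate_dropped(self):
        counts = np.random.default_rng(3).poisson(1.0, (1, 8, 5)).astype(float)
        raster, trace, trials, geom = make_stem_session(
            counts, list("LRLRLRLR"), occupancy_frames=4)
        # speed and lateral are constant in the hand-built session
        confirmed, table, dropped = spl.anova_covariate_check(
            raster.events[0], trace, trials, 20.0, geometry=geom,
            n_lengthwise_bins=5)
        assert set(dropped) == {"speed", "lateral"}


class TestPerformanceCorrelation:
    def test_perfect_correlation(self):
        m = [0.5, 0.6, 0.7, 0.8]
        r, p = spl.correlate_metric_with_performance(m, m)
        assert r == pytest.approx(1.0)

    def test_independent_metric_near_zero(self):
        rng = np.random.default_rng(11)
        m = rng.random(400)
        perf = rng.random(400)
        r, _ = spl.correlate_metric_with_performance(m, perf)
        assert abs(r) < 0.15

    def test_per_mouse_level_aggregates(self):
        m = [0.1, 0.3, 0.8, 0.6, 0.5, 0.5]
        perf = [0.5, 0.7, 0.9, 0.7, 0.6, 0.8]
        mice = ["a", "a", "b", "b", "c", "c"]
        r, p = spl.correlate_metric_with_performance(m, perf, mice, level="mice")
        # three per-mouse means: (0.2,0.6), (0.7,0.8), (0.5,0.7)
        exp_r = np.corrcoef([0.2, 0.7, 0.5], [0.6, 0.8, 0.7])[0, 1]
        assert r == pytest.approx(exp_r)

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            spl.correlate_metric_with_performance([0.1, 0.2], [0.3, 0.4])
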