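"""Modulation ratio, latency, kinematic regression, and group comparisons."""
import numpy as np
import pytest

from pcsacc.popmetrics import (cohen_d, compare_groups, kinematic_regression,
                               modulation_ratio, normalized_population_sdf,
                               response_latency)
from pcsacc.synthgen import CellConfig, simulate_pc
from pcsacc.types import CellRecording, SaccadeEvent, TrialRecord


def _trials_with_saccades(n, rng, condition_split=True):
    trials = []
    t = 1.0
    for i in range(n):
        cond = "pro" if (i % 2 == 0 or not condition_split) else "anti"
        tr = TrialRecord(i, cond, i % 8, 8.0, t, t + 0.4, t + 0.5, 0.4,
                         t_end=t + 1.3, outcome="correct")
        onset = t + 0.5 + 0.2
        amp = float(rng.uniform(3, 13))
        dur = 0.02 + 0.004 * amp
        tr.ground_truth_saccade = SaccadeEvent(
            onset=onset, offset=onset + dur, amplitude=amp,
            peak_velocity=1.875 * amp / dur, duration=dur, direction=0.0)
        trials.append(tr)
        t += 3.0
    return trials


class TestModulationRatio:
    def test_deterministic_arithmetic(self):
        """pro 80 spks/s vs anti 64 spks/s in the window -> ratio 1.25."""
        rng = np.random.default_rng(0)
        trials = _trials_with_saccades(2, rng)
        spikes = []
        for t in trials:
            onset = t.ground_truth_saccade.onset
            n = 12 if t.condition == "pro" else 9   # over 0.15 s: 80 and 60
            spikes.append(onset + np.linspace(0.001, 0.149, n))
        cell = CellRecording("c", "medial", np.sort(np.concatenate(spikes)),
                             np.array([]), trials=trials)
        assert modulation_ratio(cell) == pytest.approx(80.0 / 60.0)

    def test_condition_gain_recovered(self, scored_trials_10):
        cfg = CellConfig(baseline_rate_ss=60.0, condition_gain=1.4)
        ratios = [modulation_ratio(simulate_pc(scored_trials_10, cfg, s))
                  for s in range(6)]
        assert np.mean(ratios) == pytest.approx(1.4, rel=0.05)

    def test_unit_centred_when_no_condition_effect(self, scored_trials_10):
        ratios = np.array([modulation_ratio(simulate_pc(
            scored_trials_10, CellConfig(baseline_rate_ss=60.0), 50 + s))
            for s in range(20)])
        se = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.0) < 3 * se


class TestLatency:
    def test_peak_at_84_ms(self):
        rng = np.random.default_rng(1)
        trials = _trials_with_saccades(60, rng)
        spikes = []
        for t in trials:
            onset = t.ground_truth_saccade.onset
            base = rng.uniform(-0.4, 0.4, 20) + onset
            burst = onset + 0.084 + rng.normal(0, 0.01, 12)
            spikes.extend([base, burst])
        cell = CellRecording("c", "medial", np.sort(np.concatenate(spikes)),
                             np.array([]), trials=trials)
        res = response_latency(cell, "facilitation")
        assert res.latency == pytest.approx(0.084, abs=0.010)
        assert not res.at_boundary

    def test_generator_latency_recovered(self, make_scored_trials):
        trials = make_scored_trials(n_blocks=13, seed=61)
        cfg = CellConfig(baseline_rate_ss=60.0, saccade_profile="facilitation",
                         saccade_gain=40.0, saccade_latency=0.120)
        cell = simulate_pc(trials, cfg, 5)
        res = response_latency(cell, "facilitation")
        assert res.latency == pytest.approx(0.120, abs=0.015)

    def test_monotone_decay_flags_boundary_for_suppression(self):
        rng = np.random.default_rng(2)
        trials = _trials_with_saccades(60, rng)
        spikes = []
        for t in trials:
            onset = t.ground_truth_saccade.onset
            n = rng.poisson(30)
            # density decaying after onset: trough at the window end
            spikes.append(onset + 0.35 * rng.random(n) ** 2)
        cell = CellRecording("c", "medial", np.sort(np.concatenate(spikes)),
                             np.array([]), trials=trials)
        res = response_latency(cell, "suppression")
        assert res.at_boundary

    def test_flat_cell_latency_undefined(self):
        rng = np.random.default_rng(3)
        trials = _trials_with_saccades(10, rng)
        cell = CellRecording("c", "medial", np.array([]), np.array([]), trials=trials)
        assert response_latency(cell, "facilitation") is None


class TestKinematicRegression:
    def _amplitude_coupled_cell(self, rng, gain=5.0, n=400):
        trials = _trials_with_saccades(n, rng)
        spikes = []
        for t in trials:
            onset = t.ground_truth_saccade.onset
            lam = gain * t.ground_truth_saccade.amplitude * 0.15
            k = rng.poisson(lam)
            spikes.append(onset + rng.uniform(0, 0.15, k))
        return CellRecording("c", "medial", np.sort(np.concatenate(spikes)),
                             np.array([]), trials=trials)

    def test_constructed_coupling_recovered(self):
        rng = np.random.default_rng(4)
        cell = self._amplitude_coupled_cell(rng)
        fit = kinematic_regression([cell], "amplitude")[0]
        assert fit.r > 0.5
        assert fit.slope == pytest.approx(5.0, rel=0.10)
        assert fit.corrected_rates is not None

    def test_null_coupling_calibrated(self, scored_trials_10):
        flat = CellConfig(baseline_rate_ss=60.0)
        cells = [simulate_pc(scored_trials_10, flat, 700 + s) for s in range(60)]
        fits = kinematic_regression(cells, "amplitude")
        rate = np.mean([f.p < 0.05 for f in fits])
        assert rate <= 0.15

    def test_constant_rate_undefined(self):
        rng = np.random.default_rng(5)
        trials = _trials_with_saccades(20, rng)
        spikes = [t.ground_truth_saccade.onset + np.linspace(0.01, 0.14, 9)
                  for t in trials]
        cell = CellRecording("c", "medial", np.sort(np.concatenate(spikes)),
                             np.array([]), trials=trials)
        fit = kinematic_regression([cell], "amplitude")[0]
        assert np.isnan(fit.r)

    def test_unknown_kinematic_rejected(self):
        with pytest.raises(ValueError):
            kinematic_regression([], "velocity_profile")


class TestCompareGroups:
    def test_identical_groups_null(self):
        a = np.arange(10.0)
        res = compare_groups(a, a.copy(), "ranksum")
        assert res.p > 0.5
        assert res.cohen_d == pytest.approx(0.0)
        res2 = compare_groups(a, a.copy(), "signed_rank")
        assert res2.p == pytest.approx(1.0)

    def test_chi2_proportions_closed_form(self):
        """2x2 [[3,37],[11,27]] gives uncorrected chi2 = 6.09 by the standard
        n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) formula."""
        res = compare_groups([3, 37], [11, 27], "chi2_proportions")
        assert res.statistic == pytest.approx(6.087, abs=0.01)
        assert res.p < 0.05

    def test_ranksum_power_on_unit_shift(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(500):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            hits += compare_groups(a, b, "ranksum").p < 0.05
        assert 0.97 <= hits / 500 <= 1.0

    def test_cohen_d_known_value(self):
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([1.0, 2.0, 3.0])
        assert cohen_d(a, b) == pytest.approx(-1.0)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2, 3, 4], "signed_rank")


class TestPopulationTraces:
    def test_facilitation_and_suppression_diverge_in_sign(self, scored_trials_10):
        fac = [simulate_pc(scored_trials_10,
                           CellConfig(baseline_rate_ss=60, saccade_profile="facilitation",
                                      saccade_gain=30, saccade_latency=0.05), 800 + s)
               for s in range(4)]
        sup = [simulate_pc(scored_trials_10,
                           CellConfig(baseline_rate_ss=75, saccade_profile="suppression",
                                      saccade_gain=30, saccade_latency=0.05), 900 + s)
               for s in range(4)]
        t, zf = normalized_population_sdf(fac)
        _, zs = normalized_population_sdf(sup)
        post = (t > 0.0) & (t < 0.15)
        assert zf[post].mean() > 0.5
        assert zs[post].mean() < -0.5
        # suppression cells configured at higher baseline are recovered so
        from pcsacc.cellclass import baseline_rate
        assert (np.mean([baseline_rate(c) for c in sup])
                > np.mean([baseline_rate(c) for c in fac]))
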