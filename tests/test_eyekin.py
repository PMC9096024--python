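"""Filter chain, fixation-noise estimation, detection, and trial scoring."""
import numpy as np
import pytest

from pcsacc.eyekin import (detect_saccades, estimate_fixation_noise,
                           preprocess_trace, score_trial)
from pcsacc.synthgen import KinematicsConfig, simulate_eye_trace
from pcsacc.types import EyeTrace, SaccadeEvent, TrialRecord

FS = 350.0


def _trace(x, y=None, fs=FS):
    n = len(x)
    return EyeTrace(time=np.arange(n) / fs, x=np.asarray(x, float),
                    y=np.zeros(n) if y is None else np.asarray(y, float),
                    sampling_rate=fs)


def _trial(amplitude=10.0, duration=0.040, rt=0.2, condition="pro", direction=0):
    trial = TrialRecord(0, condition, direction, amplitude, 1.0, 1.4, 1.5, 0.4,
                        t_end=2.3)
    onset = trial.t_go + rt
    ang = np.deg2rad(direction * 45.0 + (0 if condition == "pro" else 180))
    trial.ground_truth_saccade = SaccadeEvent(
        onset=onset, offset=onset + duration, amplitude=amplitude,
        peak_velocity=1.875 * amplitude / duration, duration=duration,
        direction=np.rad2deg(ang) % 360, reaction_time=rt,
        x_end=amplitude * np.cos(ang), y_end=amplitude * np.sin(ang))
    return trial


class TestPreprocess:
    def test_constant_position_zero_speed(self):
        out = preprocess_trace(_trace(np.full(700, 3.5)))
        assert np.allclose(out.speed, 0.0, atol=1e-9)
        assert np.allclose(out.acceleration, 0.0, atol=1e-6)

    def test_linear_ramp_speed_exact_in_interior(self):
        t = np.arange(700) / FS
        out = preprocess_trace(_trace(5.0 * t))
        interior = slice(100, -100)
        assert np.allclose(out.speed[interior], 5.0, atol=1e-6)

    @pytest.mark.parametrize("amp,dur", [(10.0, 0.040), (9.5, 0.0698), (14.0, 0.080)])
    def test_min_jerk_peak_speed_preserved(self, amp, dur):
        kin0 = KinematicsConfig(fixation_noise_sd=0.0)
        out = preprocess_trace(simulate_eye_trace(_trial(amp, dur), kin0, seed=0))
        assert out.speed.max() == pytest.approx(1.875 * amp / dur, rel=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            preprocess_trace(_trace(np.zeros(20)))

    def test_grid_unchanged(self):
        raw = _trace(np.random.default_rng(0).normal(0, 0.03, 500))
        out = preprocess_trace(raw)
        assert np.array_equal(out.time, raw.time)


class TestFixationNoise:
    def test_zero_noise_gives_zero(self):
        out = preprocess_trace(_trace(np.zeros(700)))
        assert estimate_fixation_noise(out, [(0.2, 1.8)]) == 0.0

    def test_insufficient_data_rejected(self):
        out = preprocess_trace(_trace(np.zeros(700)))
        with pytest.raises(ValueError):
            estimate_fixation_noise(out, [(0.0, 0.1)])

    def test_matches_monte_carlo_oracle(self):
        """The session estimate agrees with a brute-force resampling oracle
        that pushes fresh noise through the identical filter chain."""
        rng = np.random.default_rng(42)
        sigma_p = 0.03
        est = estimate_fixation_noise(
            preprocess_trace(_trace(rng.normal(0, sigma_p, 3500),
                                    rng.normal(0, sigma_p, 3500))),
            [(0.1, 9.8)])
        oracle = []
        for _ in range(20):
            tr = preprocess_trace(_trace(rng.normal(0, sigma_p, 3500),
                                         rng.normal(0, sigma_p, 3500)))
            oracle.append(np.std(tr.speed[35:-35]))
        assert est == pytest.approx(np.mean(oracle), rel=0.10)

    def test_pooling_two_windows_matches_concatenation(self):
        rng = np.random.default_rng(1)
        out = preprocess_trace(_trace(rng.normal(0, 0.03, 3500),
                                      rng.normal(0, 0.03, 3500)))
        split = estimate_fixation_noise(out, [(0.2, 4.0), (5.0, 9.0)])
        merged = estimate_fixation_noise(out, [(0.2, 9.0)])
        assert split == pytest.approx(merged, rel=0.02)


class TestDetection:
    def test_flat_noisy_trace_yields_no_events(self):
        rng = np.random.default_rng(3)
        out = preprocess_trace(_trace(rng.normal(0, 0.03, 7000),
                                      rng.normal(0, 0.03, 7000)))
        noise_mean, noise_sd = out.speed.mean(), out.speed.std()
        assert detect_saccades(out, noise_sd, noise_mean=noise_mean) == []

    def test_single_noiseless_saccade_onset_within_one_sample(self):
        kin0 = KinematicsConfig(fixation_noise_sd=0.0)
        trial = _trial(10.0, 0.040)
        out = preprocess_trace(simulate_eye_trace(trial, kin0, seed=0))
        events = detect_saccades(out, noise_sd=3.0)
        assert len(events) == 1
        gt = trial.ground_truth_saccade
        assert abs(events[0].onset - gt.onset) <= 1.0 / FS
        assert abs(events[0].offset - gt.offset) <= 1.0 / FS
        assert events[0].amplitude == pytest.approx(10.0, rel=0.02)

    def test_invalid_noise_sd_rejected(self):
        out = preprocess_trace(_trace(np.zeros(700)))
        with pytest.raises(ValueError):
            detect_saccades(out, noise_sd=0.0)

    def test_threshold_monotonicity(self):
        """Raising the threshold multiplier never increases the event count."""
        kin = KinematicsConfig()
        trial = _trial(6.0, 0.04)
        out = preprocess_trace(simulate_eye_trace(trial, kin, seed=5))
        counts = [len(detect_saccades(out, 2.0, noise_mean=4.0, high_mult=m))
                  for m in (2, 4, 6, 10, 30, 100)]
        assert counts == sorted(counts, reverse=True)

    def test_amplitude_unbiased_on_noiseless_saccades(self):
        kin0 = KinematicsConfig(fixation_noise_sd=0.0)
        rng = np.random.default_rng(8)
        rel = []
        for _ in range(60):
            amp = rng.uniform(2.0, 14.0)
            dur = 0.025 + 0.004 * amp
            trial = _trial(amp, dur, direction=int(rng.integers(8)))
            out = preprocess_trace(simulate_eye_trace(trial, kin0, seed=0))
            ev = detect_saccades(out, noise_sd=3.0)
            assert len(ev) == 1
            rel.append(ev[0].amplitude / amp - 1)
        assert abs(np.mean(rel)) < 0.02


class TestScoring:
    def _detected(self, trial, kin=None, seed=0):
        kin = kin or KinematicsConfig()
        out = preprocess_trace(simulate_eye_trace(trial, kin, seed=seed))
        noise_mean, noise_sd = out.speed.mean(), max(out.speed.std(), 1e-3)
        if kin.fixation_noise_sd == 0:
            noise_mean, noise_sd = 0.0, 3.0
        return out, detect_saccades(out, noise_sd, noise_mean=noise_mean)

    def test_on_target_saccade_is_correct(self):
        trial = _trial(8.0, 0.05, rt=0.2, condition="pro")
        trace, events = self._detected(trial)
        scored = score_trial(trial, events, trace=trace)
        assert scored.outcome == "correct"
        assert scored.saccade.reaction_time == pytest.approx(0.2, abs=0.01)

    def test_anticipatory_rt_excluded_not_error(self):
        trial = _trial(8.0, 0.05, rt=0.080)
        trace, events = self._detected(trial)
        scored = score_trial(trial, events, trace=trace)
        assert scored.outcome == "excluded"
        assert scored.exclusion_reason == "anticipatory"

    def test_anti_trial_toward_target_is_error(self):
        trial = _trial(8.0, 0.05, rt=0.2, condition="anti")
        # overwrite ground truth: gaze goes to the visible target instead
        gt = trial.ground_truth_saccade
        gt.x_end, gt.y_end = 8.0, 0.0   # target at 0 deg; goal is the mirror
        trace, events = self._detected(trial)
        scored = score_trial(trial, events, trace=trace)
        assert scored.outcome == "error"
        assert scored.exclusion_reason == "endpoint"

    def test_late_saccade_is_timeout_error(self):
        trial = _trial(8.0, 0.05, rt=0.6)
        trace, events = self._detected(trial)
        scored = score_trial(trial, events, trace=trace)
        assert scored.outcome == "error"
        assert scored.exclusion_reason == "timeout"

    def test_no_saccade_is_error(self):
        trial = _trial(8.0, 0.05)
        scored = score_trial(trial, [])
        assert scored.outcome == "error"
        assert scored.exclusion_reason == "no_saccade"
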