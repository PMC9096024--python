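"""Synthetic pro/anti-saccade sessions with ground-truth labels.

The generator emulates the statistical structure the downstream analyses
assume: balanced randomized blocks of 8 directions x 2 conditions, 300-500 ms
instruction periods, saccade kinematics matching the published session-pooled
means/SDs, and Purkinje-cell spike trains (inhomogeneous Poisson) with
facilitation / suppression / ramping simple-spike profiles, ~1 Hz complex
spikes with epoch-locked gains, and a post-CS pause in simple-spike firing.

Kinematic calibration
---------------------
Reaction time, amplitude and duration are drawn from floored (left-truncated)
normals. The published summary moments describe *included* trials, i.e. the
post-floor distribution, so the parent (mu, sigma) of each draw is solved
numerically such that the truncated distribution has exactly the published
mean and SD. Amplitude and duration are drawn jointly with a per-condition
correlation (the saccadic main sequence); the correlations are calibrated so
that the *emergent* minimum-jerk peak velocity (V_p = 1.875 A / D, never
drawn) reproduces the published peak-velocity means through the measurement
filter chain.

All randomness flows from a single session seed through
``numpy.random.SeedSequence`` spawning: child 0 drives the schedule, child 1
the eye traces (one grandchild per trial), and children 2.. one per cell.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .types import (CONDITIONS, DIRECTION_STEP_DEG, N_DIRECTIONS, CellRecording,
                    EyeTrace, SaccadeEvent, Session, TrialRecord)

log = logging.getLogger(__name__)

GO_CUE_DELAY = 0.100       # fixation point turns gray 100 ms after target onset
INSTRUCTION_RANGE = (0.3, 0.5)
SACCADE_DEADLINE = 0.500   # response window after the go cue
TRIAL_TAIL = 0.800         # trace continues this long after the go cue
PRE_TRIAL_PAD = 0.100      # eye trace starts this long before fixation onset


@dataclass(frozen=True)
class ConditionKinematics:
    """Floored-normal kinematic distributions for one condition.

    Means/SDs are the moments of the *floored* draw (what a downstream
    analysis of included trials measures). ``amp_dur_corr`` couples amplitude
    and duration (main sequence).
    """

    rt_mean: float
    rt_sd: float
    amp_mean: float
    amp_sd: float
    dur_mean: float
    dur_sd: float
    amp_dur_corr: float = 0.5


@dataclass(frozen=True)
class KinematicsConfig:
    """Session-level kinematics. Defaults reproduce the published
    session-pooled saccade statistics per condition."""

    pro: ConditionKinematics = ConditionKinematics(
        rt_mean=0.1784, rt_sd=0.0706, amp_mean=5.8, amp_sd=2.3,
        dur_mean=0.0347, dur_sd=0.0079, amp_dur_corr=0.32)
    anti: ConditionKinematics = ConditionKinematics(
        rt_mean=0.2366, rt_sd=0.0727, amp_mean=9.5, amp_sd=4.1,
        dur_mean=0.0698, dur_sd=0.0240, amp_dur_corr=0.68)
    fixation_noise_sd: float = 0.03   # deg per axis, raw samples
    sampling_rate: float = 350.0      # Hz
    velocity_profile: str = "min_jerk"
    rt_floor: float = 0.100           # s; anticipatory saccades excluded below this
    amp_floor: float = 2.0            # deg
    dur_floor: float = 0.010          # s
    intertrial_interval: float = 1.5  # s (unreported in the source study)

    def __post_init__(self) -> None:
        for cond in (self.pro, self.anti):
            for v in (cond.rt_sd, cond.amp_sd, cond.dur_sd):
                if v <= 0:
                    raise ValueError("all kinematic SDs must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.velocity_profile != "min_jerk":
            raise ValueError("only the minimum-jerk velocity profile is implemented")

    def for_condition(self, condition: str) -> ConditionKinematics:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.pro if condition == "pro" else self.anti


@dataclass(frozen=True)
class CellConfig:
    """Generative profile of one synthetic Purkinje cell.

    ``instruction_profile`` / ``saccade_profile`` select the simple-spike
    modulation shape; gains are in spks/s (ramp slope in spks/s per s).
    ``condition_gain`` multiplies the within-trial rate on pro trials, so the
    pro/anti modulation ratio of the cell equals the configured value.
    ``cs_epoch_gain`` adds a boxcar (Hz) to the complex-spike rate in the
    instruction window (50-350 ms after instruction onset) and/or the saccade
    window (+-150 ms around saccade onset). Each CS silences SS for
    ``cs_pause`` seconds.
    """

    region: str = "medial"
    baseline_rate_ss: float = 60.0
    instruction_profile: str = "none"   # none | facilitation | suppression | ramp
    instruction_gain: float = 0.0       # spks/s; for ramp: slope in spks/s per s
    saccade_profile: str = "none"       # none | facilitation | suppression
    saccade_gain: float = 0.0           # spks/s
    saccade_latency: float = 0.0        # s, peak of the transient after saccade onset
    saccade_width: float = 0.050        # s, Gaussian SD of the transient
    condition_gain: float = 1.0         # multiplicative pro-vs-anti factor
    cs_baseline: float = 1.0            # Hz
    cs_instruction_gain: float = 0.0    # Hz
    cs_saccade_gain: float = 0.0        # Hz
    cs_pause: float = 0.015             # s of SS silencing after each CS
    tuning_gain: float = 0.0            # cosine directional gain, spks/s
    tuning_pref_direction: int = 0

    def __post_init__(self) -> None:
        if self.instruction_profile not in ("none", "facilitation", "suppression", "ramp"):
            raise ValueError(f"unknown instruction profile {self.instruction_profile!r}")
        if self.saccade_profile not in ("none", "facilitation", "suppression"):
            raise ValueError(f"unknown saccade profile {self.saccade_profile!r}")
        if self.cs_pause < 0:
            raise ValueError("cs_pause must be non-negative")


@lru_cache(maxsize=64)
def truncnorm_parent(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a normal whose left truncation at ``floor`` has
    the given mean and SD.

    Feasible whenever sd < mean - floor is not required but
    sd / (mean - floor) < 1 (the exponential limit); raises otherwise.
    """
    if mean <= floor:
        raise ValueError("target mean must exceed the floor")
    if sd / (mean - floor) >= 1.0:
        raise ValueError("moments infeasible for a left-truncated normal")

    def eqs(p):
        mu, lsig = p
        sig = np.exp(lsig)
        a = (floor - mu) / sig
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        return [d.mean() - mean, d.std() - sd]

    (mu, lsig), info, ier, msg = optimize.fsolve(
        eqs, [mean, np.log(sd)], full_output=True)
    if ier != 1:
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    return float(mu), float(np.exp(lsig))


def _draw_floored_normal(rng: np.random.Generator, mean: float, sd: float,
                         floor: float, size: int) -> np.ndarray:
    mu, sig = truncnorm_parent(mean, sd, floor)
    a = (floor - mu) / sig
    # inverse-CDF sampling keeps the draw a single rng call
    u = rng.uniform(stats.norm.cdf(a), 1.0, size)
    return mu + sig * stats.norm.ppf(u)


def _draw_amp_dur(rng: np.random.Generator, ck: ConditionKinematics,
                  amp_floor: float, dur_floor: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (amplitude, duration) with floors enforced by rejection."""
    mu_a, sg_a = truncnorm_parent(ck.amp_mean, ck.amp_sd, amp_floor)
    mu_d, sg_d = truncnorm_parent(ck.dur_mean, ck.dur_sd, dur_floor)
    rho = ck.amp_dur_corr
    cov = np.array([[sg_a**2, rho * sg_a * sg_d], [rho * sg_a * sg_d, sg_d**2]])
    amps = np.empty(0)
    durs = np.empty(0)
    while amps.size < size:
        z = rng.multivariate_normal([mu_a, mu_d], cov, size=max(2 * size, 16),
                                    method="cholesky")
        keep = (z[:, 0] >= amp_floor) & (z[:, 1] >= dur_floor)
        amps = np.concatenate([amps, z[keep, 0]])
        durs = np.concatenate([durs, z[keep, 1]])
    return amps[:size], durs[:size]


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def generate_schedule(n_blocks: int, kin: KinematicsConfig,
                      seed: int | np.random.SeedSequence) -> list[TrialRecord]:
    """Balanced randomized schedule: each block presents every
    (direction, condition) pair once, in random order; instruction durations
    are uniform on [0.3, 0.5] s."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    combos = [(d, c) for d in range(N_DIRECTIONS) for c in CONDITIONS]
    trials: list[TrialRecord] = []
    t = 1.0  # leave room before the first trial for the intertrial baseline
    tid = 0
    for _ in range(n_blocks):
        order = rng.permutation(len(combos))
        for k in order:
            d, c = combos[k]
            instr = rng.uniform(*INSTRUCTION_RANGE)
            t_fix = t
            t_target = t_fix + instr
            t_go = t_target + GO_CUE_DELAY
            t_end = t_go + TRIAL_TAIL
            trials.append(TrialRecord(
                trial_id=tid, condition=c, direction=d, target_amplitude=np.nan,
                t_fix_on=t_fix, t_target_on=t_target, t_go=t_go,
                instruction_duration=instr, t_end=t_end))
            t = t_end + kin.intertrial_interval
            tid += 1
    return trials


def draw_saccade_events(trials: Sequence[TrialRecord], kin: KinematicsConfig,
                        seed: int | np.random.SeedSequence) -> None:
    """Draw per-trial ground-truth saccades (RT, amplitude, duration) in place.

    Peak velocity is emergent from the minimum-jerk relation
    V_p = (15/8) A / D. Also fills ``target_amplitude``.
    """
    rng = np.random.default_rng(seed)
    for cond in CONDITIONS:
        sub = [t for t in trials if t.condition == cond]
        if not sub:
            continue
        ck = kin.for_condition(cond)
        rts = _draw_floored_normal(rng, ck.rt_mean, ck.rt_sd, kin.rt_floor, len(sub))
        amps, durs = _draw_amp_dur(rng, ck, kin.amp_floor, kin.dur_floor, len(sub))
        for trial, rt, a, d in zip(sub, rts, amps, durs):
            ang = np.deg2rad(trial.direction_deg + (0.0 if cond == "pro" else 180.0))
            onset = trial.t_go + rt
            trial.target_amplitude = float(a)
            trial.ground_truth_saccade = SaccadeEvent(
                onset=onset, offset=onset + d, amplitude=float(a),
                peak_velocity=float(1.875 * a / d), duration=float(d),
                direction=float(np.rad2deg(ang) % 360.0), reaction_time=float(rt),
                x_start=0.0, y_start=0.0,
                x_end=float(a * np.cos(ang)), y_end=float(a * np.sin(ang)))


def _minjerk_displacement(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Normalized minimum-jerk position profile (0 before onset, 1 after offset)."""
    tau = np.clip((t - onset) / duration, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_eye_trace(trial: TrialRecord, kin: KinematicsConfig,
                       seed: int | np.random.SeedSequence) -> EyeTrace:
    """Render one trial's eye-position trace.

    Fixation-centred Gaussian positional noise; the ground-truth saccade
    (drawn first if absent) moves gaze to the trial's goal position along a
    minimum-jerk trajectory. A saccade whose onset falls beyond the trace is
    simply absent (speed stays at noise level).
    """
    rng = np.random.default_rng(seed)
    if trial.ground_truth_saccade is None:
        draw_saccade_events([trial], kin, rng)
    sacc = trial.ground_truth_saccade
    fs = kin.sampling_rate
    # snap the grid to multiples of 1/fs in session time for reproducibility
    i0 = int(np.floor((trial.t_fix_on - PRE_TRIAL_PAD) * fs))
    i1 = int(np.ceil(trial.t_end * fs))
    t = np.arange(i0, i1 + 1) / fs
    disp = _minjerk_displacement(t, sacc.onset, sacc.duration)
    x = sacc.x_start + (sacc.x_end - sacc.x_start) * disp
    y = sacc.y_start + (sacc.y_end - sacc.y_start) * disp
    if kin.fixation_noise_sd > 0:
        x = x + rng.normal(0.0, kin.fixation_noise_sd, t.size)
        y = y + rng.normal(0.0, kin.fixation_noise_sd, t.size)
    return EyeTrace(time=t, x=x, y=y, sampling_rate=fs)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

_RATE_DT = 0.001


def _saccade_onset_for(trial: TrialRecord) -> Optional[float]:
    if trial.ground_truth_saccade is not None:
        return trial.ground_truth_saccade.onset
    if trial.saccade is not None:
        return trial.saccade.onset
    return None


def _ss_rate(trials: Sequence[TrialRecord], cfg: CellConfig,
             grid: np.ndarray) -> np.ndarray:
    rate = np.full(grid.size, float(cfg.baseline_rate_ss))
    dt = _RATE_DT

    def idx(t0: float, t1: float) -> slice:
        return slice(max(0, int(round(t0 / dt))), min(grid.size, int(round(t1 / dt))))

    for trial in trials:
        tuning = 1.0
        if cfg.tuning_gain != 0.0:
            dtheta = np.deg2rad((trial.direction - cfg.tuning_pref_direction)
                                * DIRECTION_STEP_DEG)
            tuning = 1.0 + (cfg.tuning_gain / max(cfg.baseline_rate_ss, 1e-9)) \
                * 0.5 * (1.0 + np.cos(dtheta))
        onset = _saccade_onset_for(trial)
        if cfg.instruction_profile == "facilitation":
            rate[idx(trial.t_fix_on, trial.t_target_on)] += cfg.instruction_gain * tuning
        elif cfg.instruction_profile == "suppression":
            rate[idx(trial.t_fix_on, trial.t_target_on)] -= cfg.instruction_gain * tuning
        elif cfg.instruction_profile == "ramp":
            end = onset if onset is not None else trial.t_go + 0.25
            sl = idx(trial.t_fix_on, end)
            tt = grid[sl] - trial.t_fix_on
            rate[sl] += cfg.instruction_gain * tt * tuning
        if cfg.saccade_profile != "none" and onset is not None:
            center = onset + cfg.saccade_latency
            sl = idx(center - 4 * cfg.saccade_width, center + 4 * cfg.saccade_width)
            bump = np.exp(-0.5 * ((grid[sl] - center) / cfg.saccade_width) ** 2)
            sign = 1.0 if cfg.saccade_profile == "facilitation" else -1.0
            rate[sl] += sign * cfg.saccade_gain * tuning * bump
        if cfg.condition_gain != 1.0 and trial.condition == "pro":
            sl = idx(trial.t_fix_on, trial.t_end)
            rate[sl] *= cfg.condition_gain
    return np.clip(rate, 0.0, None)


def _cs_rate(trials: Sequence[TrialRecord], cfg: CellConfig,
             grid: np.ndarray) -> np.ndarray:
    rate = np.full(grid.size, float(cfg.cs_baseline))
    dt = _RATE_DT

    def idx(t0: float, t1: float) -> slice:
        return slice(max(0, int(round(t0 / dt))), min(grid.size, int(round(t1 / dt))))

    for trial in trials:
        if cfg.cs_instruction_gain != 0.0:
            rate[idx(trial.t_fix_on + 0.050, trial.t_fix_on + 0.350)] += cfg.cs_instruction_gain
        onset = _saccade_onset_for(trial)
        if cfg.cs_saccade_gain != 0.0 and onset is not None:
            rate[idx(onset - 0.150, onset + 0.150)] += cfg.cs_saccade_gain
    return np.clip(rate, 0.0, None)


def _poisson_times(rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(rate * _RATE_DT)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(rate.size), counts)
    return np.sort(bins * _RATE_DT + rng.uniform(0.0, _RATE_DT, total))


def simulate_pc(trials: Sequence[TrialRecord], cfg: CellConfig,
                seed: int | np.random.SeedSequence,
                cell_id: str = "cell") -> CellRecording:
    """Inhomogeneous-Poisson simple and complex spikes for one cell.

    Every complex spike silences simple-spike firing for ``cfg.cs_pause``
    seconds (spikes in the pause are removed)."""
    if not trials:
        raise ValueError("trials must be non-empty")
    rng = np.random.default_rng(seed)
    t_max = max(t.t_end for t in trials if np.isfinite(t.t_end)) + 1.0
    grid = np.arange(0.0, t_max, _RATE_DT)
    ss = _poisson_times(_ss_rate(trials, cfg, grid), rng)
    cs = _poisson_times(_cs_rate(trials, cfg, grid), rng)
    if cfg.cs_pause > 0 and cs.size and ss.size:
        j = np.searchsorted(cs, ss, side="right") - 1
        valid = j < 0
        j = np.clip(j, 0, cs.size - 1)
        keep = valid | (ss - cs[j] > cfg.cs_pause)
        ss = ss[keep]
    # keep the caller's list so later in-place scoring is visible to the cell
    shared = trials if isinstance(trials, list) else list(trials)
    return CellRecording(cell_id=cell_id, region=cfg.region, ss_times=ss,
                         cs_times=cs, trials=shared, ground_truth=cfg)


def generate_population(pop_spec: dict[str, list[CellConfig]],
                        kin: KinematicsConfig, n_blocks: int,
                        seed: int) -> Session:
    """One shared schedule and eye-trace set; independent cell simulations.

    ``pop_spec`` maps region -> list of CellConfig (one entry per cell).
    Deterministic under a fixed seed (SeedSequence splitting)."""
    configs: list[CellConfig] = []
    for region, cfgs in pop_spec.items():
        for cfg in cfgs:
            if cfg.region != region:
                raise ValueError("CellConfig.region must match its pop_spec key")
        configs.extend(cfgs)
    if not configs:
        raise ValueError("population spec must contain at least one cell")
    root = np.random.SeedSequence(seed)
    ss_sched, ss_eye, *ss_cells = root.spawn(2 + len(configs))
    trials = generate_schedule(n_blocks, kin, ss_sched)
    draw_saccade_events(trials, kin, ss_eye)
    eye_children = ss_eye.spawn(len(trials))
    eye = {t.trial_id: simulate_eye_trace(t, kin, s)
           for t, s in zip(trials, eye_children)}
    cells = [simulate_pc(trials, cfg, s, cell_id=f"{cfg.region}_{i:03d}")
             for i, (cfg, s) in enumerate(zip(configs, ss_cells))]
    return Session(trials=trials, eye=eye, cells=cells, seed=seed, kinematics=kin)


def default_population_spec() -> dict[str, list[CellConfig]]:
    """A small demonstration population mixing the modulation archetypes."""
    return {
        "medial": [
            CellConfig(region="medial", baseline_rate_ss=60, saccade_profile="facilitation",
                       saccade_gain=30, saccade_latency=0.05, cs_saccade_gain=2.0),
            CellConfig(region="medial", baseline_rate_ss=70, saccade_profile="suppression",
                       saccade_gain=30, saccade_latency=0.08),
        ],
        "lateral": [
            CellConfig(region="lateral", baseline_rate_ss=65, instruction_profile="facilitation",
                       instruction_gain=25, saccade_profile="facilitation", saccade_gain=30,
                       saccade_latency=0.06, condition_gain=1.2,
                       cs_instruction_gain=2.0, cs_saccade_gain=2.0),
            CellConfig(region="lateral", baseline_rate_ss=60, instruction_profile="ramp",
                       instruction_gain=60, saccade_profile="facilitation", saccade_gain=25,
                       saccade_latency=0.05),
        ],
    }


def cell_config_to_dict(cfg: CellConfig) -> dict:
    return asdict(cfg)
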