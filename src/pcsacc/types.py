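"""Core data containers shared across the analysis modules.

Times are seconds from session start unless a function states otherwise.
All analysis windows are half-open ``[a, b)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CONDITIONS = ("pro", "anti")
REGIONS = ("medial", "lateral")
N_DIRECTIONS = 8

#: 45 degree steps, direction 0 = rightward.
DIRECTION_STEP_DEG = 45.0


@dataclass
class SaccadeEvent:
    """A single saccade, either generator ground truth or a detection.

    ``amplitude`` is the Euclidean start-to-end displacement in degrees;
    ``direction`` is the angle of the net displacement in degrees.
    """

    onset: float
    offset: float
    amplitude: float
    peak_velocity: float
    duration: float
    direction: float
    reaction_time: Optional[float] = None
    x_start: float = 0.0
    y_start: float = 0.0
    x_end: float = 0.0
    y_end: float = 0.0

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("saccade offset must exceed onset")


@dataclass
class TrialRecord:
    """One trial of the interleaved pro/anti-saccade task.

    The timeline is fixation-point onset (``t_fix_on``, trial onset), a
    300-500 ms instruction period ending with target appearance
    (``t_target_on``), and the go cue 100 ms later (``t_go``).
    """

    trial_id: int
    condition: str
    direction: int
    target_amplitude: float
    t_fix_on: float
    t_target_on: float
    t_go: float
    instruction_duration: float
    t_end: float = np.nan
    outcome: str = "unscored"  # correct | error | excluded | unscored
    exclusion_reason: str = ""
    ground_truth_saccade: Optional[SaccadeEvent] = None
    saccade: Optional[SaccadeEvent] = None  # detected, set by scoring

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0 <= self.direction < N_DIRECTIONS:
            raise ValueError("direction must be an integer in 0..7")
        if not (self.t_fix_on < self.t_target_on < self.t_go):
            raise ValueError("event times must be ordered fix_on < target_on < go")

    @property
    def direction_deg(self) -> float:
        return self.direction * DIRECTION_STEP_DEG

    def target_position(self) -> tuple[float, float]:
        ang = np.deg2rad(self.direction_deg)
        return (self.target_amplitude * np.cos(ang), self.target_amplitude * np.sin(ang))

    def goal_position(self) -> tuple[float, float]:
        """Required saccade endpoint: the target (pro) or its mirror (anti)."""
        tx, ty = self.target_position()
        return (tx, ty) if self.condition == "pro" else (-tx, -ty)


@dataclass
class EyeTrace:
    """Uniformly sampled 2-D gaze position, with derived speed/acceleration."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float
    speed: Optional[np.ndarray] = None
    acceleration: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.x) or len(self.x) != len(self.y):
            raise ValueError("time, x, y must be 1-D arrays of equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time must be a strictly increasing uniform grid")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class CellRecording:
    """One Purkinje cell: simple- and complex-spike times plus the session trials."""

    cell_id: str
    region: str
    ss_times: np.ndarray
    cs_times: np.ndarray
    trials: list[TrialRecord] = field(default_factory=list)
    ground_truth: Optional[object] = None  # CellConfig when synthetic

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        self.ss_times = np.sort(np.asarray(self.ss_times, dtype=float))
        self.cs_times = np.sort(np.asarray(self.cs_times, dtype=float))
        for arr, name in ((self.ss_times, "ss"), (self.cs_times, "cs")):
            if arr.size and arr[0] < 0:
                raise ValueError(f"{name} spike times must be non-negative")

    def correct_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.outcome == "correct"]

    @property
    def session_duration(self) -> float:
        ends = [t.t_end for t in self.trials if np.isfinite(t.t_end)]
        candidates = [self.ss_times[-1] if self.ss_times.size else 0.0,
                      self.cs_times[-1] if self.cs_times.size else 0.0] + ends
        return float(max(candidates))


@dataclass
class Session:
    """A recording session: shared trial schedule, eye traces, and cells."""

    trials: list[TrialRecord]
    eye: dict[int, EyeTrace]
    cells: list[CellRecording]
    seed: Optional[int] = None
    kinematics: Optional[object] = None  # KinematicsConfig


def copy_trial(trial: TrialRecord, **changes) -> TrialRecord:
    return replace(trial, **changes)
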