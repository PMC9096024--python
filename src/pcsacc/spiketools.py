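"""Spike-density functions, event alignment, and Purkinje-cell identification.

The spike density function (SDF) is the sum of unit-mass Gaussians centred on
spike times, evaluated on a 1 ms grid (sigma = 50 ms for simple spikes by
convention; complex-spike analyses pass a narrower kernel). No edge
renormalization is applied: a spike near the window edge contributes less than
unit mass inside the window.

Purkinje cells are identified by the climbing-fiber pause: a transient
silencing of simple-spike firing after each complex spike, visible as a dip in
the CS-triggered SS cross-correlogram.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import CellRecording, TrialRecord

log = logging.getLogger(__name__)

SDF_DT = 0.001
SS_SIGMA = 0.050
CS_SIGMA = 0.025

ALIGNMENT_EVENTS = ("trial_onset", "target_on", "go_cue", "saccade_onset")


@dataclass
class SDF:
    """Firing-rate estimate on a uniform 1 ms grid."""

    time: np.ndarray
    rate: np.ndarray
    sigma: float
    alignment: str = ""

    def mean(self) -> float:
        return float(self.rate.mean())

    def integral(self) -> float:
        return float(self.rate.sum() * SDF_DT)

    def to_tsv(self, path) -> None:
        """Write the SDF as a two-column TSV (time_s, rate_spks)."""
        import pandas as pd

        pd.DataFrame({"time_s": self.time, "rate_spks": self.rate}) \
            .to_csv(path, sep="\t", index=False)


def compute_sdf(spikes: np.ndarray, window: tuple[float, float],
                sigma: float = SS_SIGMA, alignment: str = "") -> SDF:
    """Gaussian-kernel SDF of one spike train over ``[window[0], window[1])``.

    Each spike contributes a unit-mass Gaussian; spikes outside the window
    still contribute their tail mass inside it.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a, b = window
    if not b > a:
        raise ValueError("window must be non-empty")
    grid = a + SDF_DT * np.arange(int(round((b - a) / SDF_DT)))
    rate = np.zeros(grid.size)
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size:
        half = 8.0 * sigma
        norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
        relevant = spikes[(spikes >= a - half) & (spikes < b + half)]
        for s in relevant:
            i0 = max(0, int(np.ceil((s - half - a) / SDF_DT)))
            i1 = min(grid.size, int(np.floor((s + half - a) / SDF_DT)) + 1)
            if i1 > i0:
                z = (grid[i0:i1] - s) / sigma
                rate[i0:i1] += norm * np.exp(-0.5 * z * z)
    return SDF(time=grid, rate=rate, sigma=sigma, alignment=alignment)


def pooled_sdf(aligned: Sequence[np.ndarray], window: tuple[float, float],
               sigma: float = SS_SIGMA, alignment: str = "") -> SDF:
    """Trial-averaged SDF: pooled spikes divided by the number of trials."""
    if not len(aligned):
        raise ValueError("need at least one trial")
    allspikes = np.concatenate([np.asarray(a, dtype=float) for a in aligned]) \
        if len(aligned) else np.empty(0)
    sdf = compute_sdf(allspikes, window, sigma=sigma, alignment=alignment)
    sdf.rate = sdf.rate / len(aligned)
    return sdf


def event_time(trial: TrialRecord, event: str) -> Optional[float]:
    """Absolute time of an alignment event in one trial, or None if undefined."""
    if event == "trial_onset":
        return trial.t_fix_on
    if event == "target_on":
        return trial.t_target_on
    if event == "go_cue":
        return trial.t_go
    if event == "saccade_onset":
        if trial.saccade is not None:
            return trial.saccade.onset
        if trial.ground_truth_saccade is not None:
            return trial.ground_truth_saccade.onset
        return None
    raise ValueError(f"unknown alignment event {event!r}")


@dataclass
class AlignedSpikes:
    """Per-trial spike times relative to an event, restricted to a window."""

    event: str
    window: tuple[float, float]
    trials: list[TrialRecord]
    rel_times: list[np.ndarray]
    event_times: list[float]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.rel_times)

    def counts(self) -> np.ndarray:
        return np.array([r.size for r in self.rel_times])

    def rates(self) -> np.ndarray:
        return self.counts() / (self.window[1] - self.window[0])


def align(cell_or_spikes, event: str, window: tuple[float, float],
          trials: Optional[Sequence[TrialRecord]] = None) -> AlignedSpikes:
    """Re-express spike times relative to a per-trial event.

    ``cell_or_spikes`` is a CellRecording (simple spikes used) or a plain
    spike-time array with ``trials`` supplied. Windows are half-open
    ``[a, b)``; trials lacking the event are dropped and counted.
    """
    if event not in ALIGNMENT_EVENTS:
        raise ValueError(f"unknown alignment event {event!r}")
    if isinstance(cell_or_spikes, CellRecording):
        spikes = cell_or_spikes.ss_times
        if trials is None:
            trials = cell_or_spikes.trials
    else:
        spikes = np.asarray(cell_or_spikes, dtype=float)
        if trials is None:
            raise ValueError("trials required when passing a raw spike array")
    a, b = window
    kept_trials, rel, etimes, dropped = [], [], [], 0
    for t in trials:
        et = event_time(t, event)
        if et is None:
            dropped += 1
            continue
        lo = np.searchsorted(spikes, et + a, side="left")
        hi = np.searchsorted(spikes, et + b, side="left")
        rel.append(spikes[lo:hi] - et)
        kept_trials.append(t)
        etimes.append(et)
    if dropped:
        log.info("align(%s): dropped %d trials lacking the event", event, dropped)
    return AlignedSpikes(event=event, window=window, trials=kept_trials,
                         rel_times=rel, event_times=etimes, n_dropped=dropped)


def kernel_mass_counts(cell_or_spikes, event: str, window: tuple[float, float],
                       sigma: float = SS_SIGMA,
                       trials: Optional[Sequence[TrialRecord]] = None) -> np.ndarray:
    """Per-trial spike counts weighted by the Gaussian kernel's mass in a window.

    Each spike contributes the fraction of its unit-mass kernel lying inside
    ``[a, b)`` — the window integral of the SDF. Unlike integer counts the
    values are continuous, which keeps rank/K-S statistics on them calibrated
    (integer counts are heavily tied and make the K-S test conservative).
    """
    from scipy.stats import norm

    a, b = window
    pad = 5.0 * sigma
    aligned = align(cell_or_spikes, event, (a - pad, b + pad), trials=trials)
    out = np.zeros(len(aligned))
    for i, rel in enumerate(aligned.rel_times):
        if rel.size:
            out[i] = float((norm.cdf((b - rel) / sigma)
                            - norm.cdf((a - rel) / sigma)).sum())
    return out


@dataclass
class PauseCheck:
    """Result of the climbing-fiber pause verification."""

    status: str               # "present" | "absent" | "indeterminate"
    pause_s: float            # length of the sub-50% run, NaN if indeterminate
    n_cs: int

    def __bool__(self) -> bool:
        return self.status == "present"


def verify_cs_pause(cell: CellRecording, check_duration: float = 120.0,
                    max_lag: float = 0.050, bin_s: float = 0.001,
                    min_cs: int = 10, min_run_s: float = 0.008) -> PauseCheck:
    """Check for a post-CS pause in simple-spike firing.

    Builds the CS-triggered SS cross-correlogram (1 ms bins, lags 0 to 50 ms)
    from complex spikes in the first ``check_duration`` seconds, and compares
    it with the pre-CS baseline rate (lags -50 to 0 ms). The pause is present
    when a contiguous run of at least ``min_run_s`` stays below 50% of the
    baseline. Fewer than ``min_cs`` complex spikes yield an indeterminate
    result (distinct from absent).
    """
    cs = cell.cs_times[cell.cs_times < check_duration]
    if cs.size < min_cs:
        return PauseCheck(status="indeterminate", pause_s=float("nan"), n_cs=int(cs.size))
    nbins = int(round(max_lag / bin_s))
    post = np.zeros(nbins)
    pre = 0
    for c in cs:
        lo = np.searchsorted(cell.ss_times, c - max_lag)
        hi = np.searchsorted(cell.ss_times, c + max_lag)
        lags = cell.ss_times[lo:hi] - c
        pre += int((lags < 0).sum())
        pos = lags[lags >= 0]
        idx = (pos / bin_s).astype(int)
        idx = idx[idx < nbins]
        np.add.at(post, idx, 1)
    baseline = pre / nbins  # mean pre-CS count per 1 ms bin
    if baseline <= 0:
        return PauseCheck(status="indeterminate", pause_s=float("nan"), n_cs=int(cs.size))
    below = post < 0.5 * baseline
    best = cur = 0
    for flag in below:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    pause = best * bin_s
    status = "present" if pause >= min_run_s else "absent"
    return PauseCheck(status=status, pause_s=pause, n_cs=int(cs.size))
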