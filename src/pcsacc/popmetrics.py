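"""Population-level simple-spike metrics and group comparisons.

Covers the pro/anti modulation ratio, peak/trough response latencies,
the firing-rate-vs-kinematics regression with corrected firing
(rate / regression coefficient), baseline-normalized population traces, and
two-group statistics (rank-sum, signed-rank, K-S, chi-square for proportions)
with a pooled-SD Cohen's d.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cellclass import BASELINE_WINDOW, SACCADE_TEST_WINDOW
from .spiketools import SS_SIGMA, align, pooled_sdf
from .types import CONDITIONS, CellRecording

log = logging.getLogger(__name__)

LATENCY_WINDOW = (0.0, 0.300)   # search window after saccade onset
FLAT_SDF_RANGE = 1.0            # spks/s; below this the latency is undefined


def saccade_window_rates(cell: CellRecording, condition: Optional[str] = None,
                         window: tuple[float, float] = SACCADE_TEST_WINDOW) -> np.ndarray:
    trials = cell.correct_trials()
    if condition is not None:
        trials = [t for t in trials if t.condition == condition]
    return align(cell, "saccade_onset", window, trials=trials).rates()


def modulation_ratio(cell: CellRecording,
                     window: tuple[float, float] = SACCADE_TEST_WINDOW) -> float:
    """(mean saccade-window rate, pro) / (mean saccade-window rate, anti).

    1 means identical responses; > 1 means stronger prosaccade activity.
    Undefined (NaN, logged) when the antisaccade response is not positive.
    """
    pro = saccade_window_rates(cell, "pro", window).mean()
    anti = saccade_window_rates(cell, "anti", window).mean()
    if not anti > 0:
        log.warning("modulation ratio undefined for %s (anti response %.3f)",
                    cell.cell_id, anti)
        return float("nan")
    return float(pro / anti)


@dataclass
class LatencyResult:
    latency: float          # s after saccade onset
    at_boundary: bool       # extremum sits on the search-window edge
    value: float            # SDF value at the extremum


def response_latency(cell: CellRecording, group: str,
                     condition: Optional[str] = None,
                     window: tuple[float, float] = LATENCY_WINDOW,
                     sigma: float = SS_SIGMA) -> Optional[LatencyResult]:
    """Time of the SDF peak (facilitation) or trough (suppression) after
    saccade onset. Returns None when the SDF is flat (range < 1 spks/s)."""
    if group not in ("facilitation", "suppression"):
        raise ValueError("group must be facilitation or suppression")
    trials = cell.correct_trials()
    if condition is not None:
        trials = [t for t in trials if t.condition == condition]
    pad = 4 * sigma
    aligned = align(cell, "saccade_onset", (window[0] - pad, window[1] + pad),
                    trials=trials)
    if not len(aligned):
        return None
    sdf = pooled_sdf(aligned.rel_times, (window[0] - pad, window[1] + pad), sigma=sigma)
    m = (sdf.time > window[0]) & (sdf.time <= window[1])
    tt, rr = sdf.time[m], sdf.rate[m]
    if np.ptp(rr) < FLAT_SDF_RANGE:
        return None
    i = int(np.argmax(rr) if group == "facilitation" else np.argmin(rr))
    return LatencyResult(latency=float(tt[i]),
                         at_boundary=bool(i in (0, tt.size - 1)),
                         value=float(rr[i]))


@dataclass
class KinematicFit:
    cell_id: str
    r: float
    p: float
    slope: float
    intercept: float
    corrected_rates: Optional[np.ndarray]   # rate / slope, None if slope ~ 0


def kinematic_regression(cells: Sequence[CellRecording], kinematic: str,
                         window: tuple[float, float] = SACCADE_TEST_WINDOW,
                         slope_tol: float = 1e-9) -> list[KinematicFit]:
    """Per-cell regression of per-trial firing rate on a saccade kinematic.

    ``kinematic`` is "amplitude" or "peak_speed". Corrected firing is
    rate / slope (undefined and logged when the slope is ~0). Cells whose
    rates or kinematics have zero variance yield NaN statistics.
    """
    if kinematic not in ("amplitude", "peak_speed"):
        raise ValueError("kinematic must be amplitude or peak_speed")
    fits = []
    for cell in cells:
        trials = cell.correct_trials()
        aligned = align(cell, "saccade_onset", window, trials=trials)
        rates = aligned.rates()
        kin = []
        for t in aligned.trials:
            sacc = t.saccade if t.saccade is not None else t.ground_truth_saccade
            kin.append(sacc.amplitude if kinematic == "amplitude" else sacc.peak_velocity)
        kin = np.asarray(kin)
        if rates.size < 3 or np.ptp(rates) == 0.0 or np.ptp(kin) == 0.0:
            log.warning("kinematic regression undefined for %s (degenerate data)",
                        cell.cell_id)
            fits.append(KinematicFit(cell.cell_id, float("nan"), float("nan"),
                                     float("nan"), float("nan"), None))
            continue
        res = stats.linregress(kin, rates)
        corrected = rates / res.slope if abs(res.slope) > slope_tol else None
        if corrected is None:
            log.warning("corrected rates undefined for %s (slope ~ 0)", cell.cell_id)
        fits.append(KinematicFit(cell.cell_id, float(res.rvalue), float(res.pvalue),
                                 float(res.slope), float(res.intercept), corrected))
    return fits


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    cohen_d: float


def compare_groups(values_a, values_b, test: str = "ranksum") -> GroupComparison:
    """Two-group comparison with effect size.

    ``test``: "ranksum" (Wilcoxon rank-sum), "signed_rank" (paired Wilcoxon),
    "ks" (two-sample Kolmogorov-Smirnov), or "chi2_proportions" (2x2 counts,
    uncorrected chi-square). Cohen's d is reported for the two-sample tests.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "chi2_proportions":
        table = np.vstack([a, b])
        if table.shape != (2, 2):
            raise ValueError("chi2_proportions expects two rows of 2 counts")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(test, float(chi2), float(p), float("nan"))
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if test == "ranksum":
        s, p = stats.ranksums(a, b)
    elif test == "signed_rank":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        if np.allclose(a, b):
            return GroupComparison(test, 0.0, 1.0, 0.0)
        s, p = stats.wilcoxon(a, b)
    elif test == "ks":
        s, p = stats.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(test, float(s), float(p), cohen_d(a, b))


def normalized_population_sdf(cells: Sequence[CellRecording],
                              condition: Optional[str] = None,
                              window: tuple[float, float] = (-0.3, 0.3),
                              sigma: float = SS_SIGMA) -> tuple[np.ndarray, np.ndarray]:
    """Average of per-cell baseline-z-scored saccade-aligned SDFs.

    Each cell's SDF is z-scored against its own intertrial-baseline mean/SD
    (per-trial rates in the baseline window), then averaged across cells.
    Returns (time, mean_z).
    """
    pad = 4 * sigma
    traces = []
    grid = None
    for cell in cells:
        trials = cell.correct_trials()
        if condition is not None:
            trials = [t for t in trials if t.condition == condition]
        base = align(cell, "trial_onset", BASELINE_WINDOW, trials=trials).rates()
        if base.size < 2 or base.std(ddof=1) == 0:
            continue
        aligned = align(cell, "saccade_onset", (window[0] - pad, window[1] + pad),
                        trials=trials)
        sdf = pooled_sdf(aligned.rel_times, (window[0] - pad, window[1] + pad),
                         sigma=sigma)
        m = (sdf.time >= window[0]) & (sdf.time < window[1])
        grid = sdf.time[m]
        traces.append((sdf.rate[m] - base.mean()) / base.std(ddof=1))
    if not traces:
        raise ValueError("no usable cells")
    return grid, np.mean(traces, axis=0)
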