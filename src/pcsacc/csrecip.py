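"""Complex-spike inclusion, epoch modulation, and CS-SS reciprocity.

Complex spikes (CS) are analyzed for cells whose session-wide CS rate is at
least 0.5 Hz with at least five trials per direction and condition. Epoch
modulation compares the trial-averaged CS spike-density function (narrow
kernel, sigma = 25 ms by default — CS are sparse) in the instruction window
(50-350 ms after instruction onset) or the saccade window (+-150 ms around
saccade onset) against +-3 SD of the intertrial baseline (500 ms of
intertrial activity pooled over trials).

Reciprocity is the product of the maximum (signed, largest-magnitude) CS-rate
change from baseline in the epoch window and the associated maximum SS-rate
change in a 300 ms window centred on the CS peak: a negative product means
opposite-signed (reciprocal) modulation. Per region and condition, the
saccade-epoch reciprocity is regressed on the instruction-epoch reciprocity;
points whose Cook's distance exceeds three times the mean Cook's distance are
removed once and the fit recomputed (a single exclusion pass — iterating
changes results).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .cellclass import MIN_TRIALS_PER_COMBO
from .spiketools import CS_SIGMA, SS_SIGMA, align, pooled_sdf
from .types import CONDITIONS, N_DIRECTIONS, CellRecording

log = logging.getLogger(__name__)

CS_MIN_RATE_HZ = 0.5
BASELINE_WINDOW_CS = (-0.500, 0.0)       # relative to trial onset (intertrial)
INSTRUCTION_WINDOW = (0.050, 0.350)      # relative to instruction onset
SACCADE_WINDOW = (-0.150, 0.150)         # relative to saccade onset
SS_SEARCH_HALF = 0.150                   # +-150 ms around the CS peak


def cs_inclusion(cell: CellRecording,
                 min_rate: float = CS_MIN_RATE_HZ,
                 min_trials: int = MIN_TRIALS_PER_COMBO) -> bool:
    """Session-wide CS rate >= 0.5 Hz (inclusive) and >= 5 correct trials per
    (direction, condition)."""
    dur = cell.session_duration
    if dur <= 0 or cell.cs_times.size == 0:
        return False
    rate = cell.cs_times.size / dur
    if rate < min_rate:
        return False
    counts = np.zeros((N_DIRECTIONS, len(CONDITIONS)), dtype=int)
    for t in cell.correct_trials():
        counts[t.direction, CONDITIONS.index(t.condition)] += 1
    return bool((counts >= min_trials).all())


def _epoch_sdf(cell: CellRecording, spike_type: str, epoch: str,
               condition: Optional[str], sigma: float):
    trials = cell.correct_trials()
    if condition is not None:
        trials = [t for t in trials if t.condition == condition]
    spikes = cell.cs_times if spike_type == "cs" else cell.ss_times
    if epoch == "instruction":
        event, window = "trial_onset", INSTRUCTION_WINDOW
    elif epoch == "saccade":
        event, window = "saccade_onset", SACCADE_WINDOW
    elif epoch == "baseline":
        event, window = "trial_onset", BASELINE_WINDOW_CS
    else:
        raise ValueError(f"unknown epoch {epoch!r}")
    pad = 4 * sigma
    aligned = align(spikes, event, (window[0] - pad, window[1] + pad), trials=trials)
    if not len(aligned):
        raise ValueError(f"no trials with a defined {event} event")
    sdf = pooled_sdf(aligned.rel_times, (window[0] - pad, window[1] + pad), sigma=sigma)
    m = (sdf.time >= window[0]) & (sdf.time < window[1])
    return sdf.time[m], sdf.rate[m]


def _per_trial_sdf_matrix(cell: CellRecording, spike_type: str,
                          condition: Optional[str], sigma: float):
    """Per-trial SDFs over the intertrial baseline window, shape (n, T)."""
    from .spiketools import compute_sdf

    trials = cell.correct_trials()
    if condition is not None:
        trials = [t for t in trials if t.condition == condition]
    spikes = cell.cs_times if spike_type == "cs" else cell.ss_times
    window = BASELINE_WINDOW_CS
    pad = 4 * sigma
    aligned = align(spikes, "trial_onset", (window[0] - pad, window[1] + pad),
                    trials=trials)
    rows = []
    for rel in aligned.rel_times:
        sdf = compute_sdf(rel, (window[0] - pad, window[1] + pad), sigma=sigma)
        m = (sdf.time >= window[0]) & (sdf.time < window[1])
        rows.append(sdf.rate[m])
    if not rows:
        raise ValueError("no intertrial baseline data")
    return np.vstack(rows)


def cs_baseline_stats(cell: CellRecording, condition: Optional[str] = None,
                      sigma: float = CS_SIGMA) -> tuple[float, float]:
    """Baseline mean and sampling SD of the trial-averaged CS SDF.

    The mean is the grand mean over the pooled intertrial 500 ms segments.
    The SD is the standard error of the trial average, estimated from the
    across-trial variance of the per-trial SDFs (the trial-averaged SDF over
    a 500 ms window has only a handful of kernel-independent time samples, so
    estimating its SD along time alone is badly under-resolved and inflates
    the false-positive rate of the +-3 SD rule)."""
    R = _per_trial_sdf_matrix(cell, "cs", condition, sigma)
    n = R.shape[0]
    sem = float(np.mean(R.std(axis=0, ddof=1)) / np.sqrt(n)) if n > 1 else float("inf")
    return float(R.mean()), sem


def cs_epoch_modulation(cell: CellRecording, epoch: str,
                        condition: Optional[str] = None,
                        sigma: float = CS_SIGMA, n_sd: float = 3.0) -> str:
    """"up" / "down" / "none": sign of the first CS-SDF excursion beyond
    mean +- 3 SD of the intertrial baseline in the epoch window."""
    mean, sd = cs_baseline_stats(cell, condition, sigma)
    if not np.isfinite(mean) or sd < 0:
        raise ValueError("no intertrial baseline data")
    _, rate = _epoch_sdf(cell, "cs", epoch, condition, sigma)
    hi = rate > mean + n_sd * sd
    lo = rate < mean - n_sd * sd
    exceed = hi | lo
    if not exceed.any():
        return "none"
    first = int(np.argmax(exceed))
    return "up" if hi[first] else "down"


@dataclass
class ReciprocityValue:
    cell_id: str
    epoch: str
    condition: Optional[str]
    delta_cs: float      # Hz, signed extremal CS deviation from baseline
    delta_ss: float      # spks/s, signed extremal SS deviation near the CS peak
    product: float       # Hz * spks/s; negative = reciprocal modulation
    cs_peak_time: float  # s, within the epoch window


def reciprocity(cell: CellRecording, epoch: str,
                condition: Optional[str] = None,
                cs_sigma: float = CS_SIGMA,
                ss_sigma: float = SS_SIGMA) -> ReciprocityValue:
    """Maximum-change CS and SS deviations and their product for one epoch.

    "Maximum change" is the deviation of largest magnitude with its sign
    retained — required for the negative-product (reciprocity) semantics.
    The SS deviation is measured from the SS intertrial baseline within
    +-150 ms of the CS peak.
    """
    cs_mean, _ = cs_baseline_stats(cell, condition, cs_sigma)
    t_cs, r_cs = _epoch_sdf(cell, "cs", epoch, condition, cs_sigma)
    dev_cs = r_cs - cs_mean
    i = int(np.argmax(np.abs(dev_cs)))
    delta_cs = float(dev_cs[i])
    t_peak = float(t_cs[i])

    _, ss_base = _epoch_sdf(cell, "ss", "baseline", condition, ss_sigma)
    ss_mean = float(ss_base.mean())
    # SS SDF on a window wide enough to cover the +-150 ms around the CS peak
    trials = cell.correct_trials()
    if condition is not None:
        trials = [t for t in trials if t.condition == condition]
    event = "trial_onset" if epoch == "instruction" else "saccade_onset"
    win = (t_peak - SS_SEARCH_HALF, t_peak + SS_SEARCH_HALF)
    pad = 4 * ss_sigma
    aligned = align(cell.ss_times, event, (win[0] - pad, win[1] + pad), trials=trials)
    sdf = pooled_sdf(aligned.rel_times, (win[0] - pad, win[1] + pad), sigma=ss_sigma)
    m = (sdf.time >= win[0]) & (sdf.time < win[1])
    dev_ss = sdf.rate[m] - ss_mean
    delta_ss = float(dev_ss[int(np.argmax(np.abs(dev_ss)))])
    return ReciprocityValue(cell_id=cell.cell_id, epoch=epoch, condition=condition,
                            delta_cs=delta_cs, delta_ss=delta_ss,
                            product=delta_cs * delta_ss, cs_peak_time=t_peak)


@dataclass
class ReciprocityRegression:
    region: str
    condition: Optional[str]
    slope: float
    intercept: float
    r2: float
    n_used: int
    excluded: list[str] = field(default_factory=list)


def fit_reciprocity_products(x: np.ndarray, y: np.ndarray,
                             ids: Optional[Sequence[str]] = None,
                             cook_mult: float = 3.0,
                             region: str = "", condition: Optional[str] = None,
                             min_cells: int = 5) -> ReciprocityRegression:
    """OLS of saccade-epoch products on instruction-epoch products.

    Exactly one Cook's-distance exclusion pass: points with Cook's distance
    greater than ``cook_mult`` times the mean are removed and the model refit
    once (iterating the exclusion changes results and is deliberately not done).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(x.size)]
    if x.size < min_cells:
        raise ValueError(f"need >= {min_cells} cells with both epoch products "
                         f"(got {x.size})")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    cooks = model.get_influence().cooks_distance[0]
    keep = cooks <= cook_mult * cooks.mean()
    excluded = [i for i, k in zip(ids, keep) if not k]
    if excluded and keep.sum() >= 3:
        model = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
    slope = float(model.params[1]) if model.params.size > 1 else float("nan")
    return ReciprocityRegression(region=region, condition=condition, slope=slope,
                                 intercept=float(model.params[0]),
                                 r2=float(model.rsquared),
                                 n_used=int(keep.sum()), excluded=excluded)


def reciprocity_regression(cells: Sequence[CellRecording], region: str,
                           condition: Optional[str] = None,
                           cook_mult: float = 3.0,
                           min_cells: int = 5) -> ReciprocityRegression:
    """Association of instruction- and saccade-epoch reciprocity across a
    region's CS-included cells (single Cook's-distance exclusion pass)."""
    ids, x, y = [], [], []
    for cell in cells:
        if cell.region != region or not cs_inclusion(cell):
            continue
        rx = reciprocity(cell, "instruction", condition)
        ry = reciprocity(cell, "saccade", condition)
        ids.append(cell.cell_id)
        x.append(rx.product)
        y.append(ry.product)
    return fit_reciprocity_products(np.asarray(x), np.asarray(y), ids,
                                    cook_mult=cook_mult, region=region,
                                    condition=condition, min_cells=min_cells)
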