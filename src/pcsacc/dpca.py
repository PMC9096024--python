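"""Demixed principal component analysis of the population PSTH tensor.

The population activity tensor X is indexed (neuron, condition, time) with
100 ms bins aligned to instruction offset, trial-averaged per neuron and
condition, with directions pooled. After per-neuron mean-centering the tensor
is split into two marginalizations:

* ``condition_independent`` — the average over conditions (time-only signal);
* ``stimulus`` — the residual (condition x time signal).

For each marginalization m the method solves the ridge-regularized
reduced-rank regression

    min_{F_m, D_m} || X_m - F_m D_m X ||_F^2 + lambda || B ||_F^2,

whose solution is the full ridge regression matrix
B = X_m X^T (X X^T + lambda I)^-1 followed by an SVD of B X: the top left
singular vectors give the encoder axes F_m and D_m = F_m^T B the decoder
axes. Components are ordered by explained variance (the squared singular
values over the total tensor variance). With a single marginalization and
lambda = 0, B is the identity and the axes reduce to ordinary PCA.

Each stimulus component doubles as a linear decoder: per 100 ms bin, held-out
pseudo-trials are classified by the nearest class mean of their projection
(pro vs anti, chance 0.5), repeated over random held-out draws; significance
uses a shuffle null (condition labels permuted within neuron) with a
max-over-time 95th-percentile threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .spiketools import align
from .types import CONDITIONS, CellRecording

log = logging.getLogger(__name__)

BIN_S = 0.100
DEFAULT_WINDOW = (-0.5, 1.0)   # s around instruction offset
MARGINALIZATIONS = ("condition_independent", "stimulus")
MIN_TRIALS = 5


@dataclass
class PSTHTensor:
    """Trial-averaged population tensor plus trial-resolved companion data."""

    X: np.ndarray                      # (N, C, T) rates, spks/s
    time: np.ndarray                   # (T,) bin centers, s from instruction offset
    cell_ids: list[str]
    trial_rates: list[dict[str, np.ndarray]]   # per neuron: cond -> (K, T)
    bin_s: float = BIN_S

    @property
    def n_neurons(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[2]


def build_tensor(cells: Sequence[CellRecording],
                 window: tuple[float, float] = DEFAULT_WINDOW,
                 bin_s: float = BIN_S,
                 min_trials: int = MIN_TRIALS) -> PSTHTensor:
    """Bin each neuron's correct trials around instruction offset.

    Neurons with fewer than ``min_trials`` correct trials in either condition
    are dropped (logged). Directions are pooled.
    """
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + bin_s * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows, ids, trial_rates = [], [], []
    for cell in cells:
        per_cond = {}
        ok = True
        for cond in CONDITIONS:
            sub = [t for t in cell.correct_trials() if t.condition == cond]
            aligned = align(cell, "target_on", (window[0], window[1]), trials=sub)
            if len(aligned) < min_trials:
                ok = False
                break
            K = len(aligned)
            R = np.zeros((K, n_bins))
            for k, rel in enumerate(aligned.rel_times):
                counts, _ = np.histogram(rel, bins=edges)
                R[k] = counts / bin_s
            per_cond[cond] = R
        if not ok:
            log.info("build_tensor: dropped %s (fewer than %d trials in a condition)",
                     cell.cell_id, min_trials)
            continue
        rows.append(np.stack([per_cond[c].mean(axis=0) for c in CONDITIONS]))
        ids.append(cell.cell_id)
        trial_rates.append(per_cond)
    if not rows:
        raise ValueError("no neurons pass the trial-count rule")
    return PSTHTensor(X=np.stack(rows), time=centers, cell_ids=ids,
                      trial_rates=trial_rates, bin_s=bin_s)


@dataclass
class DPCAResult:
    encoders: dict[str, np.ndarray]       # marg -> (N, q)
    decoders: dict[str, np.ndarray]       # marg -> (q, N)
    components: dict[str, np.ndarray]     # marg -> (q, C, T)
    var_fraction: dict[str, np.ndarray]   # marg -> (q,) fractions of total variance
    marg_var_fraction: dict[str, float]   # marg -> share of total variance
    total_var: float
    center: np.ndarray                    # (N,) per-neuron means removed before fit
    time: np.ndarray
    lam: float

    def cumulative_variance(self) -> np.ndarray:
        allv = np.sort(np.concatenate(list(self.var_fraction.values())))[::-1]
        return np.cumsum(allv)


def marginalize(Xc: np.ndarray) -> dict[str, np.ndarray]:
    """Split a centered (N, C, T) tensor into its two marginalizations.

    The condition-independent part is the condition average broadcast back;
    the stimulus part is the remainder. The two sum exactly to the input.
    """
    Xt = Xc.mean(axis=1, keepdims=True) * np.ones_like(Xc)
    return {"condition_independent": Xt, "stimulus": Xc - Xt}


def fit_dpca(tensor: PSTHTensor, lam: Optional[float] = 0.0,
             n_components: int = 5,
             cv_seed: int = 0) -> DPCAResult:
    """Fit the two-marginalization dPCA model.

    ``lam`` is the ridge regularizer (relative to the mean squared tensor
    value); ``lam=None`` selects it on a logarithmic grid by held-out-trial
    cross-validation. ``n_components`` applies per marginalization and is
    reduced on rank-deficient tensors (logged).
    """
    N, C, T = tensor.X.shape
    if N < 2 or T < 2:
        raise ValueError("need at least 2 neurons and 2 time bins")
    center = tensor.X.reshape(N, -1).mean(axis=1)
    Xc = tensor.X - center[:, None, None]
    if lam is None:
        lam = _select_lambda(tensor, n_components, seed=cv_seed)
        log.info("dPCA: cross-validated lambda = %.3g", lam)
    margs = marginalize(Xc)
    Xf = Xc.reshape(N, C * T)
    total_var = float((Xf ** 2).sum())
    gram = Xf @ Xf.T
    scale = lam * np.trace(gram) / N if lam > 0 else 0.0
    inv = np.linalg.pinv(gram + scale * np.eye(N))
    encoders, decoders, components, var_frac, marg_share = {}, {}, {}, {}, {}
    for name, Xm in margs.items():
        Xmf = Xm.reshape(N, C * T)
        marg_share[name] = float((Xmf ** 2).sum()) / total_var if total_var > 0 else 0.0
        B = Xmf @ Xf.T @ inv
        U, S, Vt = np.linalg.svd(B @ Xf, full_matrices=False)
        rank = int((S > S[0] * 1e-12).sum()) if S.size and S[0] > 0 else 0
        q = min(n_components, rank)
        if q < n_components:
            log.info("dPCA: %s marginalization rank-limited to %d components", name, q)
        F = U[:, :q]
        D = F.T @ B
        encoders[name] = F
        decoders[name] = D
        components[name] = (D @ Xf).reshape(q, C, T)
        var_frac[name] = (S[:q] ** 2) / total_var if total_var > 0 else np.zeros(q)
    return DPCAResult(encoders=encoders, decoders=decoders, components=components,
                      var_fraction=var_frac, marg_var_fraction=marg_share,
                      total_var=total_var, center=center, time=tensor.time, lam=lam)


def _tensor_from_means(tensor: PSTHTensor, means: list[dict[str, np.ndarray]]) -> np.ndarray:
    return np.stack([np.stack([m[c] for c in CONDITIONS]) for m in means])


def _select_lambda(tensor: PSTHTensor, n_components: int, seed: int = 0,
                   grid: Optional[np.ndarray] = None, n_folds: int = 10) -> float:
    """Held-out-trial cross-validation over a logarithmic lambda grid."""
    if grid is None:
        grid = np.concatenate([[0.0], np.logspace(-7, -1, 7)])
    rng = np.random.default_rng(seed)
    errors = np.zeros(grid.size)
    for _ in range(n_folds):
        train_means, test_means = [], []
        for per_cond in tensor.trial_rates:
            tr, te = {}, {}
            for c, R in per_cond.items():
                k = rng.integers(R.shape[0])
                te[c] = R[k]
                tr[c] = (R.sum(axis=0) - R[k]) / (R.shape[0] - 1)
            train_means.append(tr)
            test_means.append(te)
        Xtr = _tensor_from_means(tensor, train_means)
        Xte = _tensor_from_means(tensor, test_means)
        ttr = PSTHTensor(X=Xtr, time=tensor.time, cell_ids=tensor.cell_ids,
                         trial_rates=tensor.trial_rates, bin_s=tensor.bin_s)
        for gi, lam in enumerate(grid):
            res = fit_dpca(ttr, lam=lam, n_components=n_components)
            Xte_c = (Xte - res.center[:, None, None]).reshape(Xte.shape[0], -1)
            te_margs = marginalize(Xte - res.center[:, None, None])
            for name in MARGINALIZATIONS:
                pred = res.encoders[name] @ (res.decoders[name] @ Xte_c)
                errors[gi] += ((te_margs[name].reshape(pred.shape) - pred) ** 2).sum()
    return float(grid[int(np.argmin(errors))])


@dataclass
class DecodingResult:
    accuracy: np.ndarray          # (q, T) mean cross-validated accuracy
    threshold: np.ndarray         # (q,) shuffle-null max-over-time 95th percentile
    significant: np.ndarray       # (q, T) boolean mask
    time: np.ndarray
    n_iter: int
    n_shuffles: int


def _decode_axes(decoders: np.ndarray, center: np.ndarray,
                 trial_rates: list[dict[str, np.ndarray]],
                 n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Cross-validated nearest-class-mean accuracy per axis and time bin."""
    q = decoders.shape[0]
    N = len(trial_rates)
    T = trial_rates[0][CONDITIONS[0]].shape[1]
    C = len(CONDITIONS)
    acc = np.zeros((q, T))
    for _ in range(n_iter):
        Xtr = np.empty((N, C, T))
        Xte = np.empty((N, C, T))
        for n, per_cond in enumerate(trial_rates):
            for ci, c in enumerate(CONDITIONS):
                R = per_cond[c]
                K = R.shape[0]
                if K < 2:
                    # too few trials: resample with replacement for the test draw
                    k = rng.integers(K)
                    Xte[n, ci] = R[k]
                    Xtr[n, ci] = R.mean(axis=0)
                else:
                    k = rng.integers(K)
                    Xte[n, ci] = R[k]
                    Xtr[n, ci] = (R.sum(axis=0) - R[k]) / (K - 1)
        Xtr -= center[:, None, None]
        Xte -= center[:, None, None]
        ptr = np.einsum("qn,nct->qct", decoders, Xtr)
        pte = np.einsum("qn,nct->qct", decoders, Xte)
        # classify each held-out condition by nearest class mean, per bin
        d = np.abs(pte[:, :, None, :] - ptr[:, None, :, :])   # (q, test c, class, T)
        assigned = np.argmin(d, axis=2)                        # (q, C, T)
        truth = np.arange(C)[None, :, None]
        acc += (assigned == truth).mean(axis=1)
    return acc / n_iter


def _shuffle_labels(trial_rates: list[dict[str, np.ndarray]],
                    rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    out = []
    for per_cond in trial_rates:
        pooled = np.concatenate([per_cond[c] for c in CONDITIONS], axis=0)
        perm = rng.permutation(pooled.shape[0])
        pooled = pooled[perm]
        new = {}
        k0 = 0
        for c in CONDITIONS:
            k = per_cond[c].shape[0]
            new[c] = pooled[k0:k0 + k]
            k0 += k
        out.append(new)
    return out


def decode_stimulus(result: DPCAResult, tensor: PSTHTensor,
                    n_iter: int = 100, n_shuffles: int = 100,
                    seed: int = 0,
                    n_iter_shuffle: Optional[int] = None) -> DecodingResult:
    """Per-bin pro/anti classification along each stimulus-component axis.

    Accuracy is averaged over ``n_iter`` random held-out pseudo-trial draws.
    A bin is significant when accuracy exceeds the 95th percentile of the
    max-over-time accuracies from ``n_shuffles`` label-shuffled nulls
    (condition labels permuted within neuron).
    """
    rng = np.random.default_rng(seed)
    D = result.decoders["stimulus"]
    acc = _decode_axes(D, result.center, tensor.trial_rates, n_iter, rng)
    if n_iter_shuffle is None:
        n_iter_shuffle = max(10, n_iter // 10)
    null_max = np.zeros((n_shuffles, D.shape[0]))
    for s in range(n_shuffles):
        shuffled = _shuffle_labels(tensor.trial_rates, rng)
        a = _decode_axes(D, result.center, shuffled, n_iter_shuffle, rng)
        null_max[s] = a.max(axis=1)
    threshold = np.percentile(null_max, 95, axis=0)
    significant = acc > threshold[:, None]
    return DecodingResult(accuracy=acc, threshold=threshold, significant=significant,
                          time=result.time, n_iter=n_iter, n_shuffles=n_shuffles)
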