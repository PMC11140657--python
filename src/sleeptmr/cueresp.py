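"""Cue-locked time-frequency analysis and cluster-based permutation
statistics.

Time-frequency maps use complex Morlet wavelets at 30 logarithmically spaced
frequencies from 2 to 40 Hz with 5 to 10 cycles (log-spaced to match).
Trial-averaged power is decibel normalized against mean power 500-200 ms
before cue onset. Condition contrasts are tested with a paired cluster-based
permutation test: pointwise paired t statistics are thresholded (two-tailed
p < 0.05), contiguous supra-threshold points form clusters whose summed t
(t_sum) is compared against the maximum |t_sum| distribution over random
within-participant sign flips — the exact permutation scheme for a paired
design. Positive and negative clusters are tested jointly against this
two-sided null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .preprocess import EpochSet

TFR_FREQS = np.logspace(np.log10(2.0), np.log10(40.0), 30)
TFR_CYCLES = np.logspace(np.log10(5.0), np.log10(10.0), 30)
BASELINE_S = (-0.5, -0.2)


@dataclass
class TFRResult:
    power: np.ndarray            # trials x freqs x times (or 1 x F x T if averaged)
    freqs: np.ndarray
    times: np.ndarray
    cycles: np.ndarray = field(default_factory=lambda: TFR_CYCLES.copy())
    units: str = "raw"           # "raw" or "dB"
    baseline_s: tuple[float, float] | None = None
    channel: str = "Cz"

    def trial_average(self) -> np.ndarray:
        return self.power.mean(axis=0)


@dataclass
class Cluster:
    members: np.ndarray          # boolean mask over the map
    t_sum: float
    p_corrected: float
    sign: int                    # +1 / -1


def tfr_morlet(
    epochs: EpochSet,
    channel: str = "Cz",
    freqs: np.ndarray = TFR_FREQS,
    cycles: np.ndarray = TFR_CYCLES,
) -> TFRResult:
    """Per-trial Morlet wavelet power at one channel."""
    from mne.time_frequency import tfr_array_morlet

    ep = epochs.kept_subset()
    if ep.n_trials == 0:
        raise ValueError("no usable trials")
    ci = ep.channel_labels.index(channel)
    data = ep.data[:, [ci], :]
    n_times = data.shape[2]
    longest = cycles[0] / freqs[0] * ep.fs
    if n_times < longest:
        raise ValueError("epoch shorter than the longest wavelet")
    power = tfr_array_morlet(
        data, sfreq=ep.fs, freqs=freqs, n_cycles=cycles,
        output="power", verbose="error",
    )[:, 0]  # trials x freqs x times
    return TFRResult(power, np.asarray(freqs), ep.times,
                     np.asarray(cycles), "raw", None, channel)


def db_normalize(
    tfr: TFRResult, baseline_s: tuple[float, float] = BASELINE_S
) -> TFRResult:
    """Decibel normalization of trial-averaged power.

    Baseline is the mean power per frequency over the pre-cue baseline
    window; the output map is 10*log10(power / baseline).
    """
    if baseline_s[1] > 0 or baseline_s[0] >= baseline_s[1]:
        raise ValueError("baseline must be a pre-onset window")
    avg = tfr.trial_average()
    sel = (tfr.times >= baseline_s[0]) & (tfr.times <= baseline_s[1])
    if not sel.any():
        raise ValueError("baseline window outside the epoch")
    base = avg[:, sel].mean(axis=1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("nonpositive baseline power")
    db = 10.0 * np.log10(avg / base)
    return TFRResult(db[None], tfr.freqs, tfr.times, tfr.cycles, "dB",
                     baseline_s, tfr.channel)


def spindle_probability(
    times: np.ndarray,
    spindle_intervals_per_trial: list[list[tuple[float, float]]],
) -> np.ndarray:
    """Fraction of trials with an ongoing spindle at each epoch time point.

    ``spindle_intervals_per_trial`` holds (onset_s, offset_s) pairs in epoch
    time (relative to cue onset) for every trial; trials without spindles
    contribute zeros.
    """
    n = len(spindle_intervals_per_trial)
    if n == 0:
        raise ValueError("zero trials")
    ind = np.zeros((n, times.size))
    for i, intervals in enumerate(spindle_intervals_per_trial):
        for a, b in intervals:
            ind[i, (times >= a) & (times < b)] = 1.0
    return ind.mean(axis=0)


def match_trials(
    a: EpochSet, b: EpochSet, seed: int = 0
) -> tuple[EpochSet, EpochSet]:
    """Equalize trial counts by random subsampling of the larger condition."""
    na, nb = a.n_trials, b.n_trials
    if na == 0 or nb == 0:
        raise ValueError("both conditions must be nonempty")
    rng = np.random.default_rng(seed)
    if na > nb:
        a = a.subset(np.sort(rng.choice(na, size=nb, replace=False)))
    elif nb > na:
        b = b.subset(np.sort(rng.choice(nb, size=na, replace=False)))
    return a, b


# ---------------------------------------------------------------------------
# Cluster-based permutation test
# ---------------------------------------------------------------------------

def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t over the participant axis (axis 0)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return mean / (sd / np.sqrt(n))


def _max_cluster_stat(tmap: np.ndarray, tcrit: float, structure) -> float:
    """Largest |t_sum| over positive and negative clusters of one map."""
    best = 0.0
    for sign in (1, -1):
        mask = (sign * tmap) > tcrit
        if not mask.any():
            continue
        labels, nlab = ndimage.label(mask, structure=structure)
        sums = ndimage.sum_labels(np.abs(tmap), labels, np.arange(1, nlab + 1))
        if sums.size:
            best = max(best, float(sums.max()))
    return best


def cluster_permutation(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None = None,
    n_perm: int = 1000,
    point_alpha: float = 0.05,
    seed: int = 0,
) -> list[Cluster]:
    """Paired cluster-based permutation test on per-participant maps.

    ``maps_a``/``maps_b`` are participants x map (1-D or 2-D). With
    ``maps_b=None``, ``maps_a`` is taken as the per-participant difference
    (condition A minus B). Adjacency is 4-connectivity on 2-D maps and runs
    of consecutive points on 1-D maps. Returns every supra-threshold cluster
    with its t_sum and max-statistic corrected p value; an empty list means
    no point survived the cluster-forming threshold.
    """
    diffs = np.asarray(maps_a, dtype=float)
    if maps_b is not None:
        diffs = diffs - np.asarray(maps_b, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    map_shape = diffs.shape[1:]
    structure = None  # scipy default: orthogonal neighbors (4-connectivity in 2-D)
    tcrit = float(stats.t.ppf(1.0 - point_alpha / 2.0, n - 1))
    t_obs = _paired_t(diffs)

    # observed clusters
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_obs) > tcrit
        if not mask.any():
            continue
        labels, nlab = ndimage.label(mask, structure=structure)
        for k in range(1, nlab + 1):
            mem = labels == k
            clusters.append(Cluster(mem, float(t_obs[mem].sum()), 1.0, sign))
    if not clusters:
        return []

    # permutation null: within-participant sign flips, fully vectorized
    rng = np.random.default_rng(seed)
    flat = diffs.reshape(n, -1)
    ss = (flat ** 2).sum(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    sums = signs @ flat                        # n_perm x points
    mean = sums / n
    var = (ss[None, :] - n * mean ** 2) / (n - 1)
    var[var <= 0] = np.inf
    t_perm = mean / np.sqrt(var / n)
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = _max_cluster_stat(t_perm[p].reshape(map_shape), tcrit,
                                    structure)
    for cl in clusters:
        exceed = int((null >= abs(cl.t_sum)).sum())
        cl.p_corrected = (1 + exceed) / (1 + n_perm)
    return sorted(clusters, key=lambda c: c.p_corrected)


def cluster_average(contrast_maps: np.ndarray, cluster: Cluster) -> np.ndarray:
    """Mean contrast over a cluster's member points, per participant.

    ``contrast_maps`` is participants x map (memory minus control dB maps).
    """
    if not cluster.members.any():
        raise ValueError("empty cluster")
    maps = np.asarray(contrast_maps, dtype=float)
    return maps[:, cluster.members].mean(axis=1)
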