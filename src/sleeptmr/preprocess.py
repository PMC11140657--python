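"""Preprocessing: resampling, filtering, rereferencing, epoching, artifact
rejection, and channel interpolation.

Filters are 4th-order Butterworth applied forward-backward (zero phase);
the mains notch is an IIR notch with Q=30. Epoch rejection combines an
absolute +/-500 microvolt threshold with a joint-probability criterion
(per-channel empirical log-likelihood of each epoch's samples, z-scored
across epochs, thresholded at 6 SD per channel / 2 SD globally). Continuous
NREM data are screened with a two-iteration Hjorth-parameter pass; bad
channels are repaired by spherical-spline interpolation (Perrin-style,
order m=4, 50 Legendre terms, regularization 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .sigio import Recording, Hypnogram, EventLog, stage_mask

EPOCH_WINDOW_S = (-1.0, 3.0)


@dataclass
class EpochSet:
    """Cue-locked trials x channels x samples, with per-trial bookkeeping.

    Rejected trials are flagged, never dropped: ``kept`` marks usable trials
    and ``rejection_reason`` holds a short tag for the rest.
    """

    data: np.ndarray                      # trials x channels x samples
    fs: float
    channel_labels: list[str]
    window_s: tuple[float, float]
    categories: list[str]
    kept: np.ndarray                      # bool per trial
    rejection_reason: list[str]           # "" when kept

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_s[0] + np.arange(n) / self.fs

    def subset(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            self.data[index], self.fs, list(self.channel_labels),
            self.window_s, [self.categories[i] for i in index],
            self.kept[index], [self.rejection_reason[i] for i in index],
        )

    def kept_subset(self) -> "EpochSet":
        return self.subset(np.flatnonzero(self.kept))


@dataclass
class ArtifactReport:
    interpolated_channels: list[str] = field(default_factory=list)
    per_epoch_interpolations: int = 0
    removed_epochs: list[int] = field(default_factory=list)
    removal_reasons: dict[int, str] = field(default_factory=dict)
    iterations: int = 0


# ---------------------------------------------------------------------------
# Resampling / filtering / referencing
# ---------------------------------------------------------------------------

def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs`` (downsampling only)."""
    if target_fs > rec.fs:
        raise ValueError("upsampling is out of scope")
    if target_fs == rec.fs:
        return rec.copy()
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(data, target_fs, list(rec.channel_labels), rec.reference,
                     list(rec.annotations))


def filter_signal(
    rec: Recording,
    kind: str,
    freq: float | tuple[float, float],
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase filtering: 'highpass'/'bandpass' Butterworth (forward-
    backward), or 'notch' (IIR notch, Q=30)."""
    nyq = rec.fs / 2.0
    freqs = np.atleast_1d(np.asarray(freq, dtype=float))
    if np.any(freqs >= nyq):
        raise ValueError("cutoff at or above Nyquist")
    if kind == "notch":
        b, a = signal.iirnotch(float(freqs[0]), notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, rec.data, axis=1)
    elif kind == "highpass":
        sos = signal.butter(order, float(freqs[0]), "highpass", fs=rec.fs,
                            output="sos")
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    elif kind == "bandpass":
        if freqs.size != 2:
            raise ValueError("bandpass needs (low, high)")
        sos = signal.butter(order, freqs, "bandpass", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return Recording(data, rec.fs, list(rec.channel_labels), rec.reference,
                     list(rec.annotations))


def rereference(rec: Recording, refs: Sequence[str] = ("M1", "M2")) -> Recording:
    """Subtract the mean of the mastoid channels from every channel."""
    try:
        ref_idx = [rec.channel_index(r) for r in refs]
    except KeyError as e:
        raise KeyError(f"missing reference channel: {e}") from None
    ref = rec.data[ref_idx].mean(axis=0)
    data = rec.data - ref[None, :]
    return Recording(data, rec.fs, list(rec.channel_labels),
                     f"average({','.join(refs)})", list(rec.annotations))


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(
    rec: Recording,
    events: EventLog,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
    baseline: bool = True,
) -> EpochSet:
    """Cut trials around cue onsets.

    With ``baseline=True`` each trial is mean-adjusted by its average voltage
    over the 1 s before cue onset. Events too close to the recording edge are
    kept but flagged ``"edge"``.
    """
    lo = int(round(window_s[0] * rec.fs))
    hi = int(round(window_s[1] * rec.fs))
    n_samp = hi - lo
    n_ev = len(events)
    data = np.zeros((n_ev, rec.n_channels, n_samp))
    kept = np.ones(n_ev, dtype=bool)
    reasons = [""] * n_ev
    base_lo = int(round(-1.0 * rec.fs))
    for i, (onset, _, _, _) in enumerate(events.events):
        a, b = onset + lo, onset + hi
        if a < 0 or b > rec.n_samples:
            kept[i] = False
            reasons[i] = "edge"
            continue
        trial = rec.data[:, a:b]
        if baseline:
            bl = rec.data[:, onset + base_lo:onset].mean(axis=1, keepdims=True)
            trial = trial - bl
        data[i] = trial
    return EpochSet(data, rec.fs, list(rec.channel_labels), window_s,
                    events.categories, kept, reasons)


# ---------------------------------------------------------------------------
# Epoch rejection
# ---------------------------------------------------------------------------

def _jointprob_z(data: np.ndarray, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel and global joint-probability z-scores per epoch.

    For each channel the sample distribution is estimated across all epochs
    (histogram); an epoch's statistic is the mean negative log-probability of
    its samples, z-scored over epochs. The global statistic pools channels.
    """
    n_tr, n_ch, _ = data.shape
    nll = np.zeros((n_tr, n_ch))
    for c in range(n_ch):
        x = data[:, c, :]
        edges = np.histogram_bin_edges(x.ravel(), bins=n_bins)
        p, _ = np.histogram(x.ravel(), bins=edges, density=False)
        p = p.astype(float) / p.sum()
        p = np.clip(p, 1e-12, None)
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        nll[:, c] = -np.log(p[idx]).mean(axis=1)
    sd = nll.std(axis=0)
    sd[sd == 0] = 1.0
    z_single = (nll - nll.mean(axis=0)) / sd
    g = nll.mean(axis=1)
    gsd = g.std() or 1.0
    z_global = (g - g.mean()) / gsd
    # one-sided: only *improbable* (high negative log-likelihood) epochs are
    # artifacts; unusually typical epochs are fine
    return z_single, z_global


def _robust_z(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Median/MAD z-scores, stable under heavy contamination."""
    med = np.median(x, axis=axis, keepdims=True)
    mad = np.median(np.abs(x - med), axis=axis, keepdims=True)
    scale = 1.4826 * mad
    scale[scale == 0] = np.inf
    return (x - med) / scale


def reject_epochs(
    epochs: EpochSet,
    abs_thresh_uv: float = 500.0,
    jp_single_sd: float = 6.0,
    jp_global_sd: float = 2.0,
    eeg_channels: Sequence[str] | None = None,
) -> tuple[EpochSet, ArtifactReport]:
    """Flag artifactual trials; sample values are never modified.

    A trial is flagged "amplitude" if any sample exceeds +/-500 microvolts,
    or "jointprob" if its per-channel (6 SD) or global (2 SD) joint-
    probability z-score is exceeded.
    """
    n_ok = int(epochs.kept.sum())
    if n_ok < 5:
        raise ValueError("need at least 5 usable trials for joint-probability "
                         "statistics")
    ch_idx = (
        [epochs.channel_labels.index(c) for c in eeg_channels]
        if eeg_channels is not None
        else list(range(len(epochs.channel_labels)))
    )
    kept = epochs.kept.copy()
    reasons = list(epochs.rejection_reason)
    usable = np.flatnonzero(epochs.kept)
    sub = epochs.data[np.ix_(usable, ch_idx)]
    amp_bad = np.abs(sub).max(axis=(1, 2)) > abs_thresh_uv
    z_single, z_global = _jointprob_z(sub)
    jp_bad = (z_single.max(axis=1) > jp_single_sd) | (z_global > jp_global_sd)
    report = ArtifactReport(iterations=1)
    for k, tr in enumerate(usable):
        if amp_bad[k]:
            kept[tr] = False
            reasons[tr] = "amplitude"
            report.removed_epochs.append(int(tr))
            report.removal_reasons[int(tr)] = "amplitude"
        elif jp_bad[k]:
            kept[tr] = False
            reasons[tr] = "jointprob"
            report.removed_epochs.append(int(tr))
            report.removal_reasons[int(tr)] = "jointprob"
    out = EpochSet(epochs.data, epochs.fs, list(epochs.channel_labels),
                   epochs.window_s, list(epochs.categories), kept, reasons)
    return out, report


# ---------------------------------------------------------------------------
# Hjorth screening of continuous data
# ---------------------------------------------------------------------------

def hjorth_params(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """Hjorth activity (variance), mobility (rad/s), and complexity.

    Mobility is the RMS angular frequency sqrt(var(dx/dt)/var(x)); for a pure
    sinusoid at f Hz it approaches 2*pi*f and complexity approaches 1.
    """
    dx = np.diff(x) * fs
    ddx = np.diff(dx) * fs
    var_x = np.var(x)
    if var_x == 0:
        return 0.0, 0.0, 0.0
    mob = np.sqrt(np.var(dx) / var_x)
    mob2 = np.sqrt(np.var(ddx) / np.var(dx)) if np.var(dx) > 0 else 0.0
    comp = mob2 / mob if mob > 0 else 0.0
    return float(var_x), float(mob), float(comp)


def hjorth_artifact_pass(
    rec: Recording,
    hyp: Hypnogram,
    stages: Sequence[str] = ("N2", "N3"),
    epoch_len_s: float = 30.0,
    iterations: int = 2,
    z_thresh: float = 3.0,
    bad_channel_frac: float = 0.25,
    bad_epoch_frac: float = 0.5,
    positions: dict[str, np.ndarray] | None = None,
    eeg_channels: Sequence[str] | None = None,
) -> tuple[Recording, np.ndarray, ArtifactReport]:
    """Two-iteration Hjorth screen over stage-restricted 30-s epochs.

    Per epoch and channel the three Hjorth parameters are z-scored across
    epochs (per channel); a cell is "bad" if any |z| > 3. Channels bad in
    >= 25% of epochs are interpolated globally; epochs with > 50% bad
    channels are dropped from the clean mask; remaining bad cells are
    interpolated epoch-by-epoch. Returns the repaired recording, a boolean
    per-epoch clean mask (over stage-restricted epochs), and a report.
    """
    eeg = list(eeg_channels) if eeg_channels is not None else [
        c for c in rec.channel_labels if c not in ("M1", "M2")
    ]
    ch_idx = [rec.channel_index(c) for c in eeg]
    ep_samp = int(round(epoch_len_s * rec.fs))
    wanted = set(stages)
    ep_starts = [
        int(i * hyp.epoch_length_s * rec.fs)
        for i, s in enumerate(hyp.stages)
        if s in wanted and (i + 1) * hyp.epoch_length_s * rec.fs <= rec.n_samples
    ]
    if not ep_starts:
        raise ValueError("no data in the requested stages")
    rec = rec.copy()
    report = ArtifactReport()
    n_ep = len(ep_starts)
    clean = np.ones(n_ep, dtype=bool)
    for it in range(iterations):
        report.iterations = it + 1
        live = np.flatnonzero(clean)
        if live.size == 0:
            raise ValueError("no clean data: all epochs removed")
        params = np.zeros((live.size, len(ch_idx), 3))
        for k, e in enumerate(live):
            seg = rec.data[ch_idx, ep_starts[e]:ep_starts[e] + ep_samp]
            for c in range(len(ch_idx)):
                params[k, c] = hjorth_params(seg[c], rec.fs)
        # robust z across epochs (per channel, per parameter): a mean/SD
        # estimate is diluted when a sizable fraction of epochs is bad,
        # which would make the >=25%-of-epochs rule unattainable
        bad_cell = (np.abs(_robust_z(params)) > z_thresh).any(axis=2)
        # channels bad in >= 25% of epochs: repair globally
        ch_bad_frac = bad_cell.mean(axis=0)
        glob_bad = np.flatnonzero(ch_bad_frac >= bad_channel_frac)
        for c in glob_bad:
            lab = eeg[c]
            good = [l for j, l in enumerate(eeg) if j not in glob_bad]
            if positions is not None and len(
                [g for g in good if g in positions]
            ) >= 4:
                _interp_inplace(rec, [lab], good, positions)
            if lab not in report.interpolated_channels:
                report.interpolated_channels.append(lab)
            bad_cell[:, c] = False
        # epochs with > 50% bad channels: remove
        ep_bad_frac = bad_cell.mean(axis=1)
        for k, e in enumerate(live):
            if ep_bad_frac[k] > bad_epoch_frac:
                clean[e] = False
                report.removed_epochs.append(int(e))
                report.removal_reasons[int(e)] = "hjorth"
            elif bad_cell[k].any() and positions is not None:
                bads = [eeg[c] for c in np.flatnonzero(bad_cell[k])]
                goods = [l for l in eeg
                         if l not in bads and l in positions]
                sl = slice(ep_starts[e], ep_starts[e] + ep_samp)
                if len(goods) >= 4 and all(b in positions for b in bads):
                    _interp_inplace(rec, bads, goods, positions, sl)
                    report.per_epoch_interpolations += 1
                else:
                    # too few positioned channels to repair: drop the epoch
                    clean[e] = False
                    report.removed_epochs.append(int(e))
                    report.removal_reasons[int(e)] = "hjorth-uninterpolable"
    return rec, clean, report


# ---------------------------------------------------------------------------
# Spherical-spline channel interpolation
# ---------------------------------------------------------------------------

def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos angle)."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n ** m * (n + 1) ** m) * eval_legendre(n, cosang)
    return g / (4 * np.pi)


def spline_interpolation_matrix(
    good_pos: np.ndarray, bad_pos: np.ndarray,
    m: int = 4, n_terms: int = 50, reg: float = 1e-5,
) -> np.ndarray:
    """Matrix mapping good-channel signals to spherical-spline estimates at
    the bad-channel positions (positions are unit-normalized 3-vectors)."""
    gp = good_pos / np.linalg.norm(good_pos, axis=1, keepdims=True)
    bp = bad_pos / np.linalg.norm(bad_pos, axis=1, keepdims=True)
    G = _g_matrix(gp @ gp.T, m, n_terms)
    G = G + reg * np.eye(len(gp))
    Gb = _g_matrix(bp @ gp.T, m, n_terms)
    n = len(gp)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    Ainv = np.linalg.pinv(A)
    # weights for data -> (spline coefs, constant)
    W = Ainv[:, :n]
    return np.hstack([Gb, np.ones((len(bp), 1))]) @ W


def montage_positions(labels: Sequence[str]) -> dict[str, np.ndarray]:
    """3-D positions for standard 10-20 labels from the MNE standard montage."""
    import warnings as _warnings

    import mne

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    out = {}
    for lab in labels:
        if lab in pos and np.isfinite(pos[lab]).all():
            out[lab] = np.asarray(pos[lab], dtype=float)
    return out


def _interp_inplace(
    rec: Recording,
    bad: Sequence[str],
    good: Sequence[str],
    positions: dict[str, np.ndarray],
    sl: slice | None = None,
) -> None:
    good = [g for g in good if g in positions and g not in bad]
    if len(good) < 4:
        raise ValueError("need at least 4 positioned good channels")
    for b in bad:
        if b not in positions:
            raise ValueError(f"no montage position for channel {b!r}")
    M = spline_interpolation_matrix(
        np.array([positions[g] for g in good]),
        np.array([positions[b] for b in bad]),
    )
    gi = [rec.channel_index(g) for g in good]
    bi = [rec.channel_index(b) for b in bad]
    s = sl if sl is not None else slice(None)
    rec.data[bi, s] = M @ rec.data[gi, s]


def interpolate_channel(
    rec: Recording,
    bad_labels: Sequence[str],
    positions: dict[str, np.ndarray],
) -> Recording:
    """Replace bad channels with spherical-spline estimates from the rest."""
    rec = rec.copy()
    good = [c for c in rec.channel_labels
            if c not in bad_labels and c not in ("M1", "M2")]
    _interp_inplace(rec, bad_labels, good, positions)
    return rec
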