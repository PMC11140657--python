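"""Sleep spindle detection, slow-oscillation detection, and SO-spindle
coupling.

Spindles: the signal is convolved with a complex Morlet wavelet centered on
the individual's fast-spindle peak frequency with a 3 Hz spectral bandwidth
(full width at half maximum). The wavelet magnitude is thresholded at nine
times its median over artifact-free data; supra-threshold runs lasting at
least 400 ms become events (runs separated by < 100 ms are merged first).

Slow oscillations: the signal is bandpass filtered 0.5-4 Hz; spans between
consecutive positive-to-negative zero crossings lasting 0.8-2 s are
candidates, and the top quartile by peak-to-peak amplitude per channel is
retained.

Coupling: a spindle is coupled when its amplitude peak falls inside a
detected SO span; the coupling phase is the analytic-signal angle of the
delta-filtered trace at the spindle peak. Phase convention: 0 deg at the SO
positive peak, +/-180 deg at the trough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import filter_signal
from .sigio import Recording

DELTA_BAND = (0.5, 4.0)


@dataclass
class SpindleEvent:
    channel: str
    onset_s: float
    offset_s: float
    peak_amplitude: float       # wavelet-magnitude maximum, microvolts
    peak_time_s: float
    center_frequency: float     # individualized peak frequency used

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SOEvent:
    channel: str
    start_s: float
    end_s: float
    peak_to_peak: float
    trough_time_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CoupledEvent:
    spindle: SpindleEvent
    so: SOEvent
    coupling_phase_deg: float   # in (-180, 180]


@dataclass
class CouplingSummary:
    coupled_density: float      # coupled spindles per NREM minute
    mean_phase_deg: float
    vector_length: float
    n_coupled: int
    n_spindles: int


def morlet_magnitude(
    x: np.ndarray, fs: float, center_freq: float, fwhm_hz: float = 3.0
) -> np.ndarray:
    """Magnitude of the convolution with a complex Morlet wavelet.

    The Gaussian frequency envelope has sigma_f = FWHM / 2.355; the wavelet
    is L1-normalized so a unit-amplitude sinusoid at the center frequency
    yields magnitude ~1 regardless of bandwidth.
    """
    sigma_f = fwhm_hz / 2.355
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    wavelet = np.exp(2j * np.pi * center_freq * t) * np.exp(
        -(t ** 2) / (2 * sigma_t ** 2)
    )
    wavelet /= np.abs(wavelet).sum() / 2.0  # unit response to in-band sinusoid
    return np.abs(sps.fftconvolve(x, wavelet, mode="same"))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_spindles(
    x: np.ndarray,
    fs: float,
    peak_freq: float,
    clean_mask: np.ndarray | None = None,
    threshold_factor: float = 9.0,
    min_dur_s: float = 0.4,
    fwhm_hz: float = 3.0,
    merge_gap_s: float = 0.1,
    channel: str = "Cz",
) -> list[SpindleEvent]:
    """Wavelet-threshold spindle detector.

    ``clean_mask`` marks artifact-free samples; the threshold median is taken
    over them, and events overlapping masked-out samples are discarded.
    """
    x = np.asarray(x, dtype=float)
    if clean_mask is None:
        clean_mask = np.ones(x.size, dtype=bool)
    if not clean_mask.any():
        raise ValueError("clean mask selects no samples")
    mag = morlet_magnitude(x, fs, peak_freq, fwhm_hz)
    med = float(np.median(mag[clean_mask]))
    if med == 0:
        warnings.warn("degenerate threshold (median magnitude is zero); "
                      "no spindles detected")
        return []
    thresh = threshold_factor * med
    above = mag > thresh
    runs = _runs(above)
    # merge runs separated by short envelope dips
    gap = int(round(merge_gap_s * fs))
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_samp = int(round(min_dur_s * fs))
    events = []
    for s, e in merged:
        if e - s < min_samp:
            continue
        if not clean_mask[s:e].all():
            continue
        pk = s + int(np.argmax(mag[s:e]))
        events.append(SpindleEvent(
            channel, s / fs, e / fs, float(mag[pk]), pk / fs, peak_freq
        ))
    return events


def detect_slow_oscillations(
    x: np.ndarray,
    fs: float,
    clean_mask: np.ndarray | None = None,
    dur_range_s: tuple[float, float] = (0.8, 2.0),
    amplitude_quartile: float = 0.75,
    channel: str = "Cz",
    prefiltered: bool = False,
) -> list[SOEvent]:
    """Zero-crossing slow-oscillation detector.

    Candidates are spans between consecutive positive-to-negative zero
    crossings of the 0.5-4 Hz filtered trace lasting 0.8-2 s (0.5-1.25 Hz);
    the top quartile by peak-to-peak amplitude is retained.
    """
    x = np.asarray(x, dtype=float)
    if not prefiltered:
        rec = Recording(x[None, :], fs, [channel])
        x = filter_signal(rec, "bandpass", DELTA_BAND).data[0]
    if clean_mask is None:
        clean_mask = np.ones(x.size, dtype=bool)
    pos = x > 0
    pn = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1  # first sample <= 0
    if pn.size < 2:
        raise ValueError("fewer than two positive-to-negative zero crossings")
    cands = []
    for a, b in zip(pn[:-1], pn[1:]):
        dur = (b - a) / fs
        if not dur_range_s[0] <= dur <= dur_range_s[1]:
            continue
        if not clean_mask[a:b].all():
            continue
        seg = x[a:b]
        p2p = float(seg.max() - seg.min())
        trough = a + int(np.argmin(seg))
        cands.append(SOEvent(channel, a / fs, b / fs, p2p, trough / fs))
    if not cands:
        raise ValueError("no slow-oscillation candidates")
    amps = np.array([c.peak_to_peak for c in cands])
    n_keep = int(np.ceil(len(cands) * (1.0 - amplitude_quartile)))
    keep = np.argsort(amps)[::-1][:n_keep]
    return [cands[i] for i in sorted(keep)]


def so_phase_series(x: np.ndarray, fs: float, prefiltered: bool = False) -> np.ndarray:
    """Instantaneous SO phase (radians, 0 at positive peak) of the
    delta-filtered trace, with 2 s reflection padding around the Hilbert
    transform to suppress edge effects."""
    x = np.asarray(x, dtype=float)
    if not prefiltered:
        rec = Recording(x[None, :], fs, ["sig"])
        x = filter_signal(rec, "bandpass", DELTA_BAND).data[0]
    pad = int(round(2.0 * fs))
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    phase = np.angle(sps.hilbert(padded))
    return phase[pad:pad + x.size]


def circular_mean_resultant(phases_rad: np.ndarray) -> tuple[float, float]:
    z = np.exp(1j * np.asarray(phases_rad)).mean()
    return float(np.angle(z)), float(np.abs(z))


def couple(
    spindles: list[SpindleEvent],
    sos: list[SOEvent],
    x: np.ndarray,
    fs: float,
    nrem_minutes: float,
    prefiltered: bool = False,
) -> tuple[list[CoupledEvent], CouplingSummary]:
    """Pair spindles whose amplitude peak lies inside a detected SO span and
    summarize coupling density, mean phase, and consistency (vector length).
    """
    channels = {s.channel for s in spindles} | {s.channel for s in sos}
    if len(channels) > 1:
        raise ValueError("spindles and SOs must come from the same channel")
    if nrem_minutes <= 0:
        raise ValueError("NREM minutes must be positive")
    phase = so_phase_series(x, fs, prefiltered=prefiltered)
    coupled = []
    so_starts = np.array([s.start_s for s in sos])
    so_ends = np.array([s.end_s for s in sos])
    for sp in spindles:
        inside = np.flatnonzero((so_starts <= sp.peak_time_s) &
                                (sp.peak_time_s < so_ends))
        if inside.size:
            so = sos[int(inside[0])]
            idx = min(int(round(sp.peak_time_s * fs)), phase.size - 1)
            phi = float(np.rad2deg(phase[idx]))
            if phi <= -180.0:
                phi += 360.0
            coupled.append(CoupledEvent(sp, so, phi))
    if coupled:
        mean_rad, vl = circular_mean_resultant(
            np.deg2rad([c.coupling_phase_deg for c in coupled])
        )
        mean_deg = float(np.rad2deg(mean_rad))
    else:
        mean_deg, vl = float("nan"), 0.0
    summary = CouplingSummary(
        coupled_density=len(coupled) / nrem_minutes,
        mean_phase_deg=mean_deg,
        vector_length=vl,
        n_coupled=len(coupled),
        n_spindles=len(spindles),
    )
    return coupled, summary


def event_density(n_events: int, minutes: float) -> float:
    """Events per minute."""
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    return n_events / minutes


# ---------------------------------------------------------------------------
# Scoring against ground truth
# ---------------------------------------------------------------------------

def score_detection(
    true_onsets: np.ndarray,
    detected_onsets: np.ndarray,
    tol_s: float = 0.25,
) -> tuple[float, float]:
    """Recall and precision of detected event onsets against ground truth.

    Greedy one-to-one matching: each detection matches the nearest unmatched
    true onset within ``tol_s``.
    """
    true_onsets = np.sort(np.asarray(true_onsets, dtype=float))
    detected = np.sort(np.asarray(detected_onsets, dtype=float))
    matched = np.zeros(true_onsets.size, dtype=bool)
    tp = 0
    for d in detected:
        if true_onsets.size == 0:
            break
        i = int(np.argmin(np.where(matched, np.inf, np.abs(true_onsets - d))))
        if not matched[i] and abs(true_onsets[i] - d) <= tol_s:
            matched[i] = True
            tp += 1
    recall = tp / true_onsets.size if true_onsets.size else float("nan")
    precision = tp / detected.size if detected.size else float("nan")
    return recall, precision
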