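"""Welch PSD estimation and individualized spectral-peak detection.

Peak individualization mirrors common sleep-EEG practice: the NREM power
spectrum is estimated with Welch's method (5 s Hamming windows, 50% overlap)
on the *derivative* of the signal, which whitens the 1/f background and makes
band-limited peaks stand out; the most prominent local maximum inside a
broadly defined band (fast-spindle 12.5-16 Hz, theta 3-8 Hz) is then taken as
that individual's peak frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

SPINDLE_BAND = (12.5, 16.0)
THETA_BAND = (3.0, 8.0)


@dataclass
class PSD:
    frequencies: np.ndarray            # Hz, strictly increasing
    power: np.ndarray                  # channels x frequencies, >= 0
    win_s: float = 5.0
    overlap: float = 0.5
    derivative: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class SpectralPeak:
    peak_freq: float
    prominence: float
    band: tuple[float, float]
    fallback_used: bool = False


def welch_psd(
    x: np.ndarray,
    fs: float,
    win_s: float = 5.0,
    overlap: float = 0.5,
    derivative: bool = False,
) -> PSD:
    """Hamming-window Welch periodogram, optionally of the first difference.

    The derivative is scaled by fs (a true d/dt approximation) so power keeps
    interpretable units.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nper = int(round(win_s * fs))
    if x.shape[1] < nper:
        raise ValueError("signal shorter than one Welch window")
    if derivative:
        x = np.diff(x, axis=1) * fs
    f, p = sps.welch(
        x, fs=fs, window="hamming", nperseg=nper,
        noverlap=int(round(nper * overlap)), axis=1,
    )
    return PSD(f, p, win_s, overlap, derivative)


def find_spectral_peak(
    psd: PSD, band: tuple[float, float], channel: int = 0
) -> SpectralPeak:
    """Most prominent in-band local maximum of one channel's spectrum.

    Prominence is topographic: peak height minus the higher of the two
    flanking in-band minima. Ties break toward higher prominence, then lower
    frequency. With no in-band local maximum the band midpoint is returned
    with ``fallback_used=True``.
    """
    f = psd.frequencies
    if band[0] < f[0] or band[1] > f[-1]:
        raise ValueError("band outside PSD frequency support")
    sel = (f >= band[0]) & (f <= band[1])
    pf, pp = f[sel], psd.power[channel, sel]
    peaks, props = sps.find_peaks(pp, prominence=0.0)
    if peaks.size == 0:
        return SpectralPeak(float(np.mean(band)), 0.0, band, fallback_used=True)
    prom = props["prominences"]
    order = np.lexsort((pf[peaks], -prom))
    best = peaks[order[0]]
    return SpectralPeak(float(pf[best]), float(prom[order[0]]), band, False)


def normalize_psd(psd: PSD) -> PSD:
    """Divide each channel's spectrum by its own mean power (mean becomes 1)."""
    mean = psd.power.mean(axis=1, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("zero-power channel cannot be normalized")
    return PSD(psd.frequencies, psd.power / mean, psd.win_s, psd.overlap,
               psd.derivative, normalized=True)


def band_power_around_peak(
    psd: PSD, peak: SpectralPeak, half_width_hz: float = 1.5
) -> tuple[np.ndarray, bool]:
    """Mean power per channel over peak +/- half_width, clipped to the PSD's
    support; returns (values, clipped_flag)."""
    lo = peak.peak_freq - half_width_hz
    hi = peak.peak_freq + half_width_hz
    f = psd.frequencies
    clipped = lo < f[0] or hi > f[-1]
    lo, hi = max(lo, f[0]), min(hi, f[-1])
    sel = (f >= lo) & (f <= hi)
    if not sel.any():
        raise ValueError("empty band after clipping")
    return psd.power[:, sel].mean(axis=1), clipped
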