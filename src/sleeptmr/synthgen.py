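"""Synthetic sleep-EEG sessions, cue protocols, and behavior with ground truth.

The generator emulates the statistical structure of an overnight
targeted-memory-reactivation (TMR) experiment:

* 1/f ("pink") EEG background noise,
* sleep spindles — Hann-windowed sinusoidal bursts at a per-event frequency
  drawn from the fast-spindle band (12.5-16 Hz), 0.5-2 s long,
* slow oscillations (SOs) — single high-amplitude 0.5-1.25 Hz cycles whose
  span runs between two positive-to-negative zero crossings, with the
  negative half-wave emphasized,
* SO-spindle coupling — a configurable fraction of spindles whose envelope
  peak is placed at an SO phase drawn from a von Mises distribution,
* cue-locked responses — a theta-band transient and a later spindle burst
  following memory cues with higher probability than control cues,
* recognition behavior — binomial old/new responses around logit-normal
  participant-level rates whose default means follow the group-mean hit and
  false-alarm rates of the study design this package models.

Every injected event is recorded in a :class:`GroundTruth` object so that
detectors and statistics downstream can be scored without re-deriving truth.
All randomness flows through a single integer seed; identical config + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .sigio import Recording, Hypnogram, EventLog, CUE_CATEGORIES

# Phase convention used throughout the package: 0 deg = SO positive peak,
# +/-180 deg = trough (analytic-signal angle of the delta-filtered trace).


@dataclass
class SpindleSpec:
    rate_per_min: float = 4.0
    freq_range_hz: tuple[float, float] = (12.5, 16.0)
    peak_freq_hz: float | None = None  # participant peak; drawn in-band if None
    freq_sd_hz: float = 0.3     # per-event jitter around the participant peak
    duration_range_s: tuple[float, float] = (0.5, 2.0)
    gain: float = 10.0          # peak amplitude in units of background RMS

    def draw_peak(self, rng: np.random.Generator) -> float:
        """Participant-level fast-spindle peak frequency.

        Individuals have a concentrated spindle peak; events jitter around
        it. When unspecified the peak is drawn from the central part of the
        fast-spindle band.
        """
        if self.peak_freq_hz is not None:
            return self.peak_freq_hz
        lo, hi = self.freq_range_hz
        span = hi - lo
        return float(rng.uniform(lo + 0.25 * span, hi - 0.25 * span))

    def draw_freqs(self, peak: float, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.clip(rng.normal(peak, self.freq_sd_hz, size=n),
                       *self.freq_range_hz)


@dataclass
class SOSpec:
    rate_per_min: float = 5.0
    freq_range_hz: tuple[float, float] = (0.5, 1.25)
    gain: float = 10.0          # trough depth in units of background RMS
    neg_emphasis: float = 1.2   # negative half-wave amplitude multiplier


@dataclass
class CouplingSpec:
    fraction: float = 0.0       # fraction of spindles coupled to an SO
    mu_deg: float = 0.0         # preferred SO phase of the spindle peak
    kappa: float = 5.0          # von Mises concentration


@dataclass
class CueSpec:
    n_memory: int = 46          # 23 negative + 23 neutral per block
    n_control: int = 6
    isi_s: float = 5.0
    start_after_s: float = 300.0   # uninterrupted NREM before cueing starts
    theta_freq_hz: float = 5.5
    theta_latency_s: float = 0.675  # packet center: transient ~0.35-1 s post-cue
    theta_duration_s: float = 0.6
    theta_gain: float = 6.0
    spindle_latency_s: float = 1.05  # burst center: response ~0.8-1.3 s post-cue
    spindle_duration_s: float = 0.7
    spindle_gain: float = 8.0
    latency_jitter_s: float = 0.08
    response_prob: dict[str, float] = field(
        default_factory=lambda: {"negative": 0.7, "neutral": 0.7, "control": 0.2}
    )


#: Group-mean hit rates by (emotion, component, cue condition) and
#: false-alarm rates by lure type, the defaults the behavioral generator
#: draws around (values follow the modeled study's group means).
DEFAULT_HIT_MEANS: dict[tuple[str, str, str], float] = {
    ("negative", "object", "cued"): 0.88,
    ("negative", "object", "uncued"): 0.87,
    ("negative", "background", "cued"): 0.59,
    ("negative", "background", "uncued"): 0.58,
    ("neutral", "object", "cued"): 0.77,
    ("neutral", "object", "uncued"): 0.69,
    ("neutral", "background", "cued"): 0.67,
    ("neutral", "background", "uncued"): 0.71,
}

DEFAULT_FA_MEANS: dict[str, float] = {
    "negative_object": 0.12,
    "neutral_object": 0.09,
    "background": 0.09,
}


@dataclass
class BehaviorSpec:
    hit_means: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_HIT_MEANS)
    )
    fa_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FA_MEANS)
    )
    between_sd: float = 0.5       # SD of participant effects on the logit scale
    deterministic_counts: bool = False  # rounded expected counts, no binomial draw
    n_items_per_cell: int = 23


@dataclass
class SimConfig:
    duration_s: float = 1200.0
    fs: float = 250.0
    channel_labels: tuple[str, ...] = (
        "F3", "F4", "C3", "Cz", "C4", "Pz", "M1", "M2"
    )
    noise_slope: float = 1.0      # 1/f^slope background
    noise_rms_uv: float = 15.0
    mastoid_rms_uv: float = 2.0
    spindle: SpindleSpec = field(default_factory=SpindleSpec)
    so: SOSpec = field(default_factory=SOSpec)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    cue: CueSpec = field(default_factory=CueSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.spindle.rate_per_min < 0 or self.so.rate_per_min < 0:
            raise ValueError("event rates must be nonnegative")
        if not 0.0 <= self.coupling.fraction <= 1.0:
            raise ValueError("coupling fraction must be in [0, 1]")
        if self.coupling.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        for p in self.cue.response_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("response probabilities must be in [0, 1]")
        if self.fs < 2 * max(self.spindle.freq_range_hz):
            raise ValueError("fs does not resolve the spindle band")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["behavior"]["hit_means"] = {
            "|".join(k): v for k, v in self.behavior.hit_means.items()
        }
        return d


@dataclass
class GroundTruth:
    """Exact record of everything the generator injected."""

    spindles: list[dict] = field(default_factory=list)
    sos: list[dict] = field(default_factory=list)
    coupled: list[dict] = field(default_factory=list)
    cue_responses: list[dict] = field(default_factory=list)
    behavior_latents: dict = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            self.spindles + other.spindles,
            self.sos + other.sos,
            self.coupled + other.coupled,
            self.cue_responses + other.cue_responses,
            {**self.behavior_latents, **other.behavior_latents},
        )


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------

def _pink_noise(n: int, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^slope, unit RMS."""
    n_fft = int(2 ** np.ceil(np.log2(max(n, 2))))
    white = rng.standard_normal(n_fft)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_fft, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-slope / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_fft)[:n]
    return x / x.std()


def gen_background(cfg: SimConfig, seed: int | None = None) -> Recording:
    """Channels of 1/f^slope Gaussian noise, RMS-calibrated in microvolts.

    Mastoid channels (M1/M2) get independent low-amplitude noise so that
    mastoid rereferencing is exercised without dominating the EEG.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = int(round(cfg.duration_s * cfg.fs))
    data = np.empty((len(cfg.channel_labels), n))
    for i, lab in enumerate(cfg.channel_labels):
        rms = cfg.mastoid_rms_uv if lab in ("M1", "M2") else cfg.noise_rms_uv
        data[i] = _pink_noise(n, cfg.noise_slope, rng) * rms
    return Recording(data, cfg.fs, list(cfg.channel_labels), "common")


# ---------------------------------------------------------------------------
# Event injection
# ---------------------------------------------------------------------------

def _background_rms(rec: Recording, channels: Sequence[str]) -> float:
    """Robust background RMS in microvolts (1.4826 x median absolute
    deviation), insensitive to sparse high-amplitude injected events so that
    event gains always scale the *background*, not earlier injections."""
    mads = [
        np.median(np.abs(rec.data[rec.channel_index(c)]))
        for c in channels
    ]
    return float(1.4826 * np.median(mads))


def _spindle_waveform(
    dur_s: float, freq: float, amp: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    phase0 = rng.uniform(0, 2 * np.pi)
    return amp * np.hanning(n) * np.cos(2 * np.pi * freq * t + phase0)


def _so_waveform(dur_s: float, amp: float, fs: float, neg_emphasis: float) -> np.ndarray:
    """One SO cycle: trough first, then the positive peak.

    Starts and ends at a positive-to-negative zero crossing so the detector's
    crossing-based span exists by construction.
    """
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    w = -np.sin(2 * np.pi * t / dur_s)
    w[w < 0] *= neg_emphasis
    return amp * w


def _place_events(
    n_events: int,
    dur_samples: Sequence[int],
    n_total: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    margin: int,
    max_tries: int = 20000,
) -> list[int]:
    """Non-overlapping random onsets; raises if the rate is infeasible."""
    onsets: list[int] = []
    taken = list(occupied)
    for d in dur_samples:
        for _ in range(max_tries):
            o = int(rng.integers(margin, n_total - d - margin))
            if all(o + d + margin <= s or o >= e + margin for s, e in taken):
                onsets.append(o)
                taken.append((o, o + d))
                break
        else:
            raise ValueError(
                "event rate infeasible: could not place events without overlap"
            )
    return onsets


def inject_oscillatory_events(
    rec: Recording,
    kind: str,
    spec: SpindleSpec | SOSpec,
    seed: int,
    channels: Sequence[str] | None = None,
    mode: str = "fixed",
    n_events: int | None = None,
) -> tuple[Recording, GroundTruth]:
    """Add spindle bursts or SO cycles to a recording; return the new
    recording and the exact injected intervals.

    ``mode='fixed'`` injects exactly rate x minutes events (default, for exact
    tests); ``mode='poisson'`` draws the count from a Poisson law.
    """
    if kind not in ("spindle", "so"):
        raise ValueError("kind must be 'spindle' or 'so'")
    rng = np.random.default_rng(seed)
    rec = rec.copy()
    if channels is None:
        channels = [c for c in rec.channel_labels if c not in ("M1", "M2")]
    rms = _background_rms(rec, channels)
    minutes = rec.duration_s / 60.0
    if n_events is None:
        lam = spec.rate_per_min * minutes
        n_events = int(round(lam)) if mode == "fixed" else int(rng.poisson(lam))
    gt = GroundTruth()
    peak = spec.draw_peak(rng) if kind == "spindle" else None
    for ch in channels:
        idx = rec.channel_index(ch)
        if kind == "spindle":
            durs = rng.uniform(*spec.duration_range_s, size=n_events)
            freqs = spec.draw_freqs(peak, n_events, rng)
        else:
            f = rng.uniform(*spec.freq_range_hz, size=n_events)
            durs = 1.0 / f
            freqs = f
        dur_samp = [int(round(d * rec.fs)) for d in durs]
        onsets = _place_events(
            n_events, dur_samp, rec.n_samples, rng, [], int(0.2 * rec.fs)
        )
        for o, ds, d, fq in zip(onsets, dur_samp, durs, freqs):
            if kind == "spindle":
                w = _spindle_waveform(d, fq, spec.gain * rms, rec.fs, rng)
                gt.spindles.append(
                    {"channel": ch, "onset_s": o / rec.fs,
                     "offset_s": (o + ds) / rec.fs, "freq_hz": float(fq),
                     "peak_s": (o + ds / 2) / rec.fs}
                )
            else:
                w = _so_waveform(d, spec.gain * rms, rec.fs, spec.neg_emphasis)
                gt.sos.append(
                    {"channel": ch, "start_s": o / rec.fs,
                     "end_s": (o + ds) / rec.fs, "freq_hz": float(fq)}
                )
            rec.data[idx, o:o + len(w)] += w
    return rec, gt


def _phase_to_time(so_wave: np.ndarray, fs: float, phase_deg: float) -> float:
    """Time (s, relative to SO start) at which the SO's analytic phase equals
    ``phase_deg`` under the 0 deg = positive peak convention.

    Computed by numerically inverting the phase of the isolated, zero-padded
    SO template as the coupling analysis measures it (0.5-4 Hz filtering then
    Hilbert transform), so waveform asymmetry and filter shaping cancel out.
    """
    from .events import so_phase_series

    n = len(so_wave)
    pad = max(4 * n, int(6 * fs))
    padded = np.concatenate([np.zeros(pad), so_wave, np.zeros(pad)])
    phase = np.unwrap(so_phase_series(padded, fs))[pad:pad + n]
    target = np.deg2rad(phase_deg)
    # phase rises through roughly [pi/2, 5pi/2] over the cycle
    shifted = phase - phase[0]
    target_shift = np.mod(target - phase[0], 2 * np.pi)
    idx = int(np.argmin(np.abs(shifted - target_shift)))
    return idx / fs


def inject_coupled_events(
    rec: Recording,
    coupling: CouplingSpec,
    so_spec: SOSpec,
    spindle_spec: SpindleSpec,
    seed: int,
    n_so: int,
    channels: Sequence[str] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Inject ``n_so`` SOs per channel; a ``coupling.fraction`` subset carries
    a spindle whose envelope peak sits at a von Mises(mu, kappa) SO phase.
    """
    rng = np.random.default_rng(seed)
    rec = rec.copy()
    if channels is None:
        channels = [c for c in rec.channel_labels if c not in ("M1", "M2")]
    rms = _background_rms(rec, channels)
    gt = GroundTruth()
    n_coupled = int(round(coupling.fraction * n_so))
    sp_peak = spindle_spec.draw_peak(rng)
    for ch in channels:
        idx = rec.channel_index(ch)
        f = rng.uniform(*so_spec.freq_range_hz, size=n_so)
        durs = 1.0 / f
        dur_samp = [int(round(d * rec.fs)) for d in durs]
        onsets = _place_events(
            n_so, dur_samp, rec.n_samples, rng,
            [], int(2.5 * rec.fs)  # margin leaves room for the spindle
        )
        coupled_ids = rng.choice(n_so, size=n_coupled, replace=False)
        phases = np.rad2deg(
            rng.vonmises(np.deg2rad(coupling.mu_deg), coupling.kappa,
                         size=n_coupled)
        ) if coupling.kappa > 0 else rng.uniform(-180, 180, size=n_coupled)
        phase_of = dict(zip(coupled_ids.tolist(), phases))
        for j, (o, ds, d) in enumerate(zip(onsets, dur_samp, durs)):
            w = _so_waveform(d, so_spec.gain * rms, rec.fs, so_spec.neg_emphasis)
            rec.data[idx, o:o + len(w)] += w
            so_ev = {"channel": ch, "start_s": o / rec.fs,
                     "end_s": (o + ds) / rec.fs, "freq_hz": float(f[j])}
            gt.sos.append(so_ev)
            if j in phase_of:
                phi = float(phase_of[j])
                t_peak = o / rec.fs + _phase_to_time(w, rec.fs, phi)
                sdur = rng.uniform(*spindle_spec.duration_range_s)
                sfreq = float(spindle_spec.draw_freqs(sp_peak, 1, rng)[0])
                sw = _spindle_waveform(
                    sdur, sfreq, spindle_spec.gain * rms, rec.fs, rng
                )
                so_start = int(round(t_peak * rec.fs - len(sw) / 2))
                so_start = max(0, min(so_start, rec.n_samples - len(sw)))
                rec.data[idx, so_start:so_start + len(sw)] += sw
                sp_ev = {"channel": ch, "onset_s": so_start / rec.fs,
                         "offset_s": (so_start + len(sw)) / rec.fs,
                         "freq_hz": float(sfreq),
                         "peak_s": (so_start + len(sw) / 2) / rec.fs}
                gt.spindles.append(sp_ev)
                gt.coupled.append(
                    {"channel": ch, "phase_deg": phi,
                     "spindle_peak_s": sp_ev["peak_s"],
                     "so_start_s": so_ev["start_s"], "so_end_s": so_ev["end_s"]}
                )
    return rec, gt


# ---------------------------------------------------------------------------
# Full TMR session
# ---------------------------------------------------------------------------

def _build_hypnogram(duration_s: float, arousal_epochs: Sequence[int] = ()) -> Hypnogram:
    """Schematic night: brief wake/N1 onset, alternating N2/N3 bouts, REM tail."""
    n_ep = int(duration_s // 30)
    stages = ["W", "N1"]
    rem_start = max(2, int(n_ep * 0.85))
    while len(stages) < rem_start:
        stages.extend(["N2"] * 10)
        stages.extend(["N3"] * 10)
    stages = stages[:rem_start]
    stages.extend(["REM"] * (n_ep - len(stages)))
    for i in arousal_epochs:
        if 0 <= i < len(stages):
            stages[i] = "N1"
    return Hypnogram(stages[:n_ep])


def gen_tmr_session(
    cfg: SimConfig, arousal_epochs: Sequence[int] = ()
) -> tuple[Recording, Hypnogram, EventLog, GroundTruth]:
    """Generate one participant-night: background + endogenous events +
    cue protocol with cue-locked responses.

    Cue blocks contain ``n_memory`` memory sounds (half negative, half
    neutral) and ``n_control`` control sounds, shuffled anew each block and
    delivered at a fixed inter-stimulus interval, only during N2/N3; delivery
    pauses across arousals and resumes afterwards.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rec = gen_background(cfg, seed=int(rng.integers(2**31)))
    hyp = _build_hypnogram(cfg.duration_s, arousal_epochs)

    # endogenous events only inside NREM, on the analysis channels
    rec, gt = inject_oscillatory_events(
        rec, "spindle", cfg.spindle, int(rng.integers(2**31))
    )
    if cfg.coupling.fraction > 0:
        n_so = int(round(cfg.so.rate_per_min * cfg.duration_s / 60.0))
        rec, gt2 = inject_coupled_events(
            rec, cfg.coupling, cfg.so, cfg.spindle,
            int(rng.integers(2**31)), n_so
        )
    else:
        rec, gt2 = inject_oscillatory_events(
            rec, "so", cfg.so, int(rng.integers(2**31))
        )
    gt = gt.merge(gt2)

    # --- cue protocol -----------------------------------------------------
    cs = cfg.cue
    n_neg = cs.n_memory // 2
    block_template = (
        ["negative"] * n_neg
        + ["neutral"] * (cs.n_memory - n_neg)
        + ["control"] * cs.n_control
    )
    eeg_idx = [rec.channel_index(c) for c in rec.channel_labels
               if c not in ("M1", "M2")]
    rms = _background_rms(rec, [rec.channel_labels[i] for i in eeg_idx])

    events: list[tuple[int, str, str, int]] = []
    t = cs.start_after_s
    block = 0
    max_t = cfg.duration_s - 4.0  # keep the post-cue window in-record
    while t < max_t:
        order = list(block_template)
        rng.shuffle(order)
        for cat in order:
            stage = hyp.stage_at(t)
            # cueing halts outside N2/N3; resume at the next NREM epoch
            while stage not in ("N2", "N3"):
                t = (int(t // 30) + 1) * 30.0
                stage = hyp.stage_at(t)
                if t >= max_t or stage is None:
                    break
            if t >= max_t or stage is None:
                break
            onset = int(round(t * rec.fs))
            events.append((onset, cat, stage, block))
            responded = bool(rng.random() < cs.response_prob[cat])
            resp = {"onset_sample": onset, "category": cat,
                    "responded": responded}
            if responded:
                lat_t = cs.theta_latency_s + rng.normal(0, cs.latency_jitter_s)
                lat_s = cs.spindle_latency_s + rng.normal(0, cs.latency_jitter_s)
                th = _spindle_waveform(
                    cs.theta_duration_s, cs.theta_freq_hz,
                    cs.theta_gain * rms, rec.fs, rng
                )
                sp = _spindle_waveform(
                    cs.spindle_duration_s,
                    float(np.mean(cfg.spindle.freq_range_hz)),
                    cs.spindle_gain * rms, rec.fs, rng
                )
                th_on = int(round((t + lat_t) * rec.fs - len(th) / 2))
                sp_on = int(round((t + lat_s) * rec.fs - len(sp) / 2))
                for i in eeg_idx:
                    rec.data[i, th_on:th_on + len(th)] += th
                    rec.data[i, sp_on:sp_on + len(sp)] += sp
                resp["theta_center_s"] = t + lat_t
                resp["spindle_center_s"] = t + lat_s
                gt.spindles.append(
                    {"channel": "Cz", "onset_s": sp_on / rec.fs,
                     "offset_s": (sp_on + len(sp)) / rec.fs,
                     "freq_hz": float(np.mean(cfg.spindle.freq_range_hz)),
                     "peak_s": (sp_on + len(sp) / 2) / rec.fs,
                     "cue_locked": True}
                )
            gt.cue_responses.append(resp)
            t += cs.isi_s
            if t >= max_t:
                break
        block += 1
    return rec, hyp, EventLog(events), gt


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _mean_preserving_base(mean: float, sigma: float) -> float:
    """Logit-scale location b such that E[expit(b + sigma*Z)] = mean.

    A plain logit(mean) location shrinks the probability-scale mean toward
    0.5 (Jensen); this correction keeps group means at the configured
    condition means for any between-participant spread.
    """
    from numpy.polynomial.hermite_e import hermegauss
    from scipy.optimize import brentq

    if sigma == 0:
        return float(_logit(mean))
    z, w = hermegauss(40)
    w = w / w.sum()

    def f(b: float) -> float:
        return float(np.sum(w * _expit(b + sigma * z))) - mean

    return float(brentq(f, -20.0, 20.0))


def gen_behavior(
    n_participants: int,
    spec: BehaviorSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Item-level recognition responses for ``n_participants``.

    Each participant sees 368 recognition trials: 4 x 23 old objects
    (emotion x cued), 4 x 23 old backgrounds, 2 x 46 new objects
    (emotion), and 92 new (all-neutral) backgrounds. Participant rates are
    logit-normal around the condition means; responses are binomial counts
    over items (or rounded expected counts when
    ``spec.deterministic_counts``).
    """
    spec = spec or BehaviorSpec()
    for p in list(spec.hit_means.values()) + list(spec.fa_means.values()):
        if not 0.0 <= p <= 1.0:
            raise ValueError("behavioral means must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cell = spec.n_items_per_cell
    rows = []
    gt = GroundTruth()
    for p_id in range(n_participants):
        latents: dict[str, float] = {}
        offset = rng.normal(0.0, spec.between_sd) if spec.between_sd > 0 else 0.0

        sigma_total = spec.between_sd * np.sqrt(1.25)  # offset + cell noise

        def rate(mean: float) -> float:
            if spec.between_sd == 0:
                return mean
            b = _mean_preserving_base(mean, sigma_total)
            return float(_expit(b + offset + rng.normal(0, spec.between_sd / 2)))

        def n_old(n_items: int, p_rate: float) -> int:
            if spec.deterministic_counts:
                return int(round(n_items * p_rate))
            return int(rng.binomial(n_items, p_rate))

        item = 0
        # old items
        for (emotion, component, cue), mean in spec.hit_means.items():
            r = rate(mean)
            latents[f"hit|{emotion}|{component}|{cue}"] = r
            k = n_old(n_cell, r)
            for i in range(n_cell):
                rows.append(
                    (p_id, item, component, emotion, cue, "old",
                     "old" if i < k else "new")
                )
                item += 1
        # new (lure) items
        lure_cells = [
            ("negative", "object", 2 * n_cell, spec.fa_means["negative_object"]),
            ("neutral", "object", 2 * n_cell, spec.fa_means["neutral_object"]),
            ("neutral", "background", 4 * n_cell, spec.fa_means["background"]),
        ]
        for emotion, component, n_items, mean in lure_cells:
            r = rate(mean)
            latents[f"fa|{emotion}|{component}"] = r
            k = n_old(n_items, r)
            for i in range(n_items):
                rows.append(
                    (p_id, item, component, emotion, "na", "new",
                     "old" if i < k else "new")
                )
                item += 1
        gt.behavior_latents[p_id] = latents
    df = pd.DataFrame(
        rows,
        columns=["participant", "item", "component", "emotion", "cue",
                 "old_new", "response"],
    )
    return df, gt
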