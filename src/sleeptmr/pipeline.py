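"""End-to-end orchestration: synthetic session -> preprocessing -> spectra ->
event detection -> cue-locked statistics -> behavioral scoring.

``run_full`` simulates a cohort of participant-nights, runs every analysis
stage on each, then computes group-level statistics (cluster-based
permutation contrast of memory vs. control cues, spindle-probability
contrast, one-sample t tests with FDR on cueing benefits, robust regression
of cueing benefit on cluster power, circular-linear correlation of coupling
phase with recognition). Every stage seed derives from one master seed, so a
run is fully reproducible; the effective configuration is embedded in the
report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cueresp, events, memstats, preprocess, spectral, synthgen
from .sigio import Hypnogram, stage_mask, NREM_STAGES


@dataclass
class RunConfig:
    sim: synthgen.SimConfig = field(default_factory=synthgen.SimConfig)
    n_participants: int = 6
    n_perm: int = 500
    channel: str = "Cz"
    seed: int = 0
    notch_hz: float = 60.0
    highpass_hz: float = 0.3
    target_fs: float = 250.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


def demo_config(seed: int = 0) -> RunConfig:
    """Small built-in configuration that completes in a few minutes."""
    sim = synthgen.SimConfig(
        duration_s=600.0,
        coupling=synthgen.CouplingSpec(fraction=0.5, mu_deg=-30.0, kappa=5.0),
        cue=synthgen.CueSpec(start_after_s=60.0),
    )
    return RunConfig(sim=sim, n_participants=5, n_perm=200, seed=seed)


def _analyze_participant(cfg: RunConfig, sim_cfg: synthgen.SimConfig) -> dict:
    """All within-participant stages; returns per-participant features."""
    ch = cfg.channel
    rec, hyp, log, gt = synthgen.gen_tmr_session(sim_cfg)

    # --- preprocessing ----------------------------------------------------
    rec = preprocess.resample(rec, cfg.target_fs)
    rec = preprocess.filter_signal(rec, "notch", cfg.notch_hz)
    rec = preprocess.filter_signal(rec, "highpass", cfg.highpass_hz)
    rec = preprocess.rereference(rec)
    eeg = [c for c in rec.channel_labels if c not in ("M1", "M2")]

    nrem_log = synthgen.EventLog(
        [e for e in log.events if e[2] in ("N2", "N3")]
    )
    ep = preprocess.epoch(rec, nrem_log)
    ep, reject_report = preprocess.reject_epochs(ep, eeg_channels=eeg)

    positions = preprocess.montage_positions(eeg)
    rec_clean, nrem_clean, hjorth_report = preprocess.hjorth_artifact_pass(
        rec, hyp, stages=("N2", "N3"), positions=positions, eeg_channels=eeg
    )
    # sample-level clean mask over NREM
    fs = rec.fs
    nrem_eps = [i for i, s in enumerate(hyp.stages)
                if s in ("N2", "N3")
                and (i + 1) * hyp.epoch_length_s * fs <= rec.n_samples]
    clean_mask = np.zeros(rec.n_samples, dtype=bool)
    esamp = int(round(hyp.epoch_length_s * fs))
    for k, e in enumerate(nrem_eps):
        if nrem_clean[k]:
            clean_mask[e * esamp:(e + 1) * esamp] = True
    nrem_minutes = clean_mask.sum() / fs / 60.0

    # --- spectra ----------------------------------------------------------
    x = rec_clean.get_channel(ch)
    psd = spectral.welch_psd(x[clean_mask], fs, derivative=True)
    sp_peak = spectral.find_spectral_peak(psd, spectral.SPINDLE_BAND)

    rem_mask = stage_mask(hyp, ["REM"], fs, rec.n_samples)
    rem_theta = None
    if rem_mask.sum() >= 5 * fs:
        rem_psd = spectral.welch_psd(x[rem_mask], fs, derivative=True)
        rem_psd_n = spectral.normalize_psd(
            spectral.welch_psd(x[rem_mask], fs, derivative=False)
        )
        th_peak = spectral.find_spectral_peak(rem_psd, spectral.THETA_BAND)
        vals, _ = spectral.band_power_around_peak(rem_psd_n, th_peak)
        rem_theta = {"peak_hz": th_peak.peak_freq,
                     "band_power": float(vals[0]),
                     "fallback": th_peak.fallback_used}

    # --- events & coupling ------------------------------------------------
    spindles = events.detect_spindles(
        x, fs, sp_peak.peak_freq, clean_mask, channel=ch
    )
    sos = events.detect_slow_oscillations(x, fs, clean_mask, channel=ch)
    coupled, coup = events.couple(spindles, sos, x, fs, nrem_minutes)

    # --- cue-locked analysis ----------------------------------------------
    kept_idx = np.flatnonzero(ep.kept)
    mem_idx = [i for i in kept_idx if ep.categories[i] in ("negative", "neutral")]
    ctl_idx = [i for i in kept_idx if ep.categories[i] == "control"]
    ep_mem = ep.subset(np.array(mem_idx))
    ep_ctl = ep.subset(np.array(ctl_idx))
    ep_mem, ep_ctl = cueresp.match_trials(ep_mem, ep_ctl, seed=sim_cfg.seed)
    tfr_mem = cueresp.db_normalize(cueresp.tfr_morlet(ep_mem, channel=ch))
    tfr_ctl = cueresp.db_normalize(cueresp.tfr_morlet(ep_ctl, channel=ch))
    diff_map = tfr_mem.power[0] - tfr_ctl.power[0]

    def _ep_spindles(idx: list[int]) -> list[list[tuple[float, float]]]:
        out = []
        for i in idx:
            onset_s = nrem_log.events[i][0] / fs
            out.append([
                (s.onset_s - onset_s, s.offset_s - onset_s)
                for s in spindles
                if s.offset_s > onset_s - 1.0 and s.onset_s < onset_s + 3.0
            ])
        return out

    times = ep.times
    prob_mem = cueresp.spindle_probability(times, _ep_spindles(mem_idx))
    prob_ctl = cueresp.spindle_probability(times, _ep_spindles(ctl_idx))

    return {
        "n_cues": len(log), "n_cues_nrem": len(nrem_log),
        "n_rejected": len(reject_report.removed_epochs),
        "n_hjorth_removed": len(hjorth_report.removed_epochs),
        "spindle_peak_hz": sp_peak.peak_freq,
        "n_spindles": len(spindles), "n_sos": len(sos),
        "spindle_density": events.event_density(len(spindles), nrem_minutes),
        "coupling": dataclasses.asdict(coup),
        "rem_theta": rem_theta,
        "tfr_freqs": cueresp.TFR_FREQS,
        "tfr_times": times,
        "diff_map": diff_map,
        "prob_mem": prob_mem,
        "prob_ctl": prob_ctl,
        "architecture": dataclasses.asdict(memstats.sleep_architecture(hyp)),
    }


def run_full(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full cohort analysis; optionally write report + artifacts."""
    rng = np.random.default_rng(cfg.seed)
    part_seeds = rng.integers(2 ** 31, size=cfg.n_participants)
    per_part = []
    for p in range(cfg.n_participants):
        sim_cfg = dataclasses.replace(cfg.sim, seed=int(part_seeds[p]))
        per_part.append(_analyze_participant(cfg, sim_cfg))

    # group-level EEG statistics
    diff_maps = np.stack([p["diff_map"] for p in per_part])
    clusters = cueresp.cluster_permutation(
        diff_maps, n_perm=cfg.n_perm, seed=cfg.seed
    )
    prob_diff = np.stack([p["prob_mem"] - p["prob_ctl"] for p in per_part])
    prob_clusters = cueresp.cluster_permutation(
        prob_diff, n_perm=cfg.n_perm, seed=cfg.seed + 1
    )

    # behavior
    behavior, _ = synthgen.gen_behavior(
        cfg.n_participants, cfg.sim.behavior, seed=int(rng.integers(2 ** 31))
    )
    scores = memstats.score_behavior(behavior)
    benefit_tests = {}
    pvals, keys = [], []
    for (emotion, component), d in scores.groupby(["emotion", "component"]):
        t, df, p = memstats.one_sample_t(d["cueing_benefit"].to_numpy())
        benefit_tests[f"{emotion}_{component}"] = {
            "mean": float(d["cueing_benefit"].mean()), "t": t, "df": df, "p": p,
        }
        keys.append(f"{emotion}_{component}")
        pvals.append(p)
    for k, padj in zip(keys, memstats.fdr_adjust(np.array(pvals))):
        benefit_tests[k]["p_fdr"] = float(padj)

    # brain-behavior links
    regressions = {}
    if clusters and clusters[0].p_corrected < 0.05:
        power = cueresp.cluster_average(diff_maps, clusters[0])
        obj = scores[scores.component == "object"]
        neu = obj[obj.emotion == "neutral"].sort_values("participant")
        y = neu["cueing_benefit"].to_numpy()
        if y.size == power.size:
            fit = memstats.robust_regress(y, power)
            regressions["benefit_on_cluster_power"] = {
                "params": fit.params.tolist(), "pvalues": fit.pvalues.tolist(),
            }
    phases = np.array([p["coupling"]["mean_phase_deg"] for p in per_part])
    crs = scores[(scores.component == "object") & (scores.emotion == "neutral")]\
        .sort_values("participant")["cr_cued"].to_numpy()
    circ = None
    if phases.size >= 4 and np.isfinite(phases).all() and np.std(crs) > 0:
        r, p = memstats.circ_linear_corr(phases, crs)
        circ = {"r": r, "p": p}

    report = {
        "config": cfg.to_dict(),
        "participants": [
            {k: _jsonable(v) for k, v in p.items()
             if k not in ("diff_map", "prob_mem", "prob_ctl",
                          "tfr_freqs", "tfr_times")}
            for p in per_part
        ],
        "tfr_clusters": [_cluster_dict(c, per_part[0]) for c in clusters],
        "spindle_prob_clusters": [
            _cluster_dict(c, per_part[0], onedim=True) for c in prob_clusters
        ],
        "cueing_benefit_tests": benefit_tests,
        "regressions": regressions,
        "circular_linear": circ,
        "behavior_means": {
            f"{e}_{c}": float(
                scores[(scores.emotion == e) & (scores.component == c)]
                ["cr_cued"].mean()
            )
            for e in ("negative", "neutral") for c in ("object", "background")
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        scores.to_csv(out / "behavior_scores.csv", index=False)
        memstats.to_long_format(scores).to_csv(
            out / "behavior_long.csv", index=False
        )
    return report


def _cluster_dict(c, part: dict, onedim: bool = False) -> dict:
    times = part["tfr_times"]
    d = {"t_sum": c.t_sum, "p": c.p_corrected, "sign": c.sign}
    if onedim:
        idx = np.flatnonzero(c.members)
        d["time_s"] = [float(times[idx[0]]), float(times[idx[-1]])]
    else:
        fsel = c.members.any(axis=1)
        tsel = c.members.any(axis=0)
        freqs = part["tfr_freqs"]
        d["freq_hz"] = [float(freqs[fsel].min()), float(freqs[fsel].max())]
        d["time_s"] = [float(times[tsel].min()), float(times[tsel].max())]
    return d


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
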