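import numpy as np
import pytest

from sleeptmr import synthgen
from sleeptmr.events import (
    couple,
    detect_slow_oscillations,
    detect_spindles,
    event_density,
    score_detection,
)
from sleeptmr.spectral import SPINDLE_BAND, find_spectral_peak, welch_psd


def _pink(dur=120.0, seed=0, fs=250.0):
    cfg = synthgen.SimConfig(duration_s=dur, channel_labels=("Cz",), seed=seed)
    return synthgen.gen_background(cfg).data[0], fs


class TestSpindleDetector:
    def test_injected_burst_localized(self):
        x, fs = _pink(seed=1)
        t = np.arange(x.size) / fs
        onset, dur = 60.0, 1.0
        burst = np.zeros_like(x)
        sel = (t >= onset) & (t < onset + dur)
        burst[sel] = np.hanning(sel.sum()) * 10 * x.std()
        x = x + burst * np.cos(2 * np.pi * 13.0 * (t - onset))
        events = detect_spindles(x, fs, 13.0)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(onset, abs=0.1)
        assert events[0].offset_s == pytest.approx(onset + dur, abs=0.1)
        assert events[0].peak_time_s == pytest.approx(onset + dur / 2, abs=0.1)

    def test_short_burst_rejected(self):
        """A supra-threshold burst shorter than 400 ms is not an event."""
        x, fs = _pink(seed=2)
        t = np.arange(x.size) / fs
        sel = (t >= 60.0) & (t < 60.2)  # 200 ms raw burst
        x[sel] += np.hanning(sel.sum()) * 30 * x.std() * np.cos(
            2 * np.pi * 13.0 * t[sel])
        # use a tight wavelet so smoothing cannot stretch 0.2 s past 0.4 s
        events = detect_spindles(x, fs, 13.0, fwhm_hz=6.0)
        assert events == []

    def test_zero_signal_degenerate_threshold(self):
        with pytest.warns(UserWarning, match="degenerate"):
            events = detect_spindles(np.zeros(25000), 250.0, 13.0)
        assert events == []

    def test_threshold_monotonicity(self):
        x, fs = _pink(dur=300.0, seed=3)
        cfg = synthgen.SimConfig(duration_s=300.0, channel_labels=("Cz",),
                                 seed=3)
        rec, _ = synthgen.inject_oscillatory_events(
            synthgen.gen_background(cfg), "spindle", cfg.spindle, seed=4)
        x = rec.data[0]
        counts = [len(detect_spindles(x, fs, 14.0, threshold_factor=k))
                  for k in (3, 6, 9, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_artifact_overlap_discarded(self):
        cfg = synthgen.SimConfig(duration_s=300.0, channel_labels=("Cz",),
                                 seed=5)
        rec, gt = synthgen.inject_oscillatory_events(
            synthgen.gen_background(cfg), "spindle", cfg.spindle, seed=6)
        x = rec.data[0]
        mask = np.ones(x.size, dtype=bool)
        first = gt.spindles[0]
        mask[int(first["onset_s"] * 250):int(first["offset_s"] * 250)] = False
        events = detect_spindles(x, 250.0, 14.0, clean_mask=mask)
        assert all(not (e.onset_s < first["offset_s"]
                        and e.offset_s > first["onset_s"]) for e in events)

    def test_benchmark_recall_precision(self, benchmark_session):
        cfg, rec, gt_sp, _ = benchmark_session
        x = rec.get_channel("Cz")
        pk = find_spectral_peak(welch_psd(x, cfg.fs, derivative=True),
                                SPINDLE_BAND)
        det = detect_spindles(x, cfg.fs, pk.peak_freq)
        recall, precision = score_detection(
            np.array([e["onset_s"] for e in gt_sp.spindles]),
            np.array([e.onset_s for e in det]), tol_s=0.25)
        assert recall >= 0.9 and precision >= 0.9


class TestSODetector:
    def test_pure_sinusoid_spans(self):
        fs = 250.0
        t = np.arange(int(fs * 120)) / fs
        x = 50 * np.sin(2 * np.pi * 0.75 * t)
        events = detect_slow_oscillations(x, fs, prefiltered=True)
        durs = [e.duration_s for e in events]
        np.testing.assert_allclose(durs, 1 / 0.75, atol=0.02)
        # 120 s at 0.75 Hz: ~89 full candidate spans, top quartile retained
        assert len(events) == int(np.ceil(89 / 4))

    def test_too_slow_sinusoid_no_candidates(self):
        fs = 250.0
        t = np.arange(int(fs * 120)) / fs
        x = 50 * np.sin(2 * np.pi * 0.4 * t)  # 2.5 s spans
        with pytest.raises(ValueError, match="no slow-oscillation"):
            detect_slow_oscillations(x, fs, prefiltered=True)

    def test_top_quartile_selection(self):
        """With distinct candidate amplitudes, exactly the ceil(n/4) largest
        survive."""
        fs = 250.0
        cycle = np.concatenate([
            -np.sin(2 * np.pi * np.arange(int(fs)) / fs),
            np.zeros(int(fs))])  # 1 s SO + 1 s silence -> distinct candidates
        amps = np.arange(1.0, 41.0)
        x = np.concatenate([a * cycle for a in amps])
        events = detect_slow_oscillations(x, fs, prefiltered=True)
        kept = sorted(e.peak_to_peak for e in events)
        assert len(events) == 10
        assert min(kept) > 2 * amps[-11]  # the 10 largest amplitudes only

    def test_trough_inside_span(self, benchmark_session):
        cfg, rec, _, _ = benchmark_session
        events = detect_slow_oscillations(rec.get_channel("Cz"), cfg.fs)
        for e in events:
            assert e.start_s < e.trough_time_s < e.end_s
            assert 0.8 <= e.duration_s <= 2.0


class TestCoupling:
    def test_phase_convention_trough_is_180(self):
        from sleeptmr.events import SOEvent, SpindleEvent

        fs = 250.0
        t = np.arange(int(fs * 60)) / fs
        x = 50 * np.cos(2 * np.pi * 1.0 * t)  # peak at integer seconds
        sp = [SpindleEvent("Cz", 10.3, 10.7, 5.0, 10.5, 13.0)]  # at trough
        so = [SOEvent("Cz", 9.75, 10.75, 100.0, 10.5)]
        coupled, summ = couple(sp, so, x, fs, 1.0, prefiltered=True)
        assert len(coupled) == 1
        assert abs(coupled[0].coupling_phase_deg) == pytest.approx(180, abs=3)

    def test_identical_phases_unit_vector_length(self):
        from sleeptmr.events import SOEvent, SpindleEvent

        fs = 250.0
        t = np.arange(int(fs * 60)) / fs
        x = 50 * np.cos(2 * np.pi * 1.0 * t)
        sp = [SpindleEvent("Cz", k - 0.2, k + 0.2, 5.0, float(k), 13.0)
              for k in (10, 20, 30)]  # all at positive peaks
        so = [SOEvent("Cz", k - 0.5, k + 0.5, 100.0, k + 0.5)
              for k in (10, 20, 30)]
        coupled, summ = couple(sp, so, x, fs, 1.0, prefiltered=True)
        assert summ.n_coupled == 3
        assert summ.vector_length == pytest.approx(1.0, abs=1e-3)
        assert summ.mean_phase_deg == pytest.approx(0.0, abs=3)

    @pytest.mark.parametrize("mu", [0.0, 90.0, -90.0, 180.0])
    def test_phase_round_trip(self, mu):
        """Injecting spindle peaks at a fixed SO phase recovers that phase."""
        cfg = synthgen.SimConfig(
            duration_s=1200.0, channel_labels=("Cz", "M1", "M2"), seed=3,
            coupling=synthgen.CouplingSpec(fraction=1.0, mu_deg=mu,
                                           kappa=1e6))
        bg = synthgen.gen_background(cfg)
        rec, gt = synthgen.inject_coupled_events(
            bg, cfg.coupling, cfg.so, cfg.spindle, seed=4, n_so=60,
            channels=["Cz"])
        x = rec.get_channel("Cz")
        sp = detect_spindles(x, cfg.fs, 14.0)
        so = detect_slow_oscillations(x, cfg.fs)
        _, summ = couple(sp, so, x, cfg.fs, 20.0)
        err = (summ.mean_phase_deg - mu + 180) % 360 - 180
        assert abs(err) <= 10

    def test_recovery_mu_minus30_kappa5(self, coupled_session):
        from scipy.special import i0, i1

        cfg, rec, gt = coupled_session
        x = rec.get_channel("Cz")
        pk = find_spectral_peak(welch_psd(x, cfg.fs, derivative=True),
                                SPINDLE_BAND)
        sp = detect_spindles(x, cfg.fs, pk.peak_freq)
        so = detect_slow_oscillations(x, cfg.fs)
        coupled, summ = couple(sp, so, x, cfg.fs, cfg.duration_s / 60.0)
        err = (summ.mean_phase_deg + 30 + 180) % 360 - 180
        assert abs(err) <= 10
        assert abs(summ.vector_length - i1(5) / i0(5)) <= 0.1

    def test_coupling_closure_invariant(self, coupled_session):
        cfg, rec, _ = coupled_session
        x = rec.get_channel("Cz")
        sp = detect_spindles(x, cfg.fs, 14.0)
        so = detect_slow_oscillations(x, cfg.fs)
        coupled, _ = couple(sp, so, x, cfg.fs, 40.0)
        assert coupled, "expected coupled events on the coupled benchmark"
        for c in coupled:
            assert c.so.start_s <= c.spindle.peak_time_s < c.so.end_s
            assert -180 < c.coupling_phase_deg <= 180

    def test_mismatched_channels_error(self):
        from sleeptmr.events import SOEvent, SpindleEvent

        sp = [SpindleEvent("Cz", 1.0, 1.5, 5.0, 1.2, 13.0)]
        so = [SOEvent("Fz", 0.9, 1.9, 100.0, 1.4)]
        with pytest.raises(ValueError, match="same channel"):
            couple(sp, so, np.zeros(2500), 250.0, 1.0)


class TestDensity:
    def test_values(self):
        assert event_density(30, 60.0) == 0.5
        assert event_density(0, 10.0) == 0.0
        with pytest.raises(ValueError):
            event_density(5, 0.0)

    def test_benchmark_density_recovered(self, benchmark_session):
        cfg, rec, gt_sp, _ = benchmark_session
        x = rec.get_channel("Cz")
        det = detect_spindles(x, cfg.fs, 14.4)
        d = event_density(len(det), cfg.duration_s / 60.0)
        true_d = len(gt_sp.spindles) / (cfg.duration_s / 60.0)
        assert d == pytest.approx(true_d, rel=0.15)
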