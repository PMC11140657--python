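import numpy as np
import pytest

from sleeptmr import preprocess
from sleeptmr.preprocess import (
    ArtifactReport,
    epoch,
    filter_signal,
    hjorth_artifact_pass,
    hjorth_params,
    interpolate_channel,
    montage_positions,
    rereference,
    resample,
    reject_epochs,
)
from sleeptmr.sigio import EventLog, Hypnogram, Recording


def _sine_rec(freq, fs=250.0, dur=10.0, amp=1.0, labels=("Cz",)):
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return Recording(np.tile(x, (len(labels), 1)), fs, list(labels))


class TestResample:
    def test_sinusoid_amplitude_preserved(self):
        rec = _sine_rec(10.0, fs=500.0)
        out = resample(rec, 250.0)
        assert out.fs == 250.0
        mid = out.data[0][200:-200]
        assert abs(mid.max() - 1.0) < 0.01

    def test_identity_and_upsampling_error(self):
        rec = _sine_rec(10.0)
        np.testing.assert_array_equal(resample(rec, 250.0).data, rec.data)
        with pytest.raises(ValueError, match="out of scope"):
            resample(rec, 500.0)

    def test_sample_count_halves(self):
        rec = _sine_rec(10.0, fs=500.0, dur=4.0)
        assert resample(rec, 250.0).n_samples == rec.n_samples // 2


class TestFilters:
    def test_notch_attenuates_mains(self):
        rec = _sine_rec(60.0)
        out = filter_signal(rec, "notch", 60.0)
        assert out.data[0][500:-500].std() < 0.05 * rec.data[0].std()

    def test_highpass_removes_drift(self):
        rec = _sine_rec(0.1, dur=60.0)
        out = filter_signal(rec, "highpass", 0.3)
        assert out.data[0].std() < 0.5 * rec.data[0].std()

    def test_bandpass_passes_inband(self):
        rec = _sine_rec(1.0, dur=60.0)
        out = filter_signal(rec, "bandpass", (0.5, 4.0))
        mid = out.data[0][2500:-2500]
        assert abs(mid.max() - 1.0) < 0.05

    def test_cutoff_above_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_signal(_sine_rec(10.0), "highpass", 200.0)

    def test_zero_phase_time_reversal(self, rng):
        """Linear zero-phase filtering commutes with time reversal away from
        the edge-transient region."""
        rec = Recording(rng.standard_normal((1, 8000)), 250.0, ["Cz"])
        rev = Recording(rec.data[:, ::-1].copy(), 250.0, ["Cz"])
        fwd = filter_signal(rec, "bandpass", (5.0, 20.0)).data[0]
        bwd = filter_signal(rev, "bandpass", (5.0, 20.0)).data[0][::-1]
        np.testing.assert_allclose(fwd[500:-500], bwd[500:-500], atol=1e-7)

    def test_zero_phase_no_delay(self):
        """A filtered in-band sinusoid keeps its phase (zero-phase filter)."""
        rec = _sine_rec(10.0, dur=20.0)
        out = filter_signal(rec, "bandpass", (5.0, 20.0)).data[0]
        mid = slice(1000, -1000)
        r = np.corrcoef(out[mid], rec.data[0][mid])[0, 1]
        assert r > 0.999


class TestRereference:
    def _rec(self, rng, mast):
        data = rng.standard_normal((3, 100))
        data[1:] = mast
        return Recording(data, 250.0, ["Cz", "M1", "M2"])

    def test_zero_mastoids_identity(self, rng):
        rec = self._rec(rng, 0.0)
        np.testing.assert_array_equal(rereference(rec).data[0], rec.data[0])

    def test_constant_offset_subtracted(self, rng):
        rec = self._rec(rng, 5.0)
        np.testing.assert_allclose(rereference(rec).data[0],
                                   rec.data[0] - 5.0)

    def test_idempotent(self, rng):
        rec = self._rec(rng, 5.0)
        once = rereference(rec)
        np.testing.assert_allclose(rereference(once).data, once.data)

    def test_missing_mastoid(self, rng):
        rec = Recording(rng.standard_normal((1, 10)), 250.0, ["Cz"])
        with pytest.raises(KeyError, match="reference"):
            rereference(rec)


class TestEpoching:
    def test_index_arithmetic(self, rng):
        rec = Recording(rng.standard_normal((1, 5000)), 250.0, ["Cz"])
        ep = epoch(rec, EventLog([(2500, "neutral", "N2", 0)]),
                   baseline=False)
        assert ep.data.shape == (1, 1, 1000)
        np.testing.assert_array_equal(ep.data[0, 0], rec.data[0, 2250:3250])

    def test_baseline_zeroes_constant_signal(self):
        rec = Recording(np.full((1, 5000), 7.0), 250.0, ["Cz"])
        ep = epoch(rec, EventLog([(2500, "neutral", "N2", 0)]), baseline=True)
        np.testing.assert_allclose(ep.data, 0.0)

    def test_edge_trial_flagged_not_dropped(self, rng):
        rec = Recording(rng.standard_normal((1, 2000)), 250.0, ["Cz"])
        ep = epoch(rec, EventLog([(125, "neutral", "N2", 0)]))
        assert ep.n_trials == 1 and not ep.kept[0]
        assert ep.rejection_reason[0] == "edge"


class TestRejectEpochs:
    def _epochs(self, rng, n=50):
        rec = Recording(rng.standard_normal((2, 300 * 250)) * 20, 250.0,
                        ["Cz", "Pz"])
        events = EventLog([(1000 + i * 1200, "neutral", "N2", 0)
                           for i in range(n)])
        return rec, epoch(rec, events, baseline=False)

    def test_amplitude_flag(self, rng):
        rec, _ = self._epochs(rng)
        rec.data[0, 1000 + 10 * 1200 + 100] = 600.0
        ep = epoch(rec, EventLog([(1000 + i * 1200, "neutral", "N2", 0)
                                  for i in range(50)]), baseline=False)
        out, rep = reject_epochs(ep)
        assert out.rejection_reason[10] == "amplitude"

    def test_clean_gaussian_few_rejections(self, rng):
        _, ep = self._epochs(rng)
        out, rep = reject_epochs(ep)
        # jointprob at 6/2 SD on iid trials: expect at most a couple flagged
        assert len(rep.removed_epochs) <= 3

    def test_high_variance_trial_flagged(self, rng):
        rec, _ = self._epochs(rng)
        sl = slice(1000 + 20 * 1200 - 250, 1000 + 20 * 1200 + 750)
        rec.data[:, sl] *= np.sqrt(10)  # 10x variance, below the 500 uV bound
        ep = epoch(rec, EventLog([(1000 + i * 1200, "neutral", "N2", 0)
                                  for i in range(50)]), baseline=False)
        out, rep = reject_epochs(ep)
        assert out.rejection_reason[20] == "jointprob"

    def test_never_modifies_samples(self, rng):
        _, ep = self._epochs(rng)
        before = ep.data.copy()
        out, _ = reject_epochs(ep)
        np.testing.assert_array_equal(out.data, before)

    def test_too_few_trials(self, rng):
        rec = Recording(rng.standard_normal((1, 20000)), 250.0, ["Cz"])
        ep = epoch(rec, EventLog([(1000, "neutral", "N2", 0),
                                  (3000, "neutral", "N2", 0)]))
        with pytest.raises(ValueError, match="at least 5"):
            reject_epochs(ep)


class TestHjorth:
    def test_sinusoid_closed_form(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        act, mob, comp = hjorth_params(x, fs)
        assert mob == pytest.approx(2 * np.pi * 10.0, rel=0.01)
        assert comp == pytest.approx(1.0, rel=0.01)
        assert act == pytest.approx(0.5, rel=0.01)

    def _hyp_rec(self, rng, n_epochs=20, n_ch=6):
        labels = ["F3", "F4", "C3", "C4", "Cz", "Pz"][:n_ch]
        fs = 250.0
        data = rng.standard_normal((n_ch, int(n_epochs * 30 * fs)))
        return (Recording(data, fs, labels),
                Hypnogram(["N2"] * n_epochs))

    def test_homogeneous_noise_untouched(self, rng):
        rec, hyp = self._hyp_rec(rng)
        out, clean, rep = hjorth_artifact_pass(rec, hyp)
        assert clean.all()
        assert rep.interpolated_channels == []
        np.testing.assert_array_equal(out.data, rec.data)

    def test_bad_channel_interpolated_globally(self, rng):
        rec, hyp = self._hyp_rec(rng)
        fs = 250.0
        for e in range(0, 20, 3):  # 7 of 20 epochs -> 35% bad
            sl = slice(int(e * 30 * fs), int((e + 1) * 30 * fs))
            rec.data[2, sl] *= 20
        pos = montage_positions(rec.channel_labels)
        out, clean, rep = hjorth_artifact_pass(rec, hyp, positions=pos)
        assert "C3" in rep.interpolated_channels

    def test_all_removed_errors(self, rng):
        rec, hyp = self._hyp_rec(rng, n_epochs=3)
        rec.data[:, :] = 0.0
        rec.data[:, ::100] = 1e6  # same spikes everywhere: zero-SD guard path
        with pytest.raises(ValueError, match="no data|no clean"):
            hjorth_artifact_pass(rec, Hypnogram(["REM"] * 3))


class TestSplineInterpolation:
    LABELS = ["Fz", "Cz", "Pz", "C3", "C4", "F3", "F4", "Oz"]

    def test_constant_field_reconstructed(self):
        pos = montage_positions(self.LABELS)
        data = np.ones((8, 100)) * 3.7
        rec = Recording(data, 250.0, self.LABELS)
        out = interpolate_channel(rec, ["Cz"], pos)
        np.testing.assert_allclose(out.data[1], 3.7, rtol=1e-6)

    def test_smooth_field_reconstruction(self, rng):
        """A smooth dipolar potential sampled on the montage should be
        recovered at a removed central channel (r > 0.95 with truth)."""
        pos = montage_positions(self.LABELS)
        P = np.array([pos[l] for l in self.LABELS])
        P = P / np.linalg.norm(P, axis=1, keepdims=True)
        dipole = np.array([0.2, 0.3, 0.9])
        dipole /= np.linalg.norm(dipole)
        gains = P @ dipole  # smooth angular field
        src = rng.standard_normal(200)
        data = gains[:, None] * src[None, :]
        rec = Recording(data, 250.0, self.LABELS)
        out = interpolate_channel(rec, ["Cz"], pos)
        r = np.corrcoef(out.data[1], data[1])[0, 1]
        assert r > 0.95

    def test_missing_position_errors(self, rng):
        pos = montage_positions(self.LABELS[:-1])
        rec = Recording(rng.standard_normal((8, 50)), 250.0, self.LABELS)
        with pytest.raises(ValueError, match="position"):
            interpolate_channel(rec, ["Oz"], pos)
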