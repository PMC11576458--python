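import numpy as np
import pytest

from conftest import make_epochs
from eegagree.interpolate import interpolation_matrix
from eegagree.layouts import get_layout
from eegagree.preprocess import (
    EogICA, bandpass, derive_bipolar_eog, detect_and_mark_bad_channels,
    epoch, ica_reject_eog, interpolate_bads, reject_trials_ptp, resample,
    rereference_average_mastoids,
)
from eegagree.sequence import generate_sequence
from eegagree.synth import GroundTruth, Recording, synthesize_task_recording

FS = 1024.0


def _rec(data, labels, eog=()):
    return Recording(data=np.asarray(data, float), fs=FS,
                     channel_labels=list(labels), system="wet",
                     eog_channels=list(eog))


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self, rng):
        data = rng.normal(size=(4, 100))
        data[2:] = 0.0
        rec = _rec(data, ["a", "b", "M1", "M2"])
        out = rereference_average_mastoids(rec)
        assert np.allclose(out.data, rec.data)

    def test_scalp_equal_to_mastoids_becomes_zero(self, rng):
        common = rng.normal(size=100)
        data = np.tile(common, (4, 1))
        rec = _rec(data, ["a", "b", "M1", "M2"])
        out = rereference_average_mastoids(rec)
        assert np.allclose(out.data[:2], 0.0)

    def test_matches_arithmetic_oracle(self, rng):
        data = rng.normal(size=(4, 50))
        rec = _rec(data, ["a", "b", "M1", "M2"])
        out = rereference_average_mastoids(rec)
        ref = (data[2] + data[3]) / 2
        assert np.allclose(out.data[0], data[0] - ref)
        assert np.allclose(out.data[1], data[1] - ref)
        # mastoids stay in the recording, themselves re-referenced
        assert np.allclose(out.data[2], data[2] - ref)
        assert out.channel_labels == ["a", "b", "M1", "M2"]

    def test_idempotent(self, rng):
        data = rng.normal(size=(4, 50))
        rec = _rec(data, ["a", "b", "M1", "M2"])
        once = rereference_average_mastoids(rec)
        twice = rereference_average_mastoids(once)
        assert np.allclose(once.data, twice.data)

    def test_missing_mastoids(self, rng):
        rec = _rec(rng.normal(size=(2, 50)), ["a", "b"])
        with pytest.raises(ValueError):
            rereference_average_mastoids(rec)
        out = rereference_average_mastoids(rec, on_missing="skip")
        assert np.allclose(out.data, rec.data)


class TestBandpass:
    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t)
        rec = _rec(x[None, :], ["a"])
        out = bandpass(rec, 0.1, 25.0)
        mid = slice(int(5 * FS), int(25 * FS))
        assert np.sqrt((out.data[0, mid] ** 2).mean()) < 0.1 * np.sqrt((x[mid] ** 2).mean())

    def test_passband_sinusoid_preserved(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        rec = _rec(x[None, :], ["a"])
        out = bandpass(rec, 0.1, 25.0)
        mid = slice(int(5 * FS), int(25 * FS))
        ratio = np.sqrt((out.data[0, mid] ** 2).mean()) / np.sqrt((x[mid] ** 2).mean())
        assert abs(ratio - 1) < 0.05

    def test_dc_removed(self):
        rec = _rec(np.full((1, int(40 * FS)), 7.0), ["a"])
        out = bandpass(rec, 0.1, 25.0)
        mid = slice(int(10 * FS), int(30 * FS))
        assert abs(out.data[0, mid].mean()) < 0.05

    def test_invalid_edges(self, rng):
        rec = _rec(rng.normal(size=(1, 2048)), ["a"])
        with pytest.raises(ValueError):
            bandpass(rec, 25.0, 0.1)
        with pytest.raises(ValueError):
            bandpass(rec, 0.1, 600.0)


class TestEogDerivation:
    def _wet_rec(self, rng):
        lay = get_layout("wet61")
        data = rng.normal(size=(len(lay.all_labels), 256))
        rec = Recording(data=data, fs=FS, channel_labels=lay.all_labels,
                        system="wet", eog_channels=list(lay.eog),
                        layout_name="wet61")
        return rec, lay

    def test_equal_periocular_electrodes_give_zero_veog(self, rng):
        rec, lay = self._wet_rec(rng)
        rec.data[rec.idx("EOGa")] = rec.data[rec.idx("EOGb")]
        out = derive_bipolar_eog(rec)
        assert np.allclose(out.data[out.idx("vEOG")], 0.0)

    def test_heog_is_lateral_minus_f7(self, rng):
        rec, lay = self._wet_rec(rng)
        expected = rec.data[rec.idx("EOGl")] - rec.data[rec.idx("F7")]
        out = derive_bipolar_eog(rec)
        assert np.array_equal(out.data[out.idx("hEOG")], expected)
        assert "EOGl" not in out.channel_labels
        assert out.eog_channels == ["vEOG", "hEOG"]

    def test_missing_reference_channel_raises(self, rng):
        lay = get_layout("dry62")
        labels = [l for l in lay.all_labels if l != "1LD"]
        data = rng.normal(size=(len(labels), 64))
        rec = Recording(data=data, fs=FS, channel_labels=labels, system="dry",
                        eog_channels=list(lay.eog), layout_name="dry62")
        with pytest.raises(ValueError):
            derive_bipolar_eog(rec)


class TestBadChannels:
    def _layout_rec(self, rng, scale=1e-6):
        lay = get_layout("wet61")
        data = rng.normal(scale=scale, size=(len(lay.all_labels), 4096))
        return Recording(data=data, fs=FS, channel_labels=lay.all_labels,
                         system="wet", eog_channels=list(lay.eog),
                         layout_name="wet61")

    def test_flat_channel_flagged(self, rng):
        rec = self._layout_rec(rng)
        rec.data[rec.idx("Cz")] = 0.0
        assert "Cz" in detect_and_mark_bad_channels(rec)

    def test_high_amplitude_channel_flagged(self, rng):
        rec = self._layout_rec(rng)
        rec.data[rec.idx("P3")] += 10 * 1e-6 * np.sign(
            np.sin(np.arange(4096) / 300))
        assert "P3" in detect_and_mark_bad_channels(rec)

    def test_clean_recordings_rarely_flag(self):
        seq = generate_sequence(12, 2, seed=0)
        flagged = 0
        for s in range(5):
            truth = GroundTruth(seed=s, jump_rate=0.0)
            rec = synthesize_task_recording(seq, truth, system="wet", seed=s)
            flagged += len(detect_and_mark_bad_channels(rec))
        assert flagged <= 2


class TestInterpolation:
    def test_constant_field_reproduced(self, rng):
        lay = get_layout("wet61")
        pos = lay.position_array(lay.scalp)
        W = interpolation_matrix(pos[1:], pos[:1])
        v = np.full(len(lay.scalp) - 1, 3.7)
        assert W @ v == pytest.approx(3.7, rel=1e-3)

    def test_empty_bads_is_identity(self, rng):
        lay = get_layout("wet61")
        eps = make_epochs(rng.normal(size=(2, len(lay.scalp), 32)),
                          labels=lay.scalp, layout_name="wet61")
        out = interpolate_bads(eps, [])
        assert np.array_equal(out.data, eps.data)

    def test_leave_one_out_on_dipolar_field(self):
        """A smooth dipolar potential is recovered to within 15 %."""
        lay = get_layout("dry62")
        pos = lay.position_array(lay.scalp)
        dipole = np.array([0.3, 0.4, 0.86])
        dipole /= np.linalg.norm(dipole)
        field = pos @ dipole  # smooth l=1 spherical harmonic
        errs = []
        for i in range(0, len(lay.scalp), 7):
            good = np.delete(np.arange(len(lay.scalp)), i)
            W = interpolation_matrix(pos[good], pos[i:i + 1])
            est = (W @ field[good]).item()
            errs.append(abs(est - field[i]) / np.abs(field).max())
        assert np.mean(errs) < 0.15

    def test_too_few_good_channels(self, rng):
        with pytest.raises(ValueError):
            interpolation_matrix(rng.normal(size=(3, 3)), rng.normal(size=(1, 3)))


class TestEpoching:
    def test_rest_epoch_count_and_length(self, rng):
        rec = _rec(rng.normal(size=(1, int(300 * 512))), ["a"])
        rec.fs = 512.0
        eps = epoch(rec, None, rest_len=8.0)
        assert eps.n_trials == 37
        assert eps.data.shape[2] == 4096

    def test_task_epoch_sample_convention(self, rng):
        seq = generate_sequence(12, 2, seed=1)
        n = int(seq.events[-1].onset_time * FS + 2 * FS)
        rec = _rec(rng.normal(size=(1, n)), ["a"])
        rec.events = seq
        eps = epoch(rec, seq, -0.1, 0.5)
        assert eps.data.shape[2] == 614  # half-open [tmin, tmax) at 1024 Hz
        assert eps.n_trials == len(seq.events)

    def test_event_beyond_end_dropped_with_warning(self, rng):
        seq = generate_sequence(12, 2, seed=1)
        n = int(seq.events[-2].onset_time * FS)  # truncate before last events
        rec = _rec(rng.normal(size=(1, n)), ["a"])
        with pytest.warns(UserWarning):
            eps = epoch(rec, seq, -0.1, 0.5)
        assert eps.n_trials < len(seq.events)


class TestResample:
    def test_halves_sample_count(self, rng):
        eps = make_epochs(rng.normal(size=(3, 2, 614)), fs=1024.0)
        out = resample(eps, 512.0)
        assert out.data.shape == (3, 2, 307)
        assert out.fs == 512.0

    def test_preserves_sinusoid_rms(self):
        t = np.arange(2048) / 1024.0
        x = np.sin(2 * np.pi * 10 * t)
        eps = make_epochs(x[None, None, :], fs=1024.0)
        out = resample(eps, 512.0)
        ratio = np.sqrt((out.data**2).mean()) / np.sqrt((x**2).mean())
        assert abs(ratio - 1) < 0.02

    def test_identity_and_upsampling(self, rng):
        eps = make_epochs(rng.normal(size=(1, 1, 64)), fs=512.0)
        assert np.array_equal(resample(eps, 512.0).data, eps.data)
        with pytest.raises(ValueError):
            resample(eps, 1024.0)


def _blinky_epochs(seed=0, blinks=True):
    seq = generate_sequence(48, 8, seed=seed)
    truth = GroundTruth(seed=seed, jump_rate=0.0,
                        blink_rate=0.2 if blinks else 0.0)
    rec = synthesize_task_recording(seq, truth, system="wet", seed=seed,
                                    blinks=True)
    rec = rereference_average_mastoids(rec)
    eps = derive_bipolar_eog(resample(epoch(rec, rec.events), 512.0))
    return eps


class TestICA:
    def test_threshold_one_is_identity(self):
        eps = _blinky_epochs(1)
        out, rep, model = ica_reject_eog(eps, corr_threshold=1.0, seed=0)
        assert model.rejected_ == []
        assert np.allclose(out.data, eps.data)

    def test_blinks_detected_and_removed(self):
        eps = _blinky_epochs(2)
        fcz = eps.idx("Fp1")
        veog = eps.idx("vEOG")
        before = np.corrcoef(eps.data[:, fcz, :].ravel(),
                             eps.data[:, veog, :].ravel())[0, 1]
        out, rep, model = ica_reject_eog(eps, seed=0)
        after = np.corrcoef(out.data[:, fcz, :].ravel(),
                            out.data[:, veog, :].ravel())[0, 1]
        assert rep.n_components_rejected >= 1
        assert abs(before) > 0.2
        assert abs(after) < 0.2

    def test_cleaning_spares_posterior_channels(self):
        eps = _blinky_epochs(3)
        out, rep, model = ica_reject_eog(eps, seed=0)
        for ch in ("Oz", "Pz", "POz"):
            i = eps.idx(ch)
            rms_before = np.sqrt((eps.data[:, i, :] ** 2).mean())
            rms_after = np.sqrt((out.data[:, i, :] ** 2).mean())
            assert rms_after < 1.05 * rms_before


class TestTrialRejection:
    def test_all_zero_epochs_keep_everything(self):
        eps = make_epochs(np.zeros((5, 3, 32)))
        out, rep = reject_trials_ptp(eps, 150e-3)
        assert out.kept_mask.all()
        assert rep.n_trials_rejected == 0

    def test_constructed_step_trial_rejected(self, rng):
        data = rng.normal(scale=1e-5, size=(6, 3, 64))
        data[4, 1, 32:] += 0.2  # 200 mV step
        eps = make_epochs(data)
        out, rep = reject_trials_ptp(eps, 150e-3)
        assert not out.kept_mask[4]
        assert out.kept_mask.sum() == 5

    def test_zero_threshold_rejects_all(self, rng):
        eps = make_epochs(rng.normal(size=(4, 2, 16)))
        out, _ = reject_trials_ptp(eps, 0.0)
        assert not out.kept_mask.any()

    def test_rejection_is_monotone(self, rng):
        eps = make_epochs(rng.normal(scale=1e-5, size=(4, 2, 16)))
        eps.kept_mask[0] = False
        out, _ = reject_trials_ptp(eps, 150e-3)
        assert not out.kept_mask[0]
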