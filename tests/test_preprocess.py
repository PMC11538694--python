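"""Preprocessing: filter response, detrending, artifact detection rules,
wavelet features, excision bookkeeping."""

import numpy as np
import pytest

from dyadscan.montage import Montage
from dyadscan.preprocess import (
    detect_amplitude_artifacts,
    detrend,
    excise_and_join,
    lowpass_filter,
    preprocess_dyad,
    train_artifact_ann,
    wavelet_features,
)
from dyadscan.recording import Recording

_M1 = Montage(("F1",), {"F1": "frontal"})


def _rec(x, fs=500.0):
    return Recording(samples=np.atleast_2d(np.asarray(x, dtype=float)), fs=fs, montage=_M1)


class TestLowpass:
    def test_dc_unchanged(self):
        rec = _rec(np.full(5000, 7.0))
        out = lowpass_filter(rec, cutoff=200.0)
        np.testing.assert_allclose(out.samples, 7.0, rtol=1e-6)

    def test_passband_sine_attenuation_below_one_percent(self):
        # analytic 10th-order Butterworth magnitude at 10/245 Hz: ~1 - 5e-15;
        # zero-phase application squares the magnitude, still << 1% loss
        t = np.arange(10_000) / 500.0
        rec = _rec(np.sin(2 * np.pi * 10.0 * t))
        out = lowpass_filter(rec, cutoff=245.0)
        core = slice(1000, -1000)  # ignore filter edge transients
        ratio = np.abs(out.samples[0, core]).max() / np.abs(rec.samples[0, core]).max()
        assert abs(1.0 - ratio) < 0.01

    def test_cutoff_at_nyquist_warns_above_errors(self, caplog):
        rec = _rec(np.random.default_rng(0).standard_normal(2000))
        with caplog.at_level("WARNING"):
            out = lowpass_filter(rec, cutoff=250.0)
        assert "Nyquist" in caplog.text
        assert np.isfinite(out.samples).all()
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(rec, cutoff=300.0)


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(1000) / 500.0
        out = detrend(_rec(3.0 + 2.0 * t))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-9)

    def test_sine_recovered_from_sine_plus_line(self):
        t = np.arange(5000) / 500.0
        sine = np.sin(2 * np.pi * 5.0 * t)
        out = detrend(_rec(sine + 1.5 - 0.3 * t))
        # the fitted line also absorbs the sine's tiny net trend; compare
        # against the detrended sine itself
        from scipy.signal import detrend as sp_detrend

        np.testing.assert_allclose(out.samples[0], sp_detrend(sine), atol=1e-9)

    def test_zero_mean_zero_slope_after(self, rng):
        out = detrend(_rec(rng.standard_normal(4000)))
        x = out.samples[0]
        t = np.arange(x.size)
        assert abs(x.mean()) < 1e-12
        assert abs(np.polyfit(t, x, 1)[0]) < 1e-12


class TestAmplitudeRule:
    def test_quiet_signal_unflagged(self):
        rec = _rec(np.full(5000, 100.0))
        assert not detect_amplitude_artifacts(rec).any()

    def test_single_spike_flags_its_window(self):
        x = np.zeros(5000)
        x[1250] = 400.0  # t = 2.5 s
        flags = detect_amplitude_artifacts(_rec(x))
        assert flags.tolist() == [False, False, True, False, False, False, False, False, False, False]

    def test_threshold_is_strict(self):
        x = np.zeros(2500)
        x[100] = 300.0
        assert not detect_amplitude_artifacts(_rec(x)).any()
        x[100] = 300.0001
        assert detect_amplitude_artifacts(_rec(x)).any()


class TestWaveletFeatures:
    def test_zero_segment_fallback(self):
        f = wavelet_features(np.zeros(500), fs=500.0)
        assert np.all(f[:6] == 0.0)
        assert f[-1] == 1.0  # degenerate flag

    def test_line_power_share_near_one_for_pure_50hz(self):
        t = np.arange(500) / 500.0
        f = wavelet_features(np.sin(2 * np.pi * 50.0 * t), fs=500.0)
        assert f[-2] > 0.95  # line-share feature

    def test_relative_energies_sum_to_one(self, rng):
        f = wavelet_features(rng.standard_normal(500), fs=500.0)
        assert np.isclose(f[:6].sum(), 1.0)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            wavelet_features(np.ones(16), fs=500.0)


class TestArtifactANN:
    def test_single_class_training_rejected(self):
        segs = [np.random.default_rng(i).standard_normal((1, 500)) for i in range(4)]
        with pytest.raises(ValueError, match="2 classes"):
            train_artifact_ann(segs, ["clean"] * 4, fs=500.0)

    def test_separates_clean_sine_from_emg_burst(self, rng):
        t = np.arange(500) / 500.0
        clean = [
            (10.0 * np.sin(2 * np.pi * 8 * t + rng.uniform(0, 6)) + rng.standard_normal(500))[None]
            for _ in range(40)
        ]
        emg = [c + 20.0 * _hp_noise(rng) for c in clean[:40]]
        clf = train_artifact_ann(clean + emg, ["clean"] * 40 + ["emg"] * 40, fs=500.0, seed=0)
        assert clf.predict([clean[0]])[0] == "clean"
        assert clf.predict([emg[0]])[0] == "emg"


def _hp_noise(rng):
    from scipy.signal import butter, sosfilt

    sos = butter(4, 35, "highpass", fs=500.0, output="sos")
    return sosfilt(sos, rng.standard_normal(500))[None]


class TestExciseAndJoin:
    def test_no_flags_identity(self, rng):
        rec = _rec(rng.standard_normal(5000))
        out, report = excise_and_join(rec, np.zeros(10, dtype=bool))
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert report.fraction_removed == 0.0

    def test_gap_joined_sample_shift(self, rng):
        x = rng.standard_normal(5000)
        flags = np.zeros(10, dtype=bool)
        flags[2] = True  # excise [2, 3) s
        out, report = excise_and_join(_rec(x), flags)
        assert out.n_times == 4500
        # the sample formerly at t=3.0 s is now at t=2.0 s
        assert out.samples[0, 1000] == x[1500]
        assert np.isclose(report.fraction_removed, 0.1)

    def test_idempotent_under_no_further_flags(self, rng):
        rec = _rec(rng.standard_normal(5000))
        flags = np.zeros(10, dtype=bool)
        flags[[1, 7]] = True
        once, _ = excise_and_join(rec, flags)
        twice, rep = excise_and_join(once, np.zeros(8, dtype=bool))
        np.testing.assert_array_equal(once.samples, twice.samples)
        assert rep.fraction_removed == 0.0

    def test_mask_bookkeeping(self, rng):
        rec = _rec(rng.standard_normal(5000))
        flags = np.zeros(10, dtype=bool)
        flags[[0, 3, 4]] = True
        out, _ = excise_and_join(rec, flags)
        assert out.n_times + int(flags.sum()) * 500 == rec.n_times

    def test_all_flagged_is_error(self, rng):
        rec = _rec(rng.standard_normal(5000))
        with pytest.raises(ValueError, match="no usable data"):
            excise_and_join(rec, np.ones(10, dtype=bool))


class TestJointExcision:
    def test_dyad_loses_same_windows(self, uncoupled_session):
        from dyadscan.synthetic import ArtifactEvent, inject_artifacts

        session, _ = uncoupled_session
        dirty, _ = inject_artifacts(
            session.human, [ArtifactEvent("ocular", onset=10.0, duration=1.0, amplitude=450.0)], seed=0
        )
        session = type(session)(human=dirty, dog=session.dog, meta=session.meta)
        clean, reports = preprocess_dyad(session)
        assert clean.human.n_times == clean.dog.n_times
        assert reports["human"].fraction_removed == reports["dog"].fraction_removed > 0
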