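"""Spectral layer: multitaper PSD levels, peak normalization, region
averaging, band powers and TBR."""

import numpy as np
import pytest

from dyadscan.montage import Montage
from dyadscan.recording import Recording
from dyadscan.spectral import (
    Spectrogram,
    multitaper_spectrogram,
    peak_normalize,
    region_power_series,
    tbr,
)

_M1 = Montage(("F1",), {"F1": "frontal"})
_M2 = Montage(("F1", "F2"), {"F1": "frontal", "F2": "frontal"})


def _rec(x, fs=500.0, montage=_M1):
    return Recording(samples=np.atleast_2d(np.asarray(x, dtype=float)), fs=fs, montage=montage)


class TestMultitaperSpectrogram:
    def test_zero_signal_zero_power(self):
        spec = multitaper_spectrogram(_rec(np.zeros(5000)))
        assert spec.power.shape == (1, 10, 27)
        np.testing.assert_array_equal(spec.power, 0.0)
        np.testing.assert_array_equal(spec.freqs, np.arange(4, 31))

    def test_sine_peaks_at_its_bin(self):
        t = np.arange(5000) / 500.0
        rec = _rec(np.sin(2 * np.pi * 10.0 * t))
        # NW=2: +/-2 Hz concentration, the 10 Hz bin is the strict maximum
        spec2 = multitaper_spectrogram(rec, nw=2.0)
        assert np.all(spec2.freqs[np.argmax(spec2.power[0], axis=1)] == 10)
        # NW=4: the spectral window has a +/-4 Hz flat top, so the 10 Hz bin
        # equals the per-window maximum only up to taper ripple
        spec4 = multitaper_spectrogram(rec, nw=4.0)
        at_10 = spec4.power[0][:, spec4.freqs == 10].ravel()
        assert np.all(at_10 >= 0.99 * spec4.power[0].max(axis=1))

    def test_white_noise_level_matches_periodogram_oracle(self, rng):
        x = rng.standard_normal(300 * 500) * 3.0
        rec = _rec(x)
        spec = multitaper_spectrogram(rec)
        mt_level = spec.power[0].mean()
        # oracle: averaged raw periodogram of the same data over 4-30 Hz
        from scipy.signal import periodogram

        f, pxx = periodogram(x.reshape(300, 500), fs=500.0, axis=1)
        oracle = pxx[:, (f >= 4) & (f <= 30)].mean()
        assert abs(mt_level - oracle) / oracle < 0.10

    def test_parseval_sanity_for_bandlimited_signal(self, rng):
        # total 4-30 Hz multitaper power within 15% of the Welch estimate
        from scipy.signal import butter, sosfiltfilt, welch

        sos = butter(4, [5, 25], "bandpass", fs=500.0, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(60 * 500))
        spec = multitaper_spectrogram(_rec(x))
        total_mt = spec.power[0].mean(axis=0).sum()
        f, pxx = welch(x, fs=500.0, nperseg=500)
        total_welch = pxx[(f >= 4) & (f <= 30)].sum()
        assert abs(total_mt - total_welch) / total_welch < 0.15

    def test_window_accounting_and_short_input(self):
        spec = multitaper_spectrogram(_rec(np.zeros(1250)))
        assert spec.n_windows == 2  # trailing half window dropped
        with pytest.raises(ValueError, match="shorter than one"):
            multitaper_spectrogram(_rec(np.zeros(400)))


class TestPeakNormalize:
    def _spec(self, power):
        power = np.asarray(power, dtype=float)
        return Spectrogram(
            power=power,
            freqs=np.arange(4, 4 + power.shape[2]),
            window_times=np.arange(power.shape[1], dtype=float),
            channel_names=("F1",),
        )

    def test_column_division(self):
        spec = self._spec([[[2.0], [4.0], [8.0]]])
        out = peak_normalize(spec)
        np.testing.assert_allclose(out.power[0, :, 0], [0.25, 0.5, 1.0])

    def test_idempotent_and_scale_invariant(self, rng):
        power = rng.uniform(0.1, 5.0, size=(2, 30, 27))
        spec = self._spec(power)
        once = peak_normalize(spec)
        twice = peak_normalize(once)
        np.testing.assert_allclose(once.power, twice.power)
        scaled = peak_normalize(self._spec(power * 37.5))
        np.testing.assert_allclose(once.power, scaled.power)
        assert np.allclose(once.power.max(axis=1), 1.0)

    def test_zero_column_guarded(self):
        spec = self._spec(np.zeros((1, 4, 2)))
        out = peak_normalize(spec)
        np.testing.assert_array_equal(out.power, 0.0)


class TestRegionSeries:
    def test_single_channel_identity(self, rng):
        power = rng.uniform(0, 1, size=(1, 20, 27))
        spec = Spectrogram(power, np.arange(4, 31), np.arange(20.0), ("F1",))
        series = region_power_series(spec, _M1, "frontal")
        np.testing.assert_allclose(series, power[0].mean(axis=1))

    def test_two_channel_mean(self, rng):
        s = rng.uniform(0.1, 1.0, size=20)
        power = np.stack([np.tile(s[:, None], 27), np.tile(3 * s[:, None], 27)])
        spec = Spectrogram(power, np.arange(4, 31), np.arange(20.0), ("F1", "F2"))
        series = region_power_series(spec, _M2, "frontal")
        np.testing.assert_allclose(series, 2 * s)

    def test_region_without_usable_channels_errors(self, rng):
        spec = Spectrogram(rng.uniform(0, 1, (1, 5, 27)), np.arange(4, 31), np.arange(5.0), ("F1",))
        with pytest.raises(ValueError, match="no usable channels"):
            region_power_series(spec, _M1, "occipital")

    def test_coupled_dyad_frontal_series_correlate(self, coupled_session):
        from dyadscan.coupling import pearson
        from dyadscan.spectral import session_region_series

        session, _ = coupled_session
        ser = session_region_series(session)
        assert "temporal" not in ser["dog"]  # excluded region skipped
        assert pearson(ser["human"]["frontal"], ser["dog"]["frontal"]) > 0


class TestTBR:
    def test_equal_band_powers_give_unity(self):
        power = np.zeros((1, 10, 27))
        power[:, :, 2] = 4.0  # 6 Hz (theta)
        power[:, :, 16] = 4.0  # 20 Hz (beta)
        spec = Spectrogram(power, np.arange(4, 31), np.arange(10.0), ("F1",))
        series = tbr(spec)
        np.testing.assert_allclose(series.tbr, 1.0)

    def test_two_tone_worked_example(self):
        """6 Hz at amplitude 2 vs 20 Hz at amplitude 1: sinusoid band powers
        A^2/2 = 2.0 and 0.5, so TBR = 4."""
        t = np.arange(30 * 500) / 500.0
        x = 2.0 * np.sin(2 * np.pi * 6 * t) + 1.0 * np.sin(2 * np.pi * 20 * t)
        spec = multitaper_spectrogram(_rec(x), nw=2.0)
        assert abs(tbr(spec).mean() - 4.0) / 4.0 < 0.10

    def test_self_normalization_mean_one(self, rng):
        power = rng.uniform(0.5, 2.0, size=(1, 50, 27))
        spec = Spectrogram(power, np.arange(4, 31), np.arange(50.0), ("F1",))
        base = tbr(spec)
        series = tbr(spec, baseline_mean=base.mean())
        assert np.isclose(np.nanmean(series.normalized_tbr), 1.0)

    def test_zero_beta_windows_marked_invalid(self):
        power = np.zeros((1, 10, 27))
        power[:, :, 2] = 1.0
        power[:, :9, 16] = 2.0  # last window has zero beta
        spec = Spectrogram(power, np.arange(4, 31), np.arange(10.0), ("F1",))
        series = tbr(spec)
        assert not series.valid[9]
        assert np.isnan(series.tbr[9])

    def test_normalized_spectrogram_rejected(self, rng):
        power = rng.uniform(0.5, 2.0, size=(1, 10, 27))
        spec = Spectrogram(power, np.arange(4, 31), np.arange(10.0), ("F1",))
        with pytest.raises(ValueError, match="unnormalized"):
            tbr(peak_normalize(spec))
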