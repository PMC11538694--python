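"""Multitaper spectrograms, peak normalization, region power envelopes and
theta/beta ratios.

Power spectra are computed in non-overlapping 1-s windows with the
multitaper method (DPSS tapers, time half-bandwidth product NW; 2*NW-1
tapers) at integer frequencies from 4 to 30 Hz.  Each frequency is then
peak-normalized -- divided by its maximum over windows -- so frequencies
contribute on an equal footing, and normalized power is averaged over a
region's usable channels and the 4-30 Hz bins to give one power-envelope
series per region at 1 sample/s.  That series is what the coupling and
directionality layers consume.

Band powers sum the PSD over a band's integer bins.  Because the default
NW=4 spectral window is 8 Hz wide -- wider than the 4-Hz theta band -- the
theta/beta ratio (TBR) is estimated from a dedicated NW=2 spectrogram whose
concentration half-width (2 Hz) fits inside the narrowest band; see
docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal.windows import dpss

from dyadscan.montage import Montage
from dyadscan.recording import DyadSession, Recording

logger = logging.getLogger(__name__)

THETA_BAND = (4, 8)
ALPHA_BAND = (8, 13)
BETA_BAND = (13, 30)
ANALYSIS_BAND = (4, 30)


@dataclass
class Spectrogram:
    """Windowed power spectra: (n_channels, n_windows, n_freqs)."""

    power: np.ndarray
    freqs: np.ndarray  # Hz, integer bins
    window_times: np.ndarray  # window start times, s
    channel_names: tuple[str, ...]
    normalized: bool = False

    @property
    def n_windows(self) -> int:
        return self.power.shape[1]

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))


def multitaper_spectrogram(
    rec: Recording,
    window: float = 1.0,
    nw: float = 4.0,
    fmin: float = 4.0,
    fmax: float = 30.0,
) -> Spectrogram:
    """One-sided multitaper PSD (uV^2/Hz) per non-overlapping window.

    2*NW-1 DPSS tapers are averaged; windows truncated at the end of the
    trace are dropped.
    """
    n = int(round(window * rec.fs))
    if rec.n_times < n:
        raise ValueError(
            f"recording ({rec.n_times} samples) shorter than one {window}-s window ({n} samples)"
        )
    n_win = rec.n_times // n
    k = int(2 * nw - 1)
    tapers = dpss(n, nw, Kmax=k)  # (k, n), unit-energy tapers
    df = rec.fs / n
    freqs_all = np.arange(n // 2 + 1) * df
    sel = np.flatnonzero(
        (freqs_all >= fmin - 1e-9) & (freqs_all <= fmax + 1e-9) & (np.abs(freqs_all % 1) < 1e-9)
    )
    x = rec.samples[:, : n_win * n].reshape(rec.n_channels, n_win, n)
    # taper, FFT, average periodograms over tapers
    tapered = x[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=2) / rec.fs
    psd[..., 1:-1] *= 2.0  # one-sided
    power = psd[..., sel]
    return Spectrogram(
        power=power,
        freqs=freqs_all[sel],
        window_times=np.arange(n_win) * window,
        channel_names=tuple(rec.montage.channel_names),
    )


def peak_normalize(spec: Spectrogram) -> Spectrogram:
    """Divide each frequency's power trace by its maximum over windows.

    All-zero columns are left at zero (guarding 0/0) and logged.  The
    operation is idempotent and scale-invariant.
    """
    if spec.n_windows < 1:
        raise ValueError("need at least one window")
    peaks = spec.power.max(axis=1, keepdims=True)  # (n_ch, 1, n_freq)
    zero = peaks <= 0
    if zero.any():
        logger.info("peak_normalize: %d all-zero frequency columns left at 0", int(zero.sum()))
    safe = np.where(zero, 1.0, peaks)
    return replace(spec, power=spec.power / safe, normalized=True)


def region_power_series(
    spec: Spectrogram,
    montage: Montage,
    region: str,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> np.ndarray:
    """Mean normalized power per window, averaged over the region's usable
    channels and the band's frequency bins: the region's power envelope at
    1 sample per window."""
    idx = montage.indices_in(region, usable_only=True)
    if not idx:
        raise ValueError(f"region {region!r} has no usable channels in this montage")
    bins = spec.band_indices(band)
    return spec.power[idx][:, :, bins].mean(axis=(0, 2))


def session_region_series(
    session: DyadSession,
    regions: tuple[str, ...] = ("frontal", "parietal", "temporal", "occipital"),
    window: float = 1.0,
    nw: float = 4.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-subject, per-region normalized power envelopes for one session.

    Regions without usable channels (e.g. dog temporal) are skipped and
    recorded as absent in the output.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, rec in session.subjects().items():
        spec = peak_normalize(multitaper_spectrogram(rec, window=window, nw=nw))
        series: dict[str, np.ndarray] = {}
        for region in regions:
            try:
                series[region] = region_power_series(spec, rec.montage, region)
            except ValueError:
                logger.info("session %s: %s %s skipped (no usable channels)", session.meta, name, region)
        out[name] = series
    return out


# --------------------------------------------------------------------- #
# band power and the theta/beta attention metric
# --------------------------------------------------------------------- #


def band_power(spec: Spectrogram, band: tuple[float, float]) -> np.ndarray:
    """Total power (uV^2) in a band per channel and window: PSD summed over
    the band's integer 1-Hz bins."""
    bins = spec.band_indices(band)
    return spec.power[:, :, bins].sum(axis=2)


@dataclass
class TBRSeries:
    """Per-window theta/beta ratio and its baseline-normalized form."""

    tbr: np.ndarray  # (n_windows,), NaN where invalid
    valid: np.ndarray  # (n_windows,) bool
    normalized_tbr: np.ndarray | None = None
    baseline_mean: float | None = None

    def median(self) -> float:
        return float(np.nanmedian(self.tbr[self.valid]))

    def mean(self) -> float:
        return float(np.nanmean(self.tbr[self.valid]))


def tbr(
    spec: Spectrogram,
    montage: Montage | None = None,
    region: str | None = None,
    baseline_mean: float | None = None,
    min_valid_fraction: float = 0.9,
) -> TBRSeries:
    """Theta/beta ratio per window from an (unnormalized) spectrogram.

    theta = total 4-8 Hz power, beta = total 13-30 Hz power, averaged over
    the region's usable channels (all channels when no region is given).
    Windows with zero beta power are marked invalid and excluded; more than
    ``1 - min_valid_fraction`` invalid windows is an error.  When
    ``baseline_mean`` is given (the subject's no-interaction baseline mean
    TBR) a normalized series is attached.
    """
    if spec.normalized:
        raise ValueError("tbr expects an unnormalized (uV^2/Hz) spectrogram")
    th = band_power(spec, THETA_BAND)
    be = band_power(spec, BETA_BAND)
    if montage is not None and region is not None:
        idx = montage.indices_in(region, usable_only=True)
        if not idx:
            raise ValueError(f"region {region!r} has no usable channels")
        th, be = th[idx].mean(axis=0), be[idx].mean(axis=0)
    else:
        th, be = th.mean(axis=0), be.mean(axis=0)
    valid = be > 0
    if valid.mean() < min_valid_fraction:
        raise ValueError(
            f"beta power is zero in {100 * (1 - valid.mean()):.0f}% of windows; "
            "TBR undefined"
        )
    ratio = np.full(th.shape, np.nan)
    ratio[valid] = th[valid] / be[valid]
    series = TBRSeries(tbr=ratio, valid=valid)
    if baseline_mean is not None:
        if baseline_mean <= 0:
            raise ValueError("baseline mean TBR must be > 0")
        series.normalized_tbr = ratio / baseline_mean
        series.baseline_mean = baseline_mean
    return series


def session_tbr(
    session: DyadSession,
    baseline: dict[str, dict[str, float]] | None = None,
    regions: tuple[str, ...] = ("frontal", "parietal", "temporal", "occipital"),
    nw: float = 2.0,
) -> dict[str, dict[str, TBRSeries]]:
    """Per-subject, per-region TBR series for one session (NW=2 spectra;
    see module docstring).  ``baseline`` maps subject -> region -> the
    subject's no-interaction baseline mean TBR."""
    out: dict[str, dict[str, TBRSeries]] = {}
    for name, rec in session.subjects().items():
        spec = multitaper_spectrogram(rec, nw=nw)
        series: dict[str, TBRSeries] = {}
        for region in regions:
            if not rec.montage.indices_in(region, usable_only=True):
                continue
            bl = baseline.get(name, {}).get(region) if baseline else None
            series[region] = tbr(spec, rec.montage, region, baseline_mean=bl)
        out[name] = series
    return out
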