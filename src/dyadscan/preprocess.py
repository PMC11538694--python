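"""Preprocessing: low-pass filtering, detrending, artifact detection and
excision with gap joining.

Artifact handling mirrors standard practice for free-moving EEG: an
amplitude rule (any sample exceeding a +/-300 uV threshold flags its 1-s
window) combined with a learned detector -- wavelet-decomposition energy
features per window fed to a small artificial neural network trained on
labeled (synthetic) segments.  Flagged windows are excised and the gap ends
joined; no interpolation.  A dyad's two recordings are excised *jointly*
(the union of both subjects' flags) so the paired envelope series stay
aligned on a common timeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from scipy.stats import kurtosis
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from dyadscan.recording import DyadSession, Recording

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- #
# filtering / detrending
# --------------------------------------------------------------------- #


def lowpass_filter(rec: Recording, order: int = 10, cutoff: float = 250.0) -> Recording:
    """Zero-phase Butterworth low-pass.

    A cutoff exactly at Nyquist is accepted with a warning (the filter is
    then designed marginally below Nyquist and is a near-identity); a cutoff
    above Nyquist is an error.
    """
    nyq = rec.fs / 2.0
    if cutoff > nyq:
        raise ValueError(f"cutoff {cutoff} Hz exceeds the Nyquist frequency {nyq} Hz")
    eff = cutoff
    if cutoff == nyq:
        eff = 0.999 * nyq
        logger.warning(
            "low-pass cutoff %g Hz equals Nyquist (%g Hz); applying a near-identity "
            "filter at %.3g Hz — consider cutoff <= %.3g Hz",
            cutoff, nyq, eff, 0.98 * nyq,
        )
    sos = signal.butter(order, eff, btype="low", fs=rec.fs, output="sos")
    out = rec.copy()
    out.samples = signal.sosfiltfilt(sos, out.samples, axis=1)
    return out


def detrend(rec: Recording) -> Recording:
    """Remove the per-channel least-squares line (linear trend + mean)."""
    if rec.n_times < 2:
        raise ValueError("need at least 2 samples to detrend")
    out = rec.copy()
    out.samples = signal.detrend(out.samples, axis=1, type="linear")
    return out


# --------------------------------------------------------------------- #
# artifact detection
# --------------------------------------------------------------------- #


def _analysis_channel_indices(rec: Recording) -> list[int]:
    return [
        i
        for i, c in enumerate(rec.montage.channel_names)
        if c not in rec.montage.excluded
    ]


def window_slices(n_times: int, fs: float, window: float = 1.0) -> list[slice]:
    """Whole windows on the shared timeline; a trailing partial window is
    not scored (and not excised)."""
    step = int(round(window * fs))
    n_win = n_times // step
    return [slice(i * step, (i + 1) * step) for i in range(n_win)]


def detect_amplitude_artifacts(
    rec: Recording, threshold: float = 300.0, window: float = 1.0
) -> np.ndarray:
    """Flag every 1-s window containing a sample with \\|v\\| strictly above
    ``threshold`` on any analysis channel.  Returns (n_windows,) bool."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0 uV")
    idx = _analysis_channel_indices(rec)
    slices = window_slices(rec.n_times, rec.fs, window)
    flags = np.zeros(len(slices), dtype=bool)
    absmax = np.abs(rec.samples[idx])
    for w, sl in enumerate(slices):
        flags[w] = bool((absmax[:, sl] > threshold).any())
    return flags


def wavelet_features(
    segment: np.ndarray,
    fs: float,
    wavelet: str = "db4",
    levels: int = 5,
    line_freq: float = 50.0,
    aggregate: bool = True,
) -> np.ndarray:
    """Feature vector for one 1-s segment (channels x samples or 1-D).

    Per channel: relative wavelet-level energies (``levels`` detail bands +
    the final approximation), log-variance, excess kurtosis, log max \\|v\\|,
    and the share of periodogram power within +/-1 Hz of the mains
    frequency.  Zero-energy segments get all-zero energies and a raised
    degenerate flag instead of 0/0.  With ``aggregate`` the features are
    averaged over channels (montage-size independent); otherwise
    concatenated.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    if seg.shape[1] < 2 ** levels:
        raise ValueError(f"segment too short ({seg.shape[1]} samples) for {levels} wavelet levels")
    feats = []
    for ch in seg:
        energy_total = float(np.sum(ch**2))
        if energy_total == 0.0:
            rel = np.zeros(levels + 1)
            stats = np.array([0.0, 0.0, 0.0, 0.0, 1.0])  # degenerate flag
        else:
            coeffs = pywt.wavedec(ch, wavelet, level=levels)
            energies = np.array([float(np.sum(c**2)) for c in coeffs])
            rel = energies / energies.sum()
            f, pxx = signal.periodogram(ch, fs=fs)
            total = pxx.sum()
            line = pxx[(f >= line_freq - 1.0) & (f <= line_freq + 1.0)].sum()
            stats = np.array(
                [
                    np.log1p(ch.var()),
                    kurtosis(ch, fisher=True, bias=True),
                    np.log1p(np.abs(ch).max()),
                    line / total if total > 0 else 0.0,
                    0.0,
                ]
            )
        feats.append(np.concatenate([rel, stats]))
    feats = np.asarray(feats)
    return feats.mean(axis=0) if aggregate else feats.ravel()


@dataclass
class ArtifactClassifier:
    """Wavelet-feature ANN over 1-s segments (clean vs artifact).

    ``threshold_`` is the calibrated decision threshold on the artifact
    score (set during training to target a ~2% false-flag rate on clean
    segments).
    """

    pipeline: Pipeline
    fs: float
    wavelet: str = "db4"
    levels: int = 5
    classes_: tuple = ()
    threshold_: float = 0.5

    def features(self, segments: list[np.ndarray]) -> np.ndarray:
        return np.asarray([wavelet_features(s, self.fs, self.wavelet, self.levels) for s in segments])

    def predict(self, segments: list[np.ndarray]) -> np.ndarray:
        return self.pipeline.predict(self.features(segments))

    def predict_proba(self, segments: list[np.ndarray]) -> np.ndarray:
        return self.pipeline.predict_proba(self.features(segments))

    def artifact_score(self, segments: list[np.ndarray]) -> np.ndarray:
        """P(artifact): 1 - P(class 'clean'); with multi-kind labels the
        clean class must be labeled ``"clean"``."""
        proba = self.predict_proba(segments)
        classes = list(self.pipeline.classes_)
        if "clean" in classes:
            return 1.0 - proba[:, classes.index("clean")]
        return proba[:, -1]


def train_artifact_ann(
    segments: list[np.ndarray],
    labels: list[str],
    fs: float,
    hidden: int = 32,
    seed: int = 0,
    wavelet: str = "db4",
    levels: int = 5,
) -> ArtifactClassifier:
    """Train the artifact ANN on labeled 1-s segments.

    Labels are ``"clean"`` vs artifact kind names (or just ``"artifact"``).
    Training is reproducible given ``seed``; inference is deterministic.
    """
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError(f"need >= 2 classes to train, got {uniq}")
    clf = ArtifactClassifier(pipeline=None, fs=fs, wavelet=wavelet, levels=levels)  # type: ignore[arg-type]
    X = clf.features(segments)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "ann",
                MLPClassifier(
                    hidden_layer_sizes=(hidden,),
                    early_stopping=True,
                    n_iter_no_change=25,
                    validation_fraction=0.15,
                    max_iter=2000,
                    random_state=seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny sets
        pipe.fit(X, np.asarray(labels))
    clf.pipeline = pipe
    clf.classes_ = tuple(pipe.classes_)
    # Neyman-Pearson operating point: flag threshold at the 98th percentile
    # of the artifact score over clean training segments (~2% false flags).
    labels_arr = np.asarray(labels)
    if "clean" in labels_arr:
        clean_scores = clf.artifact_score([s for s, l in zip(segments, labels_arr) if l == "clean"])
        clf.threshold_ = float(max(0.5, np.quantile(clean_scores, 0.98)))
        logger.info("artifact ANN decision threshold calibrated to %.3f", clf.threshold_)
    return clf


def detect_artifacts(
    rec: Recording,
    classifier: ArtifactClassifier | None = None,
    threshold: float = 300.0,
    window: float = 1.0,
    ann_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined detector: amplitude rule OR ANN score above threshold.

    Returns (flags, scores): per-window boolean flags and a continuous
    artifact score in [0, 1] (1 where the amplitude rule fires, else the ANN
    probability; the amplitude flag alone when no classifier is given).
    ``ann_threshold`` defaults to the classifier's calibrated operating
    point.
    """
    amp_flags = detect_amplitude_artifacts(rec, threshold=threshold, window=window)
    scores = amp_flags.astype(float)
    if classifier is not None:
        if ann_threshold is None:
            ann_threshold = classifier.threshold_
        idx = _analysis_channel_indices(rec)
        segments = [rec.samples[idx, sl] for sl in window_slices(rec.n_times, rec.fs, window)]
        ann_scores = classifier.artifact_score(segments)
        scores = np.maximum(scores, ann_scores)
    else:
        ann_threshold = 0.5
    flags = amp_flags | (scores > ann_threshold)
    return flags, scores


# --------------------------------------------------------------------- #
# excision
# --------------------------------------------------------------------- #


@dataclass
class ArtifactReport:
    flagged_windows: np.ndarray  # indices of removed windows
    n_windows: int
    fraction_removed: float
    window: float = 1.0
    kind_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_removed <= 1.0:
            raise ValueError("fraction_removed must lie in [0, 1]")


def excise_and_join(rec: Recording, flags: np.ndarray, window: float = 1.0) -> tuple[Recording, ArtifactReport]:
    """Remove flagged windows and join the gap ends.

    The output keeps the original sample order outside the flags; its length
    equals the input length minus the flagged length (a trailing partial
    window is always kept).
    """
    slices = window_slices(rec.n_times, rec.fs, window)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (len(slices),):
        raise ValueError(f"expected {len(slices)} window flags, got {flags.shape}")
    if flags.all() and len(slices) * int(round(window * rec.fs)) >= rec.n_times:
        raise ValueError("no usable data: every window is flagged")
    keep = np.ones(rec.n_times, dtype=bool)
    for w, sl in enumerate(slices):
        if flags[w]:
            keep[sl] = False
    out = rec.copy()
    out.samples = out.samples[:, keep]
    out.valid_mask = out.valid_mask[keep]
    removed = int((~keep).sum())
    report = ArtifactReport(
        flagged_windows=np.flatnonzero(flags),
        n_windows=len(slices),
        fraction_removed=removed / rec.n_times,
        window=window,
    )
    return out, report


def preprocess_recording(rec: Recording, cutoff: float = 245.0, order: int = 10) -> Recording:
    """Filter + detrend (no excision); flags are computed separately so a
    dyad can be excised jointly."""
    return detrend(lowpass_filter(rec, order=order, cutoff=cutoff))


def preprocess_dyad(
    session: DyadSession,
    classifier: ArtifactClassifier | None = None,
    cutoff: float = 245.0,
    order: int = 10,
    threshold: float = 300.0,
    window: float = 1.0,
) -> tuple[DyadSession, dict[str, ArtifactReport]]:
    """Clean both partners and excise the *union* of their flagged windows,
    keeping the paired series aligned on one shared timeline."""
    cleaned = {}
    flags = None
    for name, rec in session.subjects().items():
        r = preprocess_recording(rec, cutoff=cutoff, order=order)
        f, _ = detect_artifacts(r, classifier, threshold=threshold, window=window)
        flags = f if flags is None else (flags | f)
        cleaned[name] = r
    logger.info(
        "joint excision: %d/%d windows flagged for session %s",
        int(flags.sum()), flags.size, session.meta,
    )
    reports = {}
    out = {}
    for name, rec in cleaned.items():
        out[name], reports[name] = excise_and_join(rec, flags, window=window)
    new_session = DyadSession(human=out["human"], dog=out["dog"], meta=dict(session.meta))
    return new_session, reports
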