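"""Synthetic dyad generator: paired EEG-like recordings with known coupling.

Signal model
------------
Each subject's scalp signal is built per region from

* a slow positive *latent envelope*: an AR(1) process sampled at 1 Hz,
  linearly upsampled to the sampling rate and exponentiated (log-normal), so
  band power fluctuates on the multi-second timescale the analysis windows
  resolve;
* per-channel *carriers*: band-limited (4-30 Hz) Gaussian noise plus
  narrow oscillatory peaks in the theta (6 Hz) and beta (20 Hz) ranges,
  synthesized in the frequency domain;
* additive pink (1/f) background noise.

Interbrain coupling is implemented in the power domain: the follower's
regional envelope is a convex mixture of its own latent envelope and the
leader's envelope delayed by ``lag`` samples, with mixing weight equal to
the coupling strength.  Strength 0 therefore gives statistically
independent envelopes and strength 1 copies the leader's (lagged) envelope.
This produces exactly the phenomenon the analysis pipeline measures --
correlated, directed band-power envelopes -- without claiming biophysical
realism (no volume conduction, no source geometry).

Artifacts of five classes (ocular, EMG, cardiac, power-line, electrode) can
be injected at known locations, yielding a per-sample/channel ground-truth
mask for detector evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from dyadscan._rng import child_rng
from dyadscan.montage import REGIONS, Montage
from dyadscan.recording import DyadSession, Recording

ARTIFACT_KINDS = ("ocular", "emg", "cardiac", "line", "electrode")

# carrier composition (unit-variance components, weighted)
_W_BROAD, _W_THETA, _W_BETA = 1.0, 0.8, 0.6
_AMP_SCALE = 15.0  # uV; typical clean-signal RMS ~ 25 uV
_PINK_AMP = 6.0  # uV
_ENV_LOG_SD = 0.4
_ENV_AR = 0.7


# --------------------------------------------------------------------- #
# coupling specification
# --------------------------------------------------------------------- #


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth interbrain coupling for one session.

    ``strength`` is either a scalar (applied to the homologous
    frontal-frontal and parietal-parietal pairs, the region pairs that
    carry coupling in this paradigm) or a mapping
    ``(leader_region, follower_region) -> strength in [0, 1]``.
    ``leader`` names the driving subject; the follower's envelope mixes in
    the leader's envelope delayed by ``lag`` samples.
    """

    strength: float | Mapping[tuple[str, str], float] = 0.0
    leader: str = "human"
    lag: int = 500  # samples
    schedule: Mapping[int, float] | Callable[[int], float] | None = None

    def pair_strengths(self) -> dict[tuple[str, str], float]:
        if isinstance(self.strength, Mapping):
            pairs = dict(self.strength)
        else:
            s = float(self.strength)
            pairs = {("frontal", "frontal"): s, ("parietal", "parietal"): s}
        for (ra, rb), s in pairs.items():
            if ra not in REGIONS or rb not in REGIONS:
                raise ValueError(f"unknown region in coupling pair ({ra}, {rb})")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"coupling strength {s} outside [0, 1]")
        return pairs

    def __post_init__(self) -> None:
        if self.leader not in ("human", "dog"):
            raise ValueError("leader must be 'human' or 'dog'")
        if self.lag < 0:
            raise ValueError("lag must be >= 0 samples")
        self.pair_strengths()  # validate
        if isinstance(self.schedule, Mapping):
            if any(v < 0 for v in self.schedule.values()):
                raise ValueError("schedule multipliers must be >= 0")

    def schedule_multiplier(self, day: int) -> float:
        if self.schedule is None:
            return 1.0
        if isinstance(self.schedule, Mapping):
            return float(self.schedule[day])
        return float(self.schedule(day))


def logistic_schedule(t0: float = 4.0, rate: float = 1.1) -> Callable[[int], float]:
    """Day -> multiplier rising along a logistic curve (saturates near day 7
    with the defaults: >= 95% of the asymptote from day 7 on)."""

    def schedule(day: int) -> float:
        return 1.0 / (1.0 + math.exp(-rate * (day - t0)))

    return schedule


@dataclass
class ArtifactEvent:
    """One injected artifact: kind, affected channels, support, amplitude."""

    kind: str
    onset: float  # s
    duration: float  # s
    amplitude: float  # uV
    channels: tuple[str, ...] | None = None  # None -> kind-specific default
    freq: float = 50.0  # line artifacts only
    subtype: str | None = None  # electrode artifacts: step | flat | noisy

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}; expected one of {ARTIFACT_KINDS}")
        if self.amplitude <= 0:
            raise ValueError("artifact amplitude must be > 0 uV")
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("artifact must have onset >= 0 and duration > 0")


@dataclass
class SyntheticGroundTruth:
    """What the generator actually did; the oracle for downstream tests."""

    true_strength: dict[tuple[str, str], float]
    leader: str
    lag: int
    artifact_mask: dict[str, np.ndarray] = field(default_factory=dict)  # subject -> (n_ch, n_t) bool
    envelopes: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    # (subject, region) -> mixed envelope at fs; latent (pre-mix) envelopes
    latent_envelopes: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    events: dict[str, list[ArtifactEvent]] = field(default_factory=dict)

    def timeline_mask(self, subject: str) -> np.ndarray:
        m = self.artifact_mask.get(subject)
        if m is None:
            return np.zeros(0, dtype=bool)
        return m.any(axis=0)


# --------------------------------------------------------------------- #
# frequency-domain component synthesis
# --------------------------------------------------------------------- #


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, mask: np.ndarray) -> np.ndarray:
    """Real Gaussian noise with spectral amplitude shape ``mask`` (rfft grid),
    normalized to unit variance."""
    spec = (rng.standard_normal(mask.size) + 1j * rng.standard_normal(mask.size)) * mask
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _band_mask(n: int, fs: float, f_lo: float, f_hi: float, roll: float = 0.5) -> np.ndarray:
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = np.zeros_like(f)
    core = (f >= f_lo) & (f <= f_hi)
    mask[core] = 1.0
    lo_edge = (f >= f_lo - roll) & (f < f_lo)
    hi_edge = (f > f_hi) & (f <= f_hi + roll)
    mask[lo_edge] = 0.5 * (1 + np.cos(np.pi * (f_lo - f[lo_edge]) / roll))
    mask[hi_edge] = 0.5 * (1 + np.cos(np.pi * (f[hi_edge] - f_hi) / roll))
    return mask


def _peak_mask(n: int, fs: float, f0: float, sigma: float) -> np.ndarray:
    f = np.fft.rfftfreq(n, 1.0 / fs)
    return np.exp(-0.5 * ((f - f0) / sigma) ** 2)


def _pink_mask(n: int, fs: float) -> np.ndarray:
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = np.zeros_like(f)
    nz = f >= 1.0
    mask[nz] = 1.0 / np.sqrt(f[nz])
    return mask


def _latent_envelope(rng: np.random.Generator, n_times: int, fs: float, pad: int) -> np.ndarray:
    """Log-normal envelope on an extended grid of ``pad + n_times`` samples.

    The AR(1) latent runs at 1 Hz and is linearly upsampled; ``pad`` extra
    samples precede t=0 so lagged (delayed) reads stay in bounds.
    """
    n_total = pad + n_times
    n_sec = int(math.ceil(n_total / fs)) + 2
    z = np.empty(n_sec)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n_sec - 1) * math.sqrt(1.0 - _ENV_AR**2)
    for i in range(1, n_sec):
        z[i] = _ENV_AR * z[i - 1] + innov[i - 1]
    t_coarse = np.arange(n_sec, dtype=float)
    t_fine = np.arange(n_total) / fs
    z_fine = np.interp(t_fine, t_coarse, z)
    return np.exp(_ENV_LOG_SD * z_fine)


# --------------------------------------------------------------------- #
# dyad generation
# --------------------------------------------------------------------- #


def generate_dyad(
    spec: CouplingSpec,
    duration: float = 300.0,
    fs: float = 500.0,
    seed: int = 0,
    montage_human: Montage | None = None,
    montage_dog: Montage | None = None,
    theta_gain: Mapping[str, Mapping[str, float]] | None = None,
    meta: dict | None = None,
    keep_envelopes: bool = True,
) -> tuple[DyadSession, SyntheticGroundTruth]:
    """Generate one paired session with ground-truth coupling.

    Parameters
    ----------
    spec:
        Coupling strength/direction/lag for this session.
    duration, fs:
        Session length (s, >= 10) and sampling rate (Hz, >= 200).
    theta_gain:
        Optional per subject -> region multiplier on the theta oscillatory
        component (used to emulate attention-related TBR shifts).
    keep_envelopes:
        Store the latent and mixed envelopes in the ground truth (disable in
        large Monte-Carlo sweeps to save memory).
    """
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    montages = {
        "human": montage_human if montage_human is not None else Montage.human_16(),
        "dog": montage_dog if montage_dog is not None else Montage.dog_16(),
    }
    pairs = spec.pair_strengths()
    follower = "dog" if spec.leader == "human" else "human"
    for (r_lead, r_fol), s in pairs.items():
        if s > 0:
            if not montages[spec.leader].channels_in(r_lead, usable_only=False):
                raise ValueError(f"leader montage has no channels in coupled region {r_lead!r}")
            if not montages[follower].channels_in(r_fol, usable_only=False):
                raise ValueError(f"follower montage has no channels in coupled region {r_fol!r}")
    # total strength drawn from others must leave a convex mixture
    fol_totals: dict[str, float] = {}
    for (_, r_fol), s in pairs.items():
        fol_totals[r_fol] = fol_totals.get(r_fol, 0.0) + s
    if any(v > 1.0 + 1e-12 for v in fol_totals.values()):
        raise ValueError("total coupling strength into one follower region exceeds 1")

    n_times = int(round(duration * fs))
    pad = int(spec.lag)

    # latent envelopes per subject/region on the extended grid
    latent: dict[tuple[str, str], np.ndarray] = {}
    for subject in ("human", "dog"):
        for region in REGIONS:
            rng = child_rng(seed, "env", subject, region)
            latent[(subject, region)] = _latent_envelope(rng, n_times, fs, pad)

    # mixed envelopes (coupling acts here), restricted to t >= 0
    mixed: dict[tuple[str, str], np.ndarray] = {}
    for subject in ("human", "dog"):
        for region in REGIONS:
            own = latent[(subject, region)][pad:]
            if subject == follower:
                total = fol_totals.get(region, 0.0)
                env = (1.0 - total) * own
                for (r_lead, r_fol), s in pairs.items():
                    if r_fol == region and s > 0:
                        lead_ext = latent[(spec.leader, r_lead)]
                        delayed = lead_ext[pad - spec.lag : pad - spec.lag + n_times]
                        env = env + s * delayed
            else:
                env = own.copy()
            mixed[(subject, region)] = env

    # per-channel signals
    masks = {
        "broad": _band_mask(n_times, fs, 4.0, 30.0),
        "theta": _peak_mask(n_times, fs, 6.0, 0.15),
        "beta": _peak_mask(n_times, fs, 20.0, 0.25),
        "pink": _pink_mask(n_times, fs),
    }
    recordings: dict[str, Recording] = {}
    for subject in ("human", "dog"):
        mont = montages[subject]
        data = np.empty((mont.n_channels, n_times))
        for ci, ch in enumerate(mont.channel_names):
            region = mont.region_of[ch]
            rng = child_rng(seed, "carrier", subject, ch)
            g_theta = 1.0
            if theta_gain is not None:
                g_theta = float(theta_gain.get(subject, {}).get(region, 1.0))
            carrier = (
                _W_BROAD * _shaped_noise(rng, n_times, fs, masks["broad"])
                + _W_THETA * g_theta * _shaped_noise(rng, n_times, fs, masks["theta"])
                + _W_BETA * _shaped_noise(rng, n_times, fs, masks["beta"])
            )
            pink = _shaped_noise(rng, n_times, fs, masks["pink"])
            data[ci] = _AMP_SCALE * mixed[(subject, region)] * carrier + _PINK_AMP * pink
        recordings[subject] = Recording(
            samples=data,
            fs=fs,
            montage=mont,
            meta={"subject": subject, **(meta or {})},
        )

    truth = SyntheticGroundTruth(
        true_strength=pairs,
        leader=spec.leader,
        lag=spec.lag,
        artifact_mask={
            s: np.zeros((montages[s].n_channels, n_times), dtype=bool) for s in ("human", "dog")
        },
    )
    if keep_envelopes:
        truth.envelopes = mixed
        truth.latent_envelopes = {k: v[pad:] for k, v in latent.items()}
    session = DyadSession(human=recordings["human"], dog=recordings["dog"], meta=dict(meta or {}))
    return session, truth


# --------------------------------------------------------------------- #
# artifact injection
# --------------------------------------------------------------------- #


def _cos_ramp(n: int, fs: float, ramp_s: float = 0.01) -> np.ndarray:
    w = np.ones(n)
    nr = min(int(ramp_s * fs), n // 2)
    if nr > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        w[:nr] = edge
        w[-nr:] = edge[::-1]
    return w


def _default_channels(kind: str, montage: Montage, rng: np.random.Generator) -> tuple[str, ...]:
    if kind == "ocular":
        return tuple(montage.channels_in("frontal", usable_only=False))
    if kind == "emg":
        chans = montage.channels_in("temporal", usable_only=False) or list(montage.channel_names)
        return tuple(chans)
    if kind == "cardiac":
        chans = montage.channels_in("temporal", usable_only=False) + montage.channels_in(
            "occipital", usable_only=False
        )
        return tuple(chans or montage.channel_names)
    if kind == "line":
        return tuple(montage.channel_names)
    # electrode artifacts hit a single channel
    return (str(rng.choice(np.asarray(montage.channel_names))),)


def _ocular_wave(n: int, fs: float, amplitude: float) -> np.ndarray:
    # positive deflection followed by a negative trough, sub-4-Hz content
    x = np.arange(n) / max(n - 1, 1)
    w = np.exp(-0.5 * ((x - 0.35) / 0.16) ** 2) - 0.7 * np.exp(-0.5 * ((x - 0.72) / 0.20) ** 2)
    return amplitude * w / np.abs(w).max()


def _cardiac_wave(n: int, fs: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    rate = rng.uniform(1.0, 2.0)  # beats/s
    out = np.zeros(n)
    beat_len = int(0.06 * fs)
    t = np.arange(beat_len) / fs
    beat = np.sin(2 * np.pi * t / 0.06) * np.hanning(beat_len)
    beat *= amplitude / np.abs(beat).max()
    start = rng.uniform(0, 1.0 / rate)
    pos = int(start * fs)
    while pos + beat_len <= n:
        out[pos : pos + beat_len] += beat
        pos += int(fs / rate)
    return out


def inject_artifacts(
    rec: Recording, events: list[ArtifactEvent], seed: int = 0
) -> tuple[Recording, np.ndarray]:
    """Inject artifact events into a copy of ``rec``.

    Returns the contaminated recording and a (n_channels, n_times) boolean
    ground-truth mask covering exactly the injected supports.  Samples
    outside all events are bit-identical to the input.
    """
    out = rec.copy()
    mask = np.zeros(out.samples.shape, dtype=bool)
    fs = rec.fs
    for ev_i, ev in enumerate(events):
        i0 = int(round(ev.onset * fs))
        i1 = int(round((ev.onset + ev.duration) * fs))
        if i0 < 0 or i1 > rec.n_times:
            raise ValueError(
                f"event {ev.kind} [{ev.onset}, {ev.onset + ev.duration}) s outside recording"
            )
        n = i1 - i0
        rng = child_rng(seed, "artifact", ev_i, ev.kind)
        channels = ev.channels or _default_channels(ev.kind, rec.montage, rng)
        idx = [rec.montage.channel_names.index(c) for c in channels]
        ramp = _cos_ramp(n, fs)
        if ev.kind == "ocular":
            wave = _ocular_wave(n, fs, ev.amplitude)
            for ci in idx:
                out.samples[ci, i0:i1] += wave * rng.uniform(0.8, 1.0)
        elif ev.kind == "emg":
            hi = min(120.0, 0.45 * fs)
            band = _band_mask(n, fs, 35.0, hi, roll=2.0)
            for ci in idx:
                noise = _shaped_noise(rng, n, fs, band) * (ev.amplitude / 3.5)
                out.samples[ci, i0:i1] += noise * ramp
        elif ev.kind == "cardiac":
            wave = _cardiac_wave(n, fs, ev.amplitude, rng)
            for ci in idx:
                out.samples[ci, i0:i1] += wave
        elif ev.kind == "line":
            t = np.arange(i0, i1) / fs
            phase = rng.uniform(0, 2 * np.pi)
            wave = ev.amplitude * np.sin(2 * np.pi * ev.freq * t + phase)
            for ci in idx:
                out.samples[ci, i0:i1] += wave * ramp
        elif ev.kind == "electrode":
            sub = ev.subtype or str(rng.choice(["step", "flat", "noisy"]))
            ci = idx[0]
            if sub == "step":
                out.samples[ci, i0:i1] += ev.amplitude
            elif sub == "flat":
                out.samples[ci, i0:i1] = 0.0
            elif sub == "noisy":
                out.samples[ci, i0:i1] += rng.standard_normal(n) * (ev.amplitude / 2.0)
            else:
                raise ValueError(f"unknown electrode artifact subtype {sub!r}")
            idx = [ci]
        for ci in idx:
            mask[ci, i0:i1] = True
    return out, mask


def random_artifact_events(
    montage: Montage,
    duration: float,
    contamination: float,
    seed: int,
    kinds: tuple[str, ...] = ARTIFACT_KINDS,
) -> list[ArtifactEvent]:
    """Events covering ~``contamination`` of the timeline, aligned to whole
    1-s analysis windows, with kind-typical amplitudes."""
    amplitudes = {"ocular": 400.0, "emg": 90.0, "cardiac": 250.0, "line": 60.0, "electrode": 350.0}
    rng = child_rng(seed, "events")
    n_windows = int(duration)
    n_bad = int(round(contamination * n_windows))
    if n_bad == 0:
        return []
    starts = rng.choice(n_windows, size=n_bad, replace=False)
    starts.sort()
    events: list[ArtifactEvent] = []
    run_start = None
    prev = None
    runs: list[tuple[int, int]] = []
    for s in starts:
        if run_start is None:
            run_start, prev = s, s
        elif s == prev + 1:
            prev = s
        else:
            runs.append((run_start, prev + 1))
            run_start, prev = s, s
    if run_start is not None:
        runs.append((run_start, prev + 1))
    for a, b in runs:
        kind = str(rng.choice(np.asarray(kinds)))
        events.append(
            ArtifactEvent(kind=kind, onset=float(a), duration=float(b - a), amplitude=amplitudes[kind])
        )
    return events


# --------------------------------------------------------------------- #
# multi-day, multi-condition study designs
# --------------------------------------------------------------------- #

CONDITIONS = ("separate_room", "same_room", "interaction")


@dataclass
class StudyDesign:
    """A simulated study: dyads x days x conditions.

    ``strength`` is the asymptotic interbrain coupling in the interaction
    condition; the two control conditions (separate rooms; same room without
    interaction) always get strength 0.  ``schedule`` maps day (1-based) to
    a multiplier on ``strength`` (default: logistic growth saturating near
    day 7).  ``attention_theta_gain`` scales the frontal theta component
    during interaction (< 1 emulates the attentive-state TBR drop; 1.0
    disables the effect, as for an inattentive subject).
    """

    n_dyads: int = 10
    days: int = 5
    conditions: tuple[str, ...] = CONDITIONS
    duration: float = 300.0
    fs: float = 500.0
    strength: float = 0.8
    lag: int = 500
    leader: str = "human"
    schedule: Callable[[int], float] | Mapping[int, float] | None = None
    attention_theta_gain: float = 1.0
    artifact_contamination: float = 0.0
    channels_per_region: int = 4
    exclude_dog_temporal: bool = True

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.days < 1:
            raise ValueError("need n_dyads >= 1 and days >= 1")

    def schedule_multiplier(self, day: int) -> float:
        sched = self.schedule
        if sched is None:
            sched = logistic_schedule()
        if isinstance(sched, Mapping):
            return float(sched[day])
        return float(sched(day))


def build_study(design: StudyDesign, seed: int = 0) -> list[tuple[DyadSession, SyntheticGroundTruth]]:
    """Generate every session of a study design, deterministically in seed.

    Sessions carry metadata (dyad, day, condition, true strength) in
    ``session.meta``; ordering is dyad-major, then day, then condition.
    """
    montage_h = Montage.standard(design.channels_per_region)
    montage_d = Montage.standard(
        design.channels_per_region,
        exclude_regions=("temporal",) if design.exclude_dog_temporal else (),
    )
    out: list[tuple[DyadSession, SyntheticGroundTruth]] = []
    for dyad in range(design.n_dyads):
        for day in range(1, design.days + 1):
            for condition in design.conditions:
                if condition == "interaction":
                    s = design.strength * design.schedule_multiplier(day)
                    gain = design.attention_theta_gain
                else:
                    s, gain = 0.0, 1.0
                s = min(max(s, 0.0), 1.0)
                spec = CouplingSpec(strength=s, leader=design.leader, lag=design.lag)
                meta = {"dyad": dyad, "day": day, "condition": condition, "true_strength": s}
                theta_gain = None
                if gain != 1.0:
                    theta_gain = {"human": {"frontal": gain}, "dog": {"frontal": gain}}
                session, truth = generate_dyad(
                    spec,
                    duration=design.duration,
                    fs=design.fs,
                    seed=int(child_rng(seed, "session", dyad, day, condition).integers(2**31)),
                    montage_human=montage_h,
                    montage_dog=montage_d,
                    theta_gain=theta_gain,
                    meta=meta,
                    keep_envelopes=False,
                )
                if design.artifact_contamination > 0:
                    for subject in ("human", "dog"):
                        rec = getattr(session, subject)
                        ev_seed = int(
                            child_rng(seed, "artifacts", dyad, day, condition, subject).integers(2**31)
                        )
                        events = random_artifact_events(
                            rec.montage, design.duration, design.artifact_contamination, ev_seed
                        )
                        dirty, mask = inject_artifacts(rec, events, seed=ev_seed)
                        setattr(session, subject, dirty)
                        truth.artifact_mask[subject] = mask
                        truth.events[subject] = events
                out.append((session, truth))
    return out
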