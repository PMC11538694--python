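# Methods

## Problem setting

`dyadscan` analyzes *hyperscanning* data: simultaneous EEG from two
interacting partners (here called the human-role and dog-role subject of a
dyad).  The scientific questions it addresses are (i) whether the two
brains' band-power fluctuations become correlated during social
interaction (interbrain coupling), (ii) whether that coupling is directed
— one partner's activity leading the other's — and (iii) whether an
attention index (the theta/beta ratio) shifts during interaction.  Because
no public paired human–dog EEG exists at this scale, the package ships a
synthetic dyad generator with fully known ground truth, and every claim the
pipeline makes is validated as a *recovery* or *calibration* property
against that ground truth.

## Synthetic dyad generator

Each subject's per-channel signal is

    x_c(t) = a · E_r(t) · C_c(t) + b · n_c(t),

where `E_r` is the region's slow positive envelope, `C_c` a per-channel
carrier, and `n_c` pink (1/f) noise.  Components:

* **Envelope** `E_r = exp(0.4 z_r)`: `z_r` is a unit-variance AR(1) process
  (lag-1 coefficient 0.7) sampled at 1 Hz and linearly upsampled, so band
  power fluctuates on the multi-second scale the 1-s analysis windows
  resolve.  The log-normal form keeps envelopes positive and gives the
  power series the skewed, bursty look of real band-power traces.
* **Carrier**: unit-variance band-limited (4–30 Hz) Gaussian noise plus
  narrow oscillatory peaks at 6 Hz (theta, weight 0.8) and 20 Hz (beta,
  weight 0.6), synthesized in the frequency domain with raised-cosine band
  edges.  `a = 15 µV` puts clean-signal RMS near 25 µV; with `b = 6 µV` of
  pink noise, ≥ 97% of (4–30 Hz ∪ >40 Hz) power lies in band, and clean
  data essentially never crosses the ±300 µV artifact threshold.
* **Coupling** acts in the power domain: the follower's regional envelope
  is the convex mixture `(1−s)·own + s·leader(t − lag)`.  Strength `s = 0`
  gives independent envelopes; `s = 1` copies the leader's lagged envelope.
  Default lag 500 samples (1 s at 500 Hz).  Day schedules multiply `s`;
  the default schedule is logistic with midpoint day 4 and rate 1.1/day,
  which exceeds 95% of its asymptote from day 7 onward.
* **Attention effect**: during interaction the frontal theta carrier weight
  can be scaled (default study gain 0.7), imprinting a frontal-specific
  TBR reduction.
* **Artifacts** of five classes are injected additively (the electrode
  "flat" subtype replaces): ocular (slow positive-then-negative biphasic
  wave on frontal channels, 400 µV), EMG (35–120 Hz noise bursts, 90 µV
  scale), cardiac (1–2 Hz trains of sharp 60-ms biphasic spikes, 250 µV),
  power line (50 Hz sinusoid, 60 µV), and electrode faults
  (step/flat/noisy on a single channel, 350 µV).  Injection is confined to
  event supports and returns an exact per-sample/channel mask.

All randomness derives from one integer seed through
`SeedSequence(seed, spawn_key=…)` splitting, so identical (spec, seed)
produce bit-identical arrays and any sub-stream can be reproduced in
isolation.

**What the generator does not emulate**: volume conduction, electrode
geometry, inter-channel covariance of real scalp EEG, subject-specific
spectra, non-stationary rhythms, or any biophysics of either species.
Passing tests therefore demonstrate that the *pipeline* recovers coupling
of the power-envelope kind it is designed to measure — not that real
human–dog recordings contain such coupling.

## Preprocessing

Tenth-order Butterworth low-pass, applied forward–backward (zero phase;
downstream analysis is power-based, so phase handling is free and
zero-phase avoids group delay).  The conventional 250 Hz cutoff equals the
Nyquist frequency at fs = 500 Hz; the filter accepts it with a warning as a
near-identity, and the pipeline default is 245 Hz.  Linear detrending is
per-channel least squares.

Artifact windows (1 s, channel-agnostic) are flagged by an amplitude rule
(any sample strictly above 300 µV on an analysis channel; boundary strict
because the threshold is a convention, not a measured quantity) combined
with a learned detector: per-window features are Daubechies-4 five-level
relative wavelet energies plus log-variance, kurtosis, log peak amplitude
and the mains-frequency (±1 Hz) periodogram power share, averaged over
channels (montage-size independent); a single-hidden-layer (32-unit) MLP
with early stopping is trained on labeled synthetic segments only.  The
decision threshold on the artifact probability is calibrated on the clean
training segments to a ~2% false-flag rate (Neyman–Pearson operating
point), so the removed fraction tracks the true contamination instead of
the classifier's prior.  Zero-energy segments get defined fallback features
(energies 0, degenerate flag 1).

Flagged windows are excised and the gap ends joined — no interpolation.
The two partners of a dyad are excised *jointly* (union of their flags) so
the paired envelopes stay aligned on one shared timeline; this is required
for any meaningful interbrain correlation and is logged per session.

## Spectral analysis

1-s non-overlapping windows; multitaper PSD with time half-bandwidth
NW = 4 and 2·NW−1 = 7 DPSS tapers; integer bins 4–30 Hz (27 bins).  Each
frequency column is peak-normalized (divided by its maximum over windows;
all-zero columns are left at zero).  Normalized power is then averaged over
a region's usable channels and the 4–30 Hz bins, yielding one envelope
series per region per subject at 1 sample/s.  Averaging after
normalization keeps channels and frequencies on an equal footing; the
normalization is within-session.

Band powers sum the PSD over a band's integer bins (theta 4–8, alpha 8–13,
beta 13–30 Hz).  **TBR uses a dedicated NW = 2 spectrogram**: the NW = 4
spectral window is 8 Hz wide — wider than the 4-Hz theta band — and
measurably deflates theta/beta ratios (a 6 Hz + 20 Hz two-tone with true
ratio 4 reads ≈ 2.8 under NW = 4 but ≈ 4.0 under NW = 2, whose ±2 Hz
concentration fits inside the narrowest band).  TBR per window is
theta/beta total power; windows with zero beta power are marked invalid.
Normalized TBR divides by the same subject's same-day no-interaction
(same-room) baseline mean — the baseline definition is a package choice
and configurable.

## Interbrain coupling and the pseudo-pair null

Coupling is the Pearson correlation across time windows of the two
subjects' region envelope series, for all 4×4 ordered region pairs;
homologous frontal–frontal and parietal–parietal pairs are the primary
endpoints.  Zero-variance series yield missing values, never 0.

The pseudo-pair null pairs the human-role series of one session with the
dog-role series of every *other* session in the same stratum (all
n·(n−1) mismatched combinations, series truncated to the shortest),
controlling for condition-generic structure.  Real-vs-null is compared
with a two-sided Mann–Whitney U test.  Calibration is verified by
simulation: at strength 0 the test rejects at ≈ the nominal 5% level
(≤ 7% over 500 simulated studies of 6 dyads).

## MVAR / GPDC directionality

The paired (human, dog) region envelopes (demeaned, 1 sample/s) are
modeled as a bivariate VAR(p); coefficients by multivariate least squares,
innovation covariance from the residuals (degree-of-freedom adjusted),
order selected by BIC on a common sample (cap 20, and never more than
n/(10k)).  Stability (companion spectral radius < 1) is checked; unstable
fits are flagged, not silently used.

Generalized partial directed coherence from source j to target i:

    Ā(f) = I − Σ_r A_r e^{−i2πfr}
    G_ij(f) = (|Ā_ij(f)|/σ_i) / sqrt(Σ_m |Ā_mj(f)|²/σ_m²),  σ_m² = SIG_mm.

This innovation-variance-weighted, column-normalized form satisfies
Σ_i G_ij(f)² = 1 identically — used as a machine-precision self-check.
The transfer function H = Ā⁻¹, spectral matrix S = H·SIG·H^H and ordinary
coherence C_ij = |S_ij|²/(S_ii S_jj) are computed and exported alongside.
Because the envelopes are sampled at 1 Hz, the frequency axis is 0–0.5
cycles/s of *envelope fluctuation*; band summaries default to 0.01–0.4
cycles/s.  Bivariate models are the default; the joint multivariate
conditioning set is available through `fit_mvar`/`gpdc` on stacked series.

## Statistics layer

Friedman rank test (in-house, mid-ranked ties with the standard
correction, valid for k = 2; verified against scipy and the brute-force
rank formula), Mann–Whitney U (exact for ≤ 8 untied values per group,
tie-corrected normal approximation otherwise), Holm–Šídák step-down
adjustment, OLS exposure regression (slope ± SE, two-sided t), and a
logistic growth fit L/(1+e^{−k(t−t0)}) by multi-start least squares
(k ∈ {0.3, 0.7, 1.2, 2} × t0 at the day quartiles), reporting the plateau
day t0 + ln(19)/k (where the fitted curve reaches 95% of L).  Constant
data and non-convergent fits return flagged degenerate results.

## Study conditions and problem sizes

Monte-Carlo validations use: 300-s sessions for single-session recovery
properties (coupling curve, direction recovery), 60-s sessions and a
minimal 1-channel-per-region montage for the 500-study null calibration,
and 150-s sessions for the five-day exposure-slope and 10-day plateau
studies (4 dyads per plateau study: per-day correlation means then need
~0.035 SE, small against the 0.67 dynamic range of the day curve, so the
fitted plateau reflects the schedule rather than sampling noise).  Day-curve studies use asymptotic strength 0.5 — the
regime where the measured correlation plateaus near 0.4, matching the
level multi-day dyad studies report, and where the r-vs-strength response
is close to linear, so the fitted plateau reflects the schedule rather
than response saturation.  Direction-recovery studies use strength 0.8
with a 2-s lag.  These sizes are the package's chosen desk-scale
conditions; all are arguments, not constants.

## Known limitations

* The generator's coupling is purely power-envelope-level; phase-coupling
  methods cannot be validated against it.
* The ANN detector is trained and evaluated on synthetic artifacts; its
  performance on real EEG artifacts is untested by construction.
* The manual (visual-inspection) share of artifact rejection in real
  workflows has no counterpart here; the automatic detector stands alone.
* Pseudo-pair stratification assumes sessions of comparable length within
  a stratum; series are truncated to the shortest.
* EDF files can be read (via `mne`) but outputs are columnar CSV + JSON
  sidecars only.
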