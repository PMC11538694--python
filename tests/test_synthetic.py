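"""Generator ground truth: determinism, coupling structure, artifact
injection locality, study-design bookkeeping, spectral realism."""

import numpy as np
import pytest
from scipy.signal import periodogram

from dyadscan.coupling import pearson
from dyadscan.montage import Montage
from dyadscan.synthetic import (
    ArtifactEvent,
    CouplingSpec,
    StudyDesign,
    build_study,
    generate_dyad,
    inject_artifacts,
    logistic_schedule,
)


class TestMontage:
    def test_standard_layout(self):
        m = Montage.human_16()
        assert m.n_channels == 16
        assert all(len(m.channels_in(r)) == 4 for r in m.regions)

    def test_dog_temporal_excluded_but_generated(self):
        m = Montage.dog_16()
        assert m.channels_in("temporal") == []
        assert len(m.channels_in("temporal", usable_only=False)) == 4

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            Montage(("X1",), {"X1": "cerebellum"})


class TestGenerateDyad:
    def test_deterministic_in_seed(self, minimal_montages):
        mh, md = minimal_montages
        spec = CouplingSpec(strength=0.5)
        a, _ = generate_dyad(spec, duration=20, seed=5, montage_human=mh, montage_dog=md)
        b, _ = generate_dyad(spec, duration=20, seed=5, montage_human=mh, montage_dog=md)
        np.testing.assert_array_equal(a.human.samples, b.human.samples)
        np.testing.assert_array_equal(a.dog.samples, b.dog.samples)

    def test_zero_strength_envelopes_independent(self, minimal_montages):
        """Mean within-dyad envelope correlation is ~0 at strength 0 (the
        slow envelopes have ~50 effective samples per 300-s session, so a
        single seed can stray to |r| ~ 0.15; the mean over seeds cannot)."""
        mh, md = minimal_montages
        rs = []
        for seed in range(10):
            _, truth = generate_dyad(
                CouplingSpec(strength=0.0), duration=300, seed=seed, montage_human=mh, montage_dog=md
            )
            rs.append(pearson(truth.envelopes[("human", "frontal")], truth.envelopes[("dog", "frontal")]))
        assert abs(np.mean(rs)) < 0.1

    def test_full_strength_envelopes_shared(self, minimal_montages):
        mh, md = minimal_montages
        session, truth = generate_dyad(
            CouplingSpec(strength=1.0, lag=0), duration=300, seed=1, montage_human=mh, montage_dog=md
        )
        r = pearson(truth.envelopes[("human", "frontal")], truth.envelopes[("dog", "frontal")])
        assert r > 0.8

    def test_leader_precedes_follower_by_lag(self, coupled_session):
        """Cross-correlation of the region envelopes peaks where the leader
        (human) precedes the follower by the configured lag."""
        _, truth = coupled_session
        eh = truth.envelopes[("human", "frontal")]
        ed = truth.envelopes[("dog", "frontal")]
        eh = eh - eh.mean()
        ed = ed - ed.mean()
        lags = np.arange(0, 3001, 250)  # follower delayed relative to leader
        xcorr = [np.dot(eh[: eh.size - l], ed[l:]) for l in lags]
        assert lags[int(np.argmax(xcorr))] == truth.lag == 1000

    def test_envelope_coupling_monotone_in_strength(self, minimal_montages):
        mh, md = minimal_montages
        means = []
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            rs = []
            for seed in range(20):
                _, truth = generate_dyad(
                    CouplingSpec(strength=s), duration=60, seed=seed, montage_human=mh, montage_dog=md
                )
                rs.append(
                    pearson(truth.envelopes[("human", "frontal")], truth.envelopes[("dog", "frontal")])
                )
            means.append(np.mean(rs))
        assert np.all(np.diff(means) >= 0)

    def test_spectral_realism(self, uncoupled_session):
        """Clean synthetic EEG concentrates in 4-30 Hz: >= 80% of the
        combined (4-30) + (>40 Hz) power lies in band."""
        session, _ = uncoupled_session
        f, pxx = periodogram(session.human.samples, fs=session.fs, axis=1)
        inband = pxx[:, (f >= 4) & (f <= 30)].sum()
        high = pxx[:, f > 40].sum()
        assert inband / (inband + high) >= 0.8

    def test_coupled_region_without_channels_rejected(self):
        no_frontal = Montage(("P1", "O1", "T1"), {"P1": "parietal", "O1": "occipital", "T1": "temporal"})
        with pytest.raises(ValueError, match="no channels in coupled region"):
            generate_dyad(CouplingSpec(strength=0.5), duration=10, seed=0, montage_dog=no_frontal)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            generate_dyad(CouplingSpec(), duration=5, seed=0)
        with pytest.raises(ValueError):
            generate_dyad(CouplingSpec(), duration=20, fs=100, seed=0)
        with pytest.raises(ValueError):
            CouplingSpec(strength=1.5)
        with pytest.raises(ValueError):
            CouplingSpec(leader="cat")


class TestInjectArtifacts:
    def test_empty_event_list_is_identity(self, uncoupled_session):
        session, _ = uncoupled_session
        out, mask = inject_artifacts(session.human, [], seed=0)
        np.testing.assert_array_equal(out.samples, session.human.samples)
        assert not mask.any()

    def test_modification_confined_to_supports(self, uncoupled_session):
        session, _ = uncoupled_session
        events = [
            ArtifactEvent("ocular", onset=5.0, duration=1.0, amplitude=400.0),
            ArtifactEvent("emg", onset=20.0, duration=2.0, amplitude=90.0),
            ArtifactEvent("electrode", onset=40.0, duration=1.0, amplitude=350.0),
        ]
        out, mask = inject_artifacts(session.human, events, seed=3)
        np.testing.assert_array_equal(out.samples[~mask], session.human.samples[~mask])
        assert (out.samples[mask] != session.human.samples[mask]).mean() > 0.5

    def test_line_event_dominates_psd_at_50hz(self, uncoupled_session):
        session, _ = uncoupled_session
        ev = ArtifactEvent("line", onset=0.0, duration=300.0, amplitude=60.0, channels=("F1",))
        out, _ = inject_artifacts(session.human, [ev], seed=0)
        f, pxx = periodogram(out.samples[0], fs=session.fs)
        assert abs(f[int(np.argmax(pxx))] - 50.0) < 0.5

    def test_ocular_amplitude_exceeds_300uv(self, uncoupled_session):
        session, _ = uncoupled_session
        ev = ArtifactEvent("ocular", onset=10.0, duration=1.0, amplitude=400.0)
        out, mask = inject_artifacts(session.human, [ev], seed=0)
        assert (np.abs(out.samples[mask]) > 300.0).any()

    def test_unknown_kind_and_bounds_rejected(self, uncoupled_session):
        session, _ = uncoupled_session
        with pytest.raises(ValueError, match="unknown artifact kind"):
            ArtifactEvent("cosmic", onset=0, duration=1, amplitude=100)
        with pytest.raises(ValueError, match="outside recording"):
            inject_artifacts(session.human, [ArtifactEvent("line", onset=299.5, duration=2, amplitude=50)], seed=0)


class TestBuildStudy:
    def test_session_count_and_controls_uncoupled(self):
        design = StudyDesign(n_dyads=2, days=2, duration=10, channels_per_region=1)
        sessions = build_study(design, seed=0)
        assert len(sessions) == 2 * 2 * 3
        for session, truth in sessions:
            if session.meta["condition"] != "interaction":
                assert all(v == 0 for v in truth.true_strength.values())

    def test_increasing_schedule_gives_increasing_strengths(self):
        design = StudyDesign(
            n_dyads=1, days=5, conditions=("interaction",), duration=10, channels_per_region=1
        )
        sessions = build_study(design, seed=0)
        strengths = [s.meta["true_strength"] for s, _ in sessions]
        assert all(b > a for a, b in zip(strengths, strengths[1:]))

    def test_logistic_schedule_plateaus_by_day_seven(self):
        sched = logistic_schedule()
        asymptote = 1.0
        for day in (7, 8, 9, 10):
            assert sched(day) >= 0.95 * asymptote

    def test_deterministic(self):
        design = StudyDesign(n_dyads=1, days=1, duration=10, channels_per_region=1)
        a = build_study(design, seed=9)
        b = build_study(design, seed=9)
        np.testing.assert_array_equal(a[0][0].human.samples, b[0][0].human.samples)
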