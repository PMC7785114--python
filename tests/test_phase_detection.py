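"""Smile-phase segmentation: boundaries, validation, robustness."""

import numpy as np
import pytest

from auda.phase_detection import (
    concat_sequences,
    detect_phases,
    minimum_retained_duration,
    noise_robustness,
    phase_agreement,
)
from auda.synthetic import SyntheticConfig, generate_profile, trapezoid_profile
from auda.types import IntensitySeries, PhaseTrack, SmileEvent


def series(values, fps=50.0):
    values = np.asarray(values, dtype=float)
    return IntensitySeries(values=values, timestamps=np.arange(len(values)) / fps, fps=fps)


class TestDetectPhases:
    def test_constant_zero_no_events(self):
        track = detect_phases(series(np.zeros(200)))
        assert track.events == []
        assert all(lab == "none" for lab in track.labels)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_phases(series(np.zeros(10)))

    def test_trapezoid_apex_boundaries_within_window_blur(self):
        # rise frames 0-49, plateau 50-149, fall 150-199; omega=27 blurs
        # the detected boundaries by up to half a window
        prof, _ = trapezoid_profile(50.0, 1.0, 2.0, 1.0, ramp="linear")
        track = detect_phases(prof)
        assert len(track.events) == 1
        ev = track.events[0]
        assert abs(ev.t_ap - 50) <= 14
        assert abs(ev.t_off - 150) <= 14

    def test_two_separated_smiles_two_events(self):
        a, _ = trapezoid_profile(50.0, 0.6, 1.2, 0.6, lead_s=0.5, tail_s=0.7)
        b, _ = trapezoid_profile(50.0, 0.6, 1.2, 0.6, lead_s=0.7, tail_s=0.5)
        combined, _ = concat_sequences([a, b])
        track = detect_phases(combined)
        assert len(track.events) == 2
        assert track.events[0].t_end <= track.events[1].t_on

    def test_sub_second_smile_discarded(self):
        prof, _ = trapezoid_profile(50.0, 0.25, 0.4, 0.25)  # 0.9 s, no padding
        assert detect_phases(prof).events == []

    def test_events_satisfy_invariants(self):
        cfg = SyntheticConfig()
        for seed in range(5):
            prof, _ = generate_profile(cfg, "spontaneous", seed)
            for ev in detect_phases(prof).events:
                assert ev.t_on < ev.t_ap <= ev.t_off < ev.t_end
                assert ev.duration(prof.fps) >= 1.0

    def test_constant_offset_invariance(self):
        prof, _ = trapezoid_profile(50.0, 0.8, 1.5, 0.8, lead_s=0.4, tail_s=0.4)
        base = detect_phases(prof)
        shifted = series(prof.values - 0.63)
        assert detect_phases(shifted).events == base.events

    def test_idempotent_under_trailing_baseline(self):
        prof, _ = trapezoid_profile(50.0, 0.8, 1.5, 0.8, lead_s=0.4, tail_s=0.8)
        base = detect_phases(prof)
        extended = series(np.concatenate([prof.values, np.zeros(40)]))
        ext = detect_phases(extended)
        assert ext.events == base.events
        assert list(ext.labels[: len(prof)]) == list(base.labels)

    def test_onset_contains_delta_max_offset_contains_delta_min(self):
        from auda.dynamics import compute_dynamics

        prof, _ = trapezoid_profile(50.0, 0.8, 1.6, 0.8, lead_s=0.4, tail_s=0.4,
                                    ramp="linear")
        track = detect_phases(prof)
        (ev,) = track.events
        dyn = compute_dynamics(prof, 27)
        t_dmax = int(np.argmax(dyn.slope))
        t_dmin = int(np.argmin(dyn.slope))
        assert ev.t_on <= t_dmax < ev.t_ap
        assert ev.t_off <= t_dmin < ev.t_end


class TestMinimumRetainedDuration:
    def test_threshold_is_one_second(self):
        assert minimum_retained_duration(fps=50.0) == pytest.approx(1.0, abs=1e-9)

    def test_just_below_rejected_just_above_retained(self):
        def retained(d):
            n = int(d * 50 + 1e-9)
            nr, na = n // 4, n - 2 * (n // 4)
            prof, _ = trapezoid_profile(50.0, nr / 50, na / 50, nr / 50)
            return bool(detect_phases(prof).events)

        assert not retained(0.99)
        assert retained(1.01)


class TestPhaseAgreement:
    def test_identical_tracks(self):
        t = PhaseTrack(labels=np.array(["none"] * 5 + ["apex"] * 5, dtype=object))
        rep = phase_agreement(t, t)
        assert rep["matched"] == 1.0
        assert np.trace(rep["confusion"]) == 10

    def test_fully_disjoint_tracks(self):
        a = PhaseTrack(labels=np.array(["apex"] * 8, dtype=object))
        b = PhaseTrack(labels=np.array(["none"] * 8, dtype=object))
        assert phase_agreement(a, b)["matched"] == 0.0

    def test_partial_relabeling_exact_fraction(self, rng):
        labels = np.array(["onset"] * 100, dtype=object)
        a = PhaseTrack(labels=labels.copy())
        flip = rng.choice(100, size=10, replace=False)
        labels[flip] = "offset"
        b = PhaseTrack(labels=labels)
        assert phase_agreement(a, b)["matched"] == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        a = PhaseTrack(labels=np.array(["none"] * 5, dtype=object))
        b = PhaseTrack(labels=np.array(["none"] * 6, dtype=object))
        with pytest.raises(ValueError):
            phase_agreement(a, b)


class TestConcatSequences:
    def test_single_input_passthrough(self, single_trapezoid):
        prof, _ = single_trapezoid
        combined, offsets = concat_sequences([prof])
        np.testing.assert_array_equal(combined.values, prof.values)
        assert offsets.tolist() == [0]

    def test_offsets_and_length(self):
        a = series(np.zeros(100))
        b = series(np.ones(100))
        combined, offsets = concat_sequences([a, b])
        assert len(combined) == 200
        assert offsets.tolist() == [0, 100]

    def test_fps_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concat_sequences([series(np.zeros(50), fps=50), series(np.zeros(50), fps=25)])

    def test_concat_detection_matches_per_sequence(self):
        cfg = SyntheticConfig(tail_s=0.6, lead_s=0.6)
        profiles = [generate_profile(cfg, cls, seed)[0]
                    for seed in range(3) for cls in ("posed", "spontaneous")]
        per_seq = np.concatenate([detect_phases(p).labels for p in profiles])
        combined, _ = concat_sequences(profiles)
        joint = detect_phases(combined).labels
        matched = float(np.mean(per_seq == joint))
        assert matched >= 0.90


class TestNoiseRobustness:
    def test_degradation_monotone_in_snr(self):
        prof, _ = trapezoid_profile(50.0, 0.8, 1.6, 0.9, lead_s=0.5, tail_s=0.5)
        table = noise_robustness(prof, [25, 20, 15, 10, 5], n_reps=20, seed=3)
        fracs = [table[s] for s in (25, 20, 15, 10, 5)]
        violations = [max(0.0, fracs[i + 1] - fracs[i]) for i in range(4)]
        assert sum(v > 0 for v in violations) <= 2
        assert all(v <= 0.01 for v in violations)

    def test_noiseless_identity(self):
        prof, _ = trapezoid_profile(50.0, 0.8, 1.6, 0.9, lead_s=0.5, tail_s=0.5)
        table = noise_robustness(prof, [np.inf], n_reps=2, seed=0)
        assert table[np.inf] == 1.0
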