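"""End-to-end glue: AU sequence -> smile events -> feature sets.

The reference route estimates smile intensity with a trained frame
classifier; when none is available, a proxy intensity — the mean of the
smile-defining channels AU6 (cheek raiser) and AU12 (lip corner puller)
— is used instead.  Phase detection only relies on relative changes and
slope signs, so any monotone intensity surrogate yields the same events.

A sequence in which no smile is detected is handled with a fallback
event spanning the whole sequence (apex = the whole extent), flagged so
callers can tell detection-based features from fallback ones.
"""

from __future__ import annotations

import numpy as np

from .features import DEFAULT_OMEGA_SET, extract_feature_set
from .phase_detection import detect_phases
from .smile_intensity import FrameClassifier, score_sequence
from .types import AUSequence, FeatureSet, IntensitySeries, PhaseTrack, SmileEvent


def smile_intensity_proxy(seq: AUSequence) -> IntensitySeries:
    """Mean of AU6 and AU12 as a frame-wise smile-intensity surrogate."""
    values = 0.5 * (seq.channel("AU06") + seq.channel("AU12"))
    return IntensitySeries(values=values, timestamps=seq.timestamp, fps=seq.fps)


def fallback_event(n_frames: int) -> SmileEvent:
    """Whole-sequence event with apex covering (almost) the whole extent."""
    if n_frames < 4:
        raise ValueError("sequence too short for a fallback event")
    return SmileEvent(t_on=0, t_ap=1, t_off=n_frames - 1, t_end=n_frames)


def detect_events(
    seq: AUSequence, clf: FrameClassifier | None = None
) -> tuple[PhaseTrack, bool]:
    """Phase track for a sequence; returns (track, used_fallback)."""
    intensity = score_sequence(clf, seq) if clf is not None else smile_intensity_proxy(seq)
    track = detect_phases(intensity)
    if track.events:
        return track, False
    ev = fallback_event(len(seq))
    return PhaseTrack.from_events(len(seq), [ev]), True


def sequence_feature_set(
    seq: AUSequence,
    clf: FrameClassifier | None = None,
    omega_set: tuple[int, ...] = DEFAULT_OMEGA_SET,
) -> tuple[FeatureSet, bool]:
    """FeatureSet for a sequence's principal (longest) smile event."""
    track, fallback = detect_events(seq, clf)
    event = max(track.events, key=lambda ev: ev.n_frames)
    return extract_feature_set(seq, event, omega_set), fallback


def dataset_feature_sets(
    sequences: list[AUSequence],
    clf: FrameClassifier | None = None,
    omega_set: tuple[int, ...] = DEFAULT_OMEGA_SET,
) -> tuple[list[FeatureSet], np.ndarray]:
    """Per-sequence feature sets; returns (feature_sets, fallback mask)."""
    out, fb = [], []
    for seq in sequences:
        fs, fallback = sequence_feature_set(seq, clf, omega_set)
        out.append(fs)
        fb.append(fallback)
    return out, np.asarray(fb, dtype=bool)
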