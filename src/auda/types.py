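"""Shared domain containers for the AU-dynamics pipeline.

The pipeline works on per-frame facial action-unit (AU) intensities.  The
canonical channel set is the 17 AUs emitted by OpenFace-style detectors
(AU1, AU2, AU4, AU5, AU6, AU7, AU9, AU10, AU12, AU14, AU15, AU17, AU20,
AU23, AU25, AU26, AU45), each normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical AU channel order used everywhere in the package.
CANONICAL_AU_NAMES: tuple[str, ...] = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
)

N_AU = len(CANONICAL_AU_NAMES)  # 17

#: Per-frame smile phase labels.
PHASE_LABELS: tuple[str, ...] = ("none", "onset", "apex", "offset")


@dataclass
class AUSequence:
    """Per-frame AU intensities for one video sequence.

    Attributes
    ----------
    frame_index : (n,) int array
    timestamp : (n,) float array, seconds, strictly increasing
    fps : float, frames per second
    au_intensity : (n, 17) float array, normalized intensities in [0, 1]
    au_names : channel labels, canonical order
    """

    frame_index: np.ndarray
    timestamp: np.ndarray
    fps: float
    au_intensity: np.ndarray
    au_names: tuple[str, ...] = CANONICAL_AU_NAMES

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.timestamp = np.asarray(self.timestamp, dtype=float)
        self.au_intensity = np.asarray(self.au_intensity, dtype=float)
        self.au_names = tuple(self.au_names)
        if self.au_intensity.ndim != 2 or self.au_intensity.shape[1] != len(self.au_names):
            raise ValueError(
                f"au_intensity must be (n_frames, {len(self.au_names)}), "
                f"got {self.au_intensity.shape}"
            )
        if len(self.au_names) != N_AU:
            raise ValueError(f"expected {N_AU} AU channels, got {len(self.au_names)}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.timestamp) > 1 and not np.all(np.diff(self.timestamp) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.au_intensity.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one AU channel by name (e.g. ``"AU12"``)."""
        try:
            j = self.au_names.index(name)
        except ValueError:
            raise KeyError(f"unknown AU channel {name!r}") from None
        return self.au_intensity[:, j]

    def reordered(self, names: tuple[str, ...]) -> "AUSequence":
        """Return a copy with channels permuted into ``names`` order."""
        idx = [self.au_names.index(n) for n in names]
        return AUSequence(
            frame_index=self.frame_index,
            timestamp=self.timestamp,
            fps=self.fps,
            au_intensity=self.au_intensity[:, idx],
            au_names=names,
        )


@dataclass
class IntensitySeries:
    """A single per-frame intensity signal with its time base.

    Smile intensity lives in [-1, 1] (0 = smile/non-smile boundary);
    AU intensities live in [0, 1].
    """

    values: np.ndarray
    timestamps: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValueError("values and timestamps must have equal length")
        if len(self.values) < 1:
            raise ValueError("series must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DynamicsSeries:
    """First- and second-order dynamics of an intensity signal.

    slope (delta) is the sliding-window regression slope in intensity/s;
    reg_coef (r) the in-window correlation; r_adjusted = slope * |r|;
    second_order the windowed slope of slope, in intensity/s^2.
    """

    omega: int
    slope: np.ndarray
    reg_coef: np.ndarray
    r_adjusted: np.ndarray
    second_order: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.slope)


@dataclass(frozen=True)
class SmileEvent:
    """One detected smile: half-open frame ranges in 0-based indices.

    onset = [t_on, t_ap), apex = [t_ap, t_off), offset = [t_off, t_end).
    """

    t_on: int
    t_ap: int
    t_off: int
    t_end: int

    def __post_init__(self) -> None:
        if not (self.t_on < self.t_ap <= self.t_off < self.t_end):
            raise ValueError(
                f"invalid event boundaries: t_on={self.t_on} t_ap={self.t_ap} "
                f"t_off={self.t_off} t_end={self.t_end}"
            )

    @property
    def n_frames(self) -> int:
        return self.t_end - self.t_on

    def duration(self, fps: float) -> float:
        return self.n_frames / fps

    def phase_range(self, phase: str) -> tuple[int, int]:
        if phase == "whole":
            return self.t_on, self.t_end
        if phase == "onset":
            return self.t_on, self.t_ap
        if phase == "apex":
            return self.t_ap, self.t_off
        if phase == "offset":
            return self.t_off, self.t_end
        raise ValueError(f"unknown phase {phase!r}")


@dataclass
class PhaseTrack:
    """Per-frame phase labels plus the list of detected events."""

    labels: np.ndarray  # array of str in PHASE_LABELS
    events: list[SmileEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(PHASE_LABELS)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_events(cls, n_frames: int, events: list[SmileEvent]) -> "PhaseTrack":
        labels = np.array(["none"] * n_frames, dtype=object)
        for ev in events:
            labels[ev.t_on:ev.t_ap] = "onset"
            labels[ev.t_ap:ev.t_off] = "apex"
            labels[ev.t_off:ev.t_end] = "offset"
        return cls(labels=labels, events=list(events))


#: FeatureSet slot names: {AU-wise, cross-AU} x {whole, onset, apex, offset}.
SLOT_RANGES: tuple[str, ...] = ("whole", "onset", "apex", "offset")
SLOT_NAMES: tuple[str, ...] = tuple(
    f"{kind}.{rng}" for kind in ("auwise", "crossau") for rng in SLOT_RANGES
)


@dataclass
class FeatureSet:
    """The eight named feature vectors describing one smile event.

    ``slots`` maps a slot name (e.g. ``"auwise.onset"``) to a
    (feature_names, values) pair; ``omega_set`` holds the reference-rate
    window lengths (e.g. (9, 27)); ``flags`` records slots computed on a
    minimally extended range because the phase was degenerate.
    """

    slots: dict[str, tuple[tuple[str, ...], np.ndarray]]
    omega_set: tuple[int, ...]
    fps: float
    flags: tuple[str, ...] = ()

    def vector(self, slot: str) -> np.ndarray:
        return self.slots[slot][1]

    def names(self, slot: str) -> tuple[str, ...]:
        return self.slots[slot][0]
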