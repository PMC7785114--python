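"""Tabular I/O for the pipeline's CSV formats.

Supported formats (all comma-separated, '.' decimal, header required):

* OpenFace-style AU tables — one row per frame with a ``timestamp``
  column and the 17 regression-intensity columns ``AU01_r`` ... ``AU45_r``
  on the detector's 0-5 scale (header whitespace is tolerated, OpenFace
  pads its headers with spaces).  Intensities are normalized to [0, 1]
  by dividing by 5 and clipping.
* Intensity-series CSV — ``frame``/``value`` (plus optional
  ``timestamp``) columns for a single signal.
* Feature tables — one row per smile event with slot-qualified feature
  columns, a ``label`` column, and ``#``-prefixed header metadata
  (format version, window set, fps, slot names); numeric payload
  round-trips bit-exactly.
* Phase tracks — ``frame,timestamp,phase,event_id`` per frame.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_AU_NAMES,
    PHASE_LABELS,
    SLOT_NAMES,
    AUSequence,
    FeatureSet,
    IntensitySeries,
    PhaseTrack,
    SmileEvent,
)

logger = logging.getLogger("auda")

OPENFACE_AU_COLUMNS = tuple(f"{au}_r" for au in CANONICAL_AU_NAMES)
OPENFACE_RAW_MAX = 5.0
FEATURE_TABLE_VERSION = 1


class FormatError(ValueError):
    """Malformed file: wrong columns, labels or header version."""


class DataError(ValueError):
    """Well-formed file with invalid data (empty, non-monotone time...)."""


def _infer_fps(timestamps: np.ndarray) -> float:
    diffs = np.diff(timestamps)
    if len(diffs) == 0:
        raise DataError("cannot infer fps from a single frame; pass fps explicitly")
    return float(1.0 / np.median(diffs))


def read_openface_csv(
    path: str | Path,
    fps_override: float | None = None,
    normalized: bool = False,
) -> AUSequence:
    """Read an OpenFace-style AU intensity table.

    Raw 0-5 intensities are divided by 5 and clipped to [0, 1] (out-of-
    range values are clipped with a logged warning count); pass
    ``normalized=True`` for tables already on the [0, 1] scale.  fps is
    the reciprocal median timestamp spacing unless overridden.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file") from None
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    df.columns = [c.strip() for c in df.columns]
    for col in OPENFACE_AU_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing AU intensity column {col!r}")
    if "timestamp" not in df.columns:
        raise FormatError(f"{path}: missing 'timestamp' column")
    timestamps = df["timestamp"].to_numpy(dtype=float)
    if len(timestamps) > 1 and not np.all(np.diff(timestamps) > 0):
        raise DataError(f"{path}: timestamps are not strictly increasing")
    raw = df[list(OPENFACE_AU_COLUMNS)].to_numpy(dtype=float)
    if not normalized:
        n_out = int(np.sum((raw < 0) | (raw > OPENFACE_RAW_MAX)))
        if n_out:
            logger.warning("%s: clipped %d out-of-range AU values", path, n_out)
        intensity = np.clip(raw / OPENFACE_RAW_MAX, 0.0, 1.0)
    else:
        intensity = np.clip(raw, 0.0, 1.0)
    fps = float(fps_override) if fps_override else _infer_fps(timestamps)
    frames = (
        df["frame"].to_numpy(dtype=int) if "frame" in df.columns else np.arange(len(df))
    )
    return AUSequence(
        frame_index=frames, timestamp=timestamps, fps=fps, au_intensity=intensity
    )


def write_openface_csv(seq: AUSequence, path: str | Path) -> None:
    """Write an AUSequence back onto the OpenFace 0-5 scale."""
    df = pd.DataFrame({"frame": seq.frame_index, "timestamp": seq.timestamp})
    for j, col in enumerate(OPENFACE_AU_COLUMNS):
        df[col] = seq.au_intensity[:, j] * OPENFACE_RAW_MAX
    df.to_csv(path, index=False)


def read_intensity_csv(
    path: str | Path, fps_override: float | None = None
) -> IntensitySeries:
    """Read a two-column frame/value series (optional timestamp column)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file") from None
    df.columns = [c.strip() for c in df.columns]
    if "value" not in df.columns:
        raise FormatError(f"{path}: missing 'value' column")
    values = df["value"].to_numpy(dtype=float)
    if "timestamp" in df.columns:
        timestamps = df["timestamp"].to_numpy(dtype=float)
        fps = float(fps_override) if fps_override else _infer_fps(timestamps)
    else:
        if not fps_override:
            raise DataError(f"{path}: no timestamp column; fps must be given")
        fps = float(fps_override)
        timestamps = np.arange(len(values)) / fps
    return IntensitySeries(values=values, timestamps=timestamps, fps=fps)


def write_intensity_csv(series: IntensitySeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(series)),
            "timestamp": series.timestamps,
            "value": series.values,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_feature_table(
    feature_sets: list[FeatureSet],
    labels: np.ndarray | list | None,
    path: str | Path,
) -> None:
    """Write feature sets (one row per event) with header metadata.

    The numeric payload survives a round trip bit-exactly (17 significant
    digits).  ``labels`` may be None for unlabeled tables.
    """
    if not feature_sets:
        raise DataError("cannot write an empty feature table")
    ref = feature_sets[0]
    for fs in feature_sets:
        for slot in ref.slots:
            if fs.names(slot) != ref.names(slot):
                raise DataError(f"inconsistent feature names/dimensionality in slot {slot!r}")
    columns: list[str] = []
    for slot in SLOT_NAMES:
        columns.extend(ref.names(slot))
    rows = np.vstack(
        [np.concatenate([fs.vector(slot) for slot in SLOT_NAMES]) for fs in feature_sets]
    )
    df = pd.DataFrame(rows, columns=columns)
    if labels is not None:
        df.insert(0, "label", np.asarray(labels))
    header = (
        f"# auda-feature-table v{FEATURE_TABLE_VERSION}\n"
        f"# omega_set={','.join(str(w) for w in ref.omega_set)}\n"
        f"# fps={ref.fps!r}\n"
        f"# slots={';'.join(SLOT_NAMES)}\n"
    )
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(header + buf.getvalue())


def read_feature_table(
    path: str | Path,
) -> tuple[list[FeatureSet], np.ndarray | None]:
    """Read a feature table written by :func:`write_feature_table`."""
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    lines = text.splitlines()
    n_meta = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_meta += 1
        body = line[1:].strip()
        if body.startswith("auda-feature-table"):
            version = body.split("v")[-1]
            if version != str(FEATURE_TABLE_VERSION):
                raise FormatError(f"{path}: unknown feature-table version {version!r}")
            meta["version"] = version
        elif "=" in body:
            key, val = body.split("=", 1)
            meta[key] = val
    if "version" not in meta:
        raise FormatError(f"{path}: not an auda feature table (missing version header)")
    omega_set = tuple(int(w) for w in meta["omega_set"].split(","))
    fps = float(meta["fps"])
    df = pd.read_csv(
        io.StringIO("\n".join(lines[n_meta:])), float_precision="round_trip"
    )
    labels = df.pop("label").to_numpy() if "label" in df.columns else None
    slot_cols: dict[str, list[str]] = {slot: [] for slot in SLOT_NAMES}
    for col in df.columns:
        slot = ".".join(col.split(".")[:2])
        if slot not in slot_cols:
            raise FormatError(f"{path}: column {col!r} belongs to no known slot")
        slot_cols[slot].append(col)
    feature_sets = []
    for _, row in df.iterrows():
        slots = {
            slot: (tuple(cols), row[cols].to_numpy(dtype=float))
            for slot, cols in slot_cols.items()
        }
        feature_sets.append(
            FeatureSet(slots=slots, omega_set=omega_set, fps=fps)
        )
    return feature_sets, labels


def write_phase_track(
    track: PhaseTrack, path: str | Path, fps: float = 50.0
) -> None:
    """One row per frame: frame, timestamp, phase, event_id (-1 = none)."""
    n = len(track)
    event_id = np.full(n, -1, dtype=int)
    for k, ev in enumerate(track.events):
        event_id[ev.t_on : ev.t_end] = k
    pd.DataFrame(
        {
            "frame": np.arange(n),
            "timestamp": np.arange(n) / fps,
            "phase": track.labels,
            "event_id": event_id,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_phase_track(path: str | Path) -> PhaseTrack:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    labels = df["phase"].to_numpy(dtype=object)
    bad = set(labels) - set(PHASE_LABELS)
    if bad:
        raise FormatError(f"{path}: unknown phase labels {sorted(bad)}")
    events: list[SmileEvent] = []
    event_id = df["event_id"].to_numpy(dtype=int)
    for k in sorted(set(event_id[event_id >= 0])):
        frames = np.flatnonzero(event_id == k)
        t_on, t_end = int(frames[0]), int(frames[-1]) + 1
        in_ev = labels[t_on:t_end]
        ap_rel = np.flatnonzero(in_ev == "apex")
        off_rel = np.flatnonzero(in_ev == "offset")
        t_off = t_on + int(off_rel[0]) if len(off_rel) else t_end - 1
        t_ap = t_on + int(ap_rel[0]) if len(ap_rel) else t_off
        events.append(SmileEvent(t_on=t_on, t_ap=t_ap, t_off=t_off, t_end=t_end))
    return PhaseTrack(labels=labels, events=events)


def write_labels_csv(labels: np.ndarray, subjects: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"sequence": np.arange(len(labels)), "label": labels,
                  "subject": subjects}).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    subjects = df["subject"].to_numpy() if "subject" in df.columns else None
    return df["label"].to_numpy(), subjects
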