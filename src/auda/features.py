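"""AU-wise and cross-AU feature extraction from smile events.

For every detected smile, features are extracted from four time ranges —
the whole event and its onset, apex and offset phases — giving eight
feature vectors (AU-wise x 4 ranges, cross-AU x 4 ranges).

AU-wise features describe each of the 17 AU channels independently:
signal amplitude v_a = v_max - v_min, mean and maximum of the raw
intensity, plus mean and maximum of the first-order dynamics at each
window scale.  For scales Omega = {9, 27} that is 17 * (3 + 2*2) = 119
features per range.

Cross-AU features capture mutual relations between AU pairs through the
dynamics difference signal dd = |delta_x - delta_y|: its minimum and
maximum within the range, plus the temporal distances between the two
channels' r-adjusted-slope extrema (|argmax - argmax| and
|argmin - argmin|, in seconds).  That is 4 features per pair per scale:
136 pairs * 4 = 544 per scale.

Dynamics are computed once on the full sequence and then restricted to
each range, avoiding boundary-replication artifacts at phase borders.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .dynamics import effective_window, first_order_dynamics
from .types import (
    SLOT_RANGES,
    AUSequence,
    FeatureSet,
    IntensitySeries,
    SmileEvent,
)

DEFAULT_OMEGA_SET = (9, 27)

AU_WISE_KINDS = ("amplitude", "mean", "max")
AU_WISE_DYN_KINDS = ("delta_mean", "delta_max")
CROSS_AU_KINDS = ("ddelta_min", "ddelta_max", "dt_rdelta_max", "dt_rdelta_min")


def _check_range(rng: tuple[int, int], n: int) -> tuple[int, int]:
    lo, hi = int(rng[0]), int(rng[1])
    if not (0 <= lo < hi <= n) or hi - lo < 2:
        raise ValueError(f"invalid frame range [{lo}, {hi}) for sequence of {n} frames")
    return lo, hi


def _channel_dynamics(seq: AUSequence, omega_set: tuple[int, ...]) -> dict:
    """Per-scale (17, n) slope and r-adjusted-slope matrices.

    Keys are the reference-rate omega values; windows are fps-adjusted.
    """
    out = {}
    for omega_ref in omega_set:
        omega = effective_window(omega_ref, seq.fps)
        slopes = np.empty((len(seq.au_names), len(seq)))
        radj = np.empty_like(slopes)
        for j in range(len(seq.au_names)):
            series = IntensitySeries(
                values=seq.au_intensity[:, j], timestamps=seq.timestamp, fps=seq.fps
            )
            dyn = first_order_dynamics(series, omega)
            slopes[j] = dyn.slope
            radj[j] = dyn.r_adjusted
        out[omega_ref] = (slopes, radj)
    return out


def au_wise_features(
    seq: AUSequence,
    frame_range: tuple[int, int],
    omega_set: tuple[int, ...] = DEFAULT_OMEGA_SET,
    _dyn_cache: dict | None = None,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Per-channel statistics of intensity and first-order dynamics.

    Returns (names, values); 17 * (3 + 2 * len(omega_set)) features.
    """
    lo, hi = _check_range(frame_range, len(seq))
    dyn = _dyn_cache if _dyn_cache is not None else _channel_dynamics(seq, omega_set)
    names: list[str] = []
    values: list[float] = []
    for j, au in enumerate(seq.au_names):
        v = seq.au_intensity[lo:hi, j]
        names += [f"{au}.amplitude", f"{au}.mean", f"{au}.max"]
        values += [float(v.max() - v.min()), float(v.mean()), float(v.max())]
        for omega_ref in omega_set:
            d = dyn[omega_ref][0][j, lo:hi]
            names += [f"{au}.delta_mean.w{omega_ref}", f"{au}.delta_max.w{omega_ref}"]
            values += [float(d.mean()), float(d.max())]
    return tuple(names), np.asarray(values)


def dynamics_difference(delta_x: np.ndarray, delta_y: np.ndarray) -> np.ndarray:
    """Absolute slope difference |delta_x - delta_y| per frame."""
    delta_x = np.asarray(delta_x, dtype=float)
    delta_y = np.asarray(delta_y, dtype=float)
    if delta_x.shape != delta_y.shape:
        raise ValueError("dynamics series must have equal length")
    return np.abs(delta_x - delta_y)


def cross_au_features(
    seq: AUSequence,
    frame_range: tuple[int, int],
    omega_set: tuple[int, ...] = DEFAULT_OMEGA_SET,
    _dyn_cache: dict | None = None,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise dynamics-relation features.

    For each of the 136 unordered AU pairs and each scale: min and max of
    the dynamics difference signal, and the temporal distances (seconds)
    between the r-adjusted-slope maxima and minima of the two channels
    (argmax/argmin ties broken toward the earliest frame).
    """
    lo, hi = _check_range(frame_range, len(seq))
    dyn = _dyn_cache if _dyn_cache is not None else _channel_dynamics(seq, omega_set)
    pairs = list(combinations(range(len(seq.au_names)), 2))
    names: list[str] = []
    values: list[float] = []
    for omega_ref in omega_set:
        slopes, radj = dyn[omega_ref]
        d = slopes[:, lo:hi]
        ra = radj[:, lo:hi]
        t_amax = np.argmax(ra, axis=1)  # earliest frame on ties
        t_amin = np.argmin(ra, axis=1)
        for x, y in pairs:
            pair = f"{seq.au_names[x]}_{seq.au_names[y]}"
            dd = dynamics_difference(d[x], d[y])
            names += [
                f"{pair}.ddelta_min.w{omega_ref}",
                f"{pair}.ddelta_max.w{omega_ref}",
                f"{pair}.dt_rdelta_max.w{omega_ref}",
                f"{pair}.dt_rdelta_min.w{omega_ref}",
            ]
            values += [
                float(dd.min()),
                float(dd.max()),
                float(abs(int(t_amax[x]) - int(t_amax[y])) / seq.fps),
                float(abs(int(t_amin[x]) - int(t_amin[y])) / seq.fps),
            ]
    return tuple(names), np.asarray(values)


def _safe_range(rng: tuple[int, int], n: int) -> tuple[tuple[int, int], bool]:
    """Extend a degenerate (< 2 frame) range to 2 frames within bounds."""
    lo, hi = rng
    if hi - lo >= 2:
        return (lo, hi), False
    hi = min(n, lo + 2)
    lo = max(0, hi - 2)
    return (lo, hi), True


def extract_feature_set(
    seq: AUSequence,
    event: SmileEvent,
    omega_set: tuple[int, ...] = DEFAULT_OMEGA_SET,
) -> FeatureSet:
    """The eight feature vectors for one smile event.

    Slots are named ``{auwise,crossau}.{whole,onset,apex,offset}``; slot
    feature names are slot-qualified and stable across calls.  A phase
    shorter than 2 frames is computed on the minimal 2-frame extension
    and recorded in ``flags``.
    """
    if event.t_end > len(seq):
        raise ValueError("event extends past the end of the sequence")
    # channels are always processed in canonical name order, so permuting
    # the input channel order leaves every named feature unchanged
    order = tuple(sorted(seq.au_names))
    if seq.au_names != order:
        seq = seq.reordered(order)
    dyn = _channel_dynamics(seq, tuple(omega_set))
    slots: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    flags: list[str] = []
    for rng_name in SLOT_RANGES:
        rng, flagged = _safe_range(event.phase_range(rng_name), len(seq))
        for kind, fn in (("auwise", au_wise_features), ("crossau", cross_au_features)):
            slot = f"{kind}.{rng_name}"
            names, vals = fn(seq, rng, tuple(omega_set), _dyn_cache=dyn)
            slots[slot] = (tuple(f"{slot}.{n}" for n in names), vals)
            if flagged and slot not in flags:
                flags.append(slot)
    return FeatureSet(
        slots=slots, omega_set=tuple(omega_set), fps=seq.fps, flags=tuple(flags)
    )


def au_wise_length(n_au: int, n_omega: int) -> int:
    """Expected AU-wise slot length: n_au * (3 + 2 * n_omega)."""
    return n_au * (3 + 2 * n_omega)


def cross_au_length(n_au: int, n_omega: int) -> int:
    """Expected cross-AU slot length: C(n_au, 2) * 4 * n_omega."""
    return n_au * (n_au - 1) // 2 * 4 * n_omega
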