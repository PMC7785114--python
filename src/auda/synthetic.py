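"""Synthetic smile data at every level of the pipeline.

Generates (a) smile-intensity profiles with exact ground-truth phase
breakpoints, (b) 17-channel AU sequences in which each channel is a
gained, lagged, noisy copy of a master smile profile, and (c) labeled
posed/spontaneous datasets with subject IDs.

A smile event is a trapezoid-like profile: a rise (onset), a plateau
(apex) and a fall (offset), with raised-cosine ramps by default (smooth,
with a realistic second-order-dynamics structure) or linear ramps for
analytic tests.  Class effects follow the literature's main observation
that spontaneous smiles have smaller amplitudes and slower onsets, plus a
small temporal lag between the cheek raiser (AU6) and the lip-corner
puller (AU12); the effect sizes are chosen to make the two classes
separable by construction and claim no physiological fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import CANONICAL_AU_NAMES, AUSequence, IntensitySeries

#: Per-AU coupling gain to the master smile profile.  AU6 (cheek raiser)
#: and AU12 (lip corner puller) are the smile-defining channels and get
#: the largest gains; mouth-area AUs follow; the rest are weakly coupled.
DEFAULT_GAINS: dict[str, float] = {
    "AU01": 0.15, "AU02": 0.15, "AU04": 0.10, "AU05": 0.20,
    "AU06": 1.00, "AU07": 0.30, "AU09": 0.10, "AU10": 0.45,
    "AU12": 1.00, "AU14": 0.40, "AU15": 0.15, "AU17": 0.20,
    "AU20": 0.20, "AU23": 0.15, "AU25": 0.50, "AU26": 0.30,
    "AU45": 0.10,
}


@dataclass
class ClassProfile:
    """Event-shape parameters for one smile class (durations in s)."""

    onset_s: float = 0.6
    apex_s: float = 3.0
    offset_s: float = 1.2
    amplitude: float = 0.8
    amplitude_sd: float = 0.05
    duration_sd: float = 0.10  # relative jitter on each phase duration
    au6_au12_lag_frames: int = 0


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults define the study conditions."""

    fps: float = 50.0
    n_sequences: int = 100
    class_balance: float = 0.5
    baseline: float = 0.05
    lead_s: float = 0.2   # baseline padding before the event
    tail_s: float = 0.1   # baseline padding after the event
    noise_sd: float = 0.02  # per-AU independent Gaussian noise
    snr_db: float | None = None  # overrides noise_sd when set
    ramp: str = "cosine"  # "cosine" or "linear"
    sequences_per_subject: int = 2
    subject_effect_sd: float = 0.03  # per-subject baseline shift
    gains: dict[str, float] | None = None  # None -> DEFAULT_GAINS
    lag_jitter: int = 2  # max random per-AU lag, frames
    posed: ClassProfile = field(default_factory=ClassProfile)
    spontaneous: ClassProfile = field(
        default_factory=lambda: ClassProfile(
            onset_s=0.9,            # 1.5x posed onset
            apex_s=3.0,
            offset_s=1.2,
            amplitude=0.56,         # 0.7x posed amplitude
            amplitude_sd=0.05,
            au6_au12_lag_frames=3,  # AU6 lags AU12
        )
    )

    def profile_for(self, label: str) -> ClassProfile:
        if label == "posed":
            return self.posed
        if label == "spontaneous":
            return self.spontaneous
        raise ValueError(f"unknown class {label!r}")


def _ramp(n: int, kind: str) -> np.ndarray:
    """Monotone 0 -> 1 ramp over n frames (value at frame i is the
    fraction completed after i steps; reaches 1 at the final frame)."""
    if n <= 0:
        return np.empty(0)
    x = np.arange(1, n + 1) / n
    if kind == "linear":
        return x
    if kind == "cosine":
        return 0.5 * (1.0 - np.cos(np.pi * x))
    raise ValueError(f"unknown ramp kind {kind!r}")


def trapezoid_profile(
    fps: float,
    onset_s: float,
    apex_s: float,
    offset_s: float,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    lead_s: float = 0.0,
    tail_s: float = 0.0,
    ramp: str = "cosine",
) -> tuple[IntensitySeries, tuple[int, int, int, int]]:
    """Deterministic single-event profile with exact breakpoints.

    Frame counts are floor(duration * fps) per segment.  Returns the
    series and the (t_on, t_ap, t_off, t_end) breakpoints as 0-based
    frame indices with half-open phase ranges.
    """
    # floor with a tiny guard against binary float dust (n/fps * fps != n)
    frames = lambda s: int(s * fps + 1e-9)  # noqa: E731
    n_lead = frames(lead_s)
    n_on = frames(onset_s)
    n_ap = frames(apex_s)
    n_off = frames(offset_s)
    n_tail = frames(tail_s)
    if min(n_on, n_ap, n_off) < 1:
        raise ValueError("each phase must span at least one frame")
    values = np.concatenate(
        [
            np.full(n_lead, 0.0),
            _ramp(n_on, ramp),
            np.full(n_ap, 1.0),
            1.0 - _ramp(n_off, ramp),
            np.full(n_tail, 0.0),
        ]
    )
    values = baseline + amplitude * values
    t_on = n_lead
    t_ap = n_lead + n_on
    t_off = t_ap + n_ap
    t_end = t_off + n_off
    timestamps = np.arange(len(values)) / fps
    return (
        IntensitySeries(values=values, timestamps=timestamps, fps=fps),
        (t_on, t_ap, t_off, t_end),
    )


def generate_profile(
    cfg: SyntheticConfig, label: str, seed: int
) -> tuple[IntensitySeries, tuple[int, int, int, int]]:
    """Sample one class-conditional smile profile with ground truth.

    Phase durations and amplitude are jittered around the class defaults;
    total event duration stays >= 1 s by construction.
    """
    rng = np.random.default_rng(seed)
    prof = cfg.profile_for(label)
    jitter = lambda x: float(x * rng.normal(1.0, prof.duration_sd))  # noqa: E731
    onset_s = max(0.2, jitter(prof.onset_s))
    apex_s = max(0.4, jitter(prof.apex_s))
    offset_s = max(0.2, jitter(prof.offset_s))
    amplitude = max(0.2, float(rng.normal(prof.amplitude, prof.amplitude_sd)))
    return trapezoid_profile(
        fps=cfg.fps,
        onset_s=onset_s,
        apex_s=apex_s,
        offset_s=offset_s,
        amplitude=amplitude,
        baseline=cfg.baseline,
        lead_s=cfg.lead_s,
        tail_s=cfg.tail_s,
        ramp=cfg.ramp,
    )


def _shift(values: np.ndarray, lag: int, fill: float) -> np.ndarray:
    """Delay a signal by ``lag`` frames (negative = advance)."""
    if lag == 0:
        return values
    out = np.full_like(values, fill)
    if lag > 0:
        out[lag:] = values[:-lag]
    else:
        out[:lag] = values[-lag:]
    return out


def generate_au_sequence(
    cfg: SyntheticConfig,
    label: str,
    seed: int,
    baseline_shift: float = 0.0,
) -> AUSequence:
    """One 17-channel AU sequence coupled to a master smile profile.

    Each channel is gain * profile(t - lag) + baseline + noise, clipped
    to [0, 1].  For the spontaneous class AU6 lags AU12 by the configured
    number of frames; other channels receive small random lags.
    """
    rng = np.random.default_rng(seed)
    prof_series, _ = generate_profile(cfg, label, seed=int(rng.integers(2**31)))
    master = (prof_series.values - cfg.baseline)  # 0-based profile, peak ~ amplitude
    n = len(master)
    cls = cfg.profile_for(label)
    gains = DEFAULT_GAINS if cfg.gains is None else cfg.gains
    jit = cfg.lag_jitter
    mat = np.empty((n, len(CANONICAL_AU_NAMES)))
    for j, au in enumerate(CANONICAL_AU_NAMES):
        if au == "AU06":
            lag = cls.au6_au12_lag_frames
        elif au == "AU12":
            lag = 0
        else:
            lag = int(rng.integers(-jit, jit + 1)) if jit else 0
        chan = gains[au] * _shift(master, lag, 0.0) + cfg.baseline + baseline_shift
        mat[:, j] = chan
    if cfg.snr_db is not None:
        var_signal = float(np.var(mat - mat.mean(axis=0), axis=0).mean())
        sd = np.sqrt(var_signal / 10 ** (cfg.snr_db / 10))
    else:
        sd = cfg.noise_sd
    if sd > 0:
        mat = mat + rng.normal(0.0, sd, size=mat.shape)
    mat = np.clip(mat, 0.0, 1.0)
    return AUSequence(
        frame_index=np.arange(n),
        timestamp=prof_series.timestamps,
        fps=cfg.fps,
        au_intensity=mat,
    )


def generate_dataset(
    cfg: SyntheticConfig | None = None, seed: int = 0
) -> tuple[list[AUSequence], np.ndarray, np.ndarray]:
    """A labeled, subject-structured dataset of AU sequences.

    Returns (sequences, labels, subject_ids); labels are 0 = posed,
    1 = spontaneous, balanced per ``class_balance``.  Subjects contribute
    ``sequences_per_subject`` sequences each and carry a small random
    baseline shift, so subject-disjoint folding is meaningful.
    """
    cfg = cfg or SyntheticConfig()
    if cfg.n_sequences < 2:
        raise ValueError("n_sequences must be >= 2")
    rng = np.random.default_rng(seed)
    n_spont = int(round(cfg.class_balance * cfg.n_sequences))
    labels = np.array([1] * n_spont + [0] * (cfg.n_sequences - n_spont))
    rng.shuffle(labels)
    subjects = np.arange(cfg.n_sequences) // cfg.sequences_per_subject
    shifts = rng.normal(0.0, cfg.subject_effect_sd, size=int(subjects.max()) + 1)
    sequences = [
        generate_au_sequence(
            cfg,
            "spontaneous" if lab == 1 else "posed",
            seed=int(rng.integers(2**31)),
            baseline_shift=float(shifts[subjects[i]]),
        )
        for i, lab in enumerate(labels)
    ]
    return sequences, labels, subjects


def inject_noise(v: IntensitySeries, snr_db: float, seed: int) -> IntensitySeries:
    """Additive zero-mean Gaussian noise at a target signal-to-noise ratio.

    Noise variance = var(v) / 10^(snr_db / 10), with var taken on the
    mean-removed clean signal.  ``snr_db = inf`` returns the input
    unchanged.
    """
    if np.isinf(snr_db):
        return v
    var_signal = float(np.var(v.values))
    if var_signal == 0:
        raise ValueError("cannot set an SNR for a constant signal")
    sd = np.sqrt(var_signal / 10 ** (snr_db / 10))
    rng = np.random.default_rng(seed)
    return replace(v, values=v.values + rng.normal(0.0, sd, size=len(v)))
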