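"""Frame-wise smile intensity from AU vectors.

A binary margin classifier (RBF-kernel SVM) is trained on frames labeled
smile / non-smile over the 17 AU intensities.  The signed distance from
its separating hyperplane is taken as the smile intensity, rescaled into
[-1, 1] with 0 exactly on the decision boundary.  Class imbalance is
handled by class-weighted training, optionally with seeded random
undersampling of the majority class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import N_AU, AUSequence, IntensitySeries

#: Raw margins are rescaled by this percentile of |margin| on the training
#: frames (percentile rather than max, for outlier robustness).
SCALE_PERCENTILE = 99.0

C_GRID = (0.1, 1.0, 10.0, 100.0)
GAMMA_GRID = (0.01, 0.1, 1.0)


@dataclass
class FrameClassifier:
    """Standardizer + margin classifier + margin-to-[-1,1] scale factor."""

    scaler: StandardScaler
    svm: SVC
    scale_factor: float

    def raw_margin(self, frames: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(self.scaler.transform(frames))

    def score_frames(self, frames: np.ndarray) -> np.ndarray:
        """Scaled smile intensity per frame, clipped to [-1, 1]."""
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 2 or frames.shape[1] != N_AU:
            raise ValueError(f"expected (n, {N_AU}) AU frames, got {frames.shape}")
        return np.clip(self.raw_margin(frames) / self.scale_factor, -1.0, 1.0)


def train_frame_classifier(
    frames: np.ndarray,
    labels: np.ndarray,
    seed: int,
    undersample: bool = False,
) -> FrameClassifier:
    """Fit the smile / non-smile frame classifier.

    Parameters
    ----------
    frames : (n, 17) array of normalized AU intensities.
    labels : (n,) binary array (1 = smile).
    seed : RNG seed for the validation split, grid search and optional
        undersampling; results are deterministic given the seed.
    undersample : randomly downsample the majority class to the minority
        size before training (in addition to class weighting).
    """
    frames = np.asarray(frames, dtype=float)
    labels = np.asarray(labels).astype(int)
    if frames.ndim != 2 or frames.shape[1] != N_AU:
        raise ValueError(f"expected (n, {N_AU}) AU frames, got {frames.shape}")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both smile and non-smile frames are required for training")
    if len(frames) < 10:
        raise ValueError("at least 10 labeled frames are required")

    if undersample:
        rng = np.random.default_rng(seed)
        counts = {c: int(np.sum(labels == c)) for c in classes}
        n_min = min(counts.values())
        keep = np.concatenate(
            [
                rng.choice(np.flatnonzero(labels == c), size=n_min, replace=False)
                for c in classes
            ]
        )
        keep.sort()
        frames, labels = frames[keep], labels[keep]

    x_tr, x_val, y_tr, y_val = train_test_split(
        frames, labels, test_size=0.2, random_state=seed, stratify=labels
    )
    scaler = StandardScaler().fit(x_tr)
    best = None
    for c in C_GRID:
        for gamma in GAMMA_GRID:
            svm = SVC(C=c, gamma=gamma, kernel="rbf", class_weight="balanced")
            svm.fit(scaler.transform(x_tr), y_tr)
            acc = svm.score(scaler.transform(x_val), y_val)
            if best is None or acc > best[0]:
                best = (acc, c, gamma)
    _, c, gamma = best
    scaler = StandardScaler().fit(frames)
    svm = SVC(C=c, gamma=gamma, kernel="rbf", class_weight="balanced")
    svm.fit(scaler.transform(frames), labels)
    margins = np.abs(svm.decision_function(scaler.transform(frames)))
    scale = float(np.percentile(margins, SCALE_PERCENTILE))
    if scale <= 0:
        scale = 1.0
    return FrameClassifier(scaler=scaler, svm=svm, scale_factor=scale)


def score_sequence(clf: FrameClassifier, seq: AUSequence) -> IntensitySeries:
    """Smile-intensity series for an AU sequence (one value per frame)."""
    values = clf.score_frames(seq.au_intensity)
    return IntensitySeries(values=values, timestamps=seq.timestamp, fps=seq.fps)
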