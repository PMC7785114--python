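"""Two-level SVM ensemble for posed vs. spontaneous smile classification.

Each of the eight feature vectors of a smile event is standardized and
classified by its own first-level RBF-kernel SVM (hyperparameters from an
internal grid search; optional recursive feature elimination).  The eight
signed decision values — distances from the separating hyperplanes — form
a second-level feature vector classified by a polynomial-kernel SVM,
which produces the final posed/spontaneous decision.

Second-level training inputs are obtained by internal 5-fold
cross-fitting on the training set rather than by resubstitution, so the
stacker never sees optimistically large margins.

Evaluation follows a subject-disjoint k-fold protocol: when subject IDs
are supplied, folds are built so no subject appears in both the training
and the test side.  Accuracy (%) and the area under the ROC curve are
reported per fold and aggregated as mean +/- standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import SLOT_NAMES, FeatureSet

LABEL_POSED = 0
LABEL_SPONTANEOUS = 1

C_GRID = (0.1, 1.0, 10.0, 100.0)
GAMMA_REL_GRID = (0.1, 1.0, 10.0)  # multiples of 1 / n_features
POLY_DEGREE = 3
RFE_BATCH_FRACTION = 0.05
N_CROSSFIT_FOLDS = 5


@dataclass
class EnsembleConfig:
    omega_set: tuple[int, ...] = (9, 27)
    rfe: bool = False
    validation_fraction: float = 0.2
    slots: tuple[str, ...] = SLOT_NAMES


@dataclass
class SlotModel:
    scaler: StandardScaler
    mask: np.ndarray  # boolean feature mask (RFE outcome; all-true if disabled)
    svm: SVC

    def decision(self, x: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(self.scaler.transform(x)[:, self.mask])


@dataclass
class TrainedEnsemble:
    slot_models: dict[str, SlotModel]
    second_level: SVC
    config: EnsembleConfig
    seed: int
    fps: float
    slot_dims: dict[str, int] = field(default_factory=dict)


def standardize_fit(train: np.ndarray) -> StandardScaler:
    """Per-feature standardizer; zero-variance features pass through."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    return StandardScaler().fit(train)


def standardize_apply(scaler: StandardScaler, x: np.ndarray) -> np.ndarray:
    return scaler.transform(np.atleast_2d(np.asarray(x, dtype=float)))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(random positive outranks random
    negative), ties counted one half."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _grid_search_rbf(
    x_tr: np.ndarray, y_tr: np.ndarray, x_val: np.ndarray, y_val: np.ndarray
) -> tuple[float, float]:
    """Best (C, gamma) by validation accuracy over a small grid."""
    d = x_tr.shape[1]
    best = None
    for c in C_GRID:
        for g_rel in GAMMA_REL_GRID:
            gamma = g_rel / d
            svm = SVC(C=c, gamma=gamma, kernel="rbf")
            svm.fit(x_tr, y_tr)
            acc = svm.score(x_val, y_val)
            if best is None or acc > best[0]:
                best = (acc, c, gamma)
    return best[1], best[2]


def rfe_select(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    seed: int,
    svm_params: dict | None = None,
) -> np.ndarray:
    """Recursive feature elimination with validation-accuracy stopping.

    Feature importance is assessed by leave-one-feature-out: each
    remaining feature is excluded in turn and the model retrained; the
    smaller the validation-accuracy drop, the less important the feature.
    Per round, the least important batch (max(1, 5% of remaining)) is
    removed; the round is accepted iff validation accuracy does not
    decrease (ties accepted).  Stops at the first rejected round or when
    one feature remains.  Returns a boolean mask over the features.
    """
    train_x = np.asarray(train_x, dtype=float)
    val_x = np.asarray(val_x, dtype=float)
    train_y = np.asarray(train_y).astype(int)
    val_y = np.asarray(val_y).astype(int)
    n_feat = train_x.shape[1]
    mask = np.ones(n_feat, dtype=bool)
    if len(np.unique(val_y)) < 2 or len(val_y) < 2:
        warnings.warn("degenerate validation set; RFE skipped", stacklevel=2)
        return mask
    params = svm_params or {"C": 1.0, "gamma": "scale", "kernel": "rbf"}

    def fit_acc(cols: np.ndarray) -> float:
        svm = SVC(**params)
        svm.fit(train_x[:, cols], train_y)
        return svm.score(val_x[:, cols], val_y)

    current_acc = fit_acc(mask)
    while mask.sum() > 1:
        active = np.flatnonzero(mask)
        # leave-one-feature-out importance: accuracy without the feature
        loo_acc = np.empty(len(active))
        for i, j in enumerate(active):
            trial = mask.copy()
            trial[j] = False
            loo_acc[i] = fit_acc(trial)
        # features whose removal hurts least (highest LOO accuracy) first
        batch = max(1, int(RFE_BATCH_FRACTION * mask.sum()))
        batch = min(batch, int(mask.sum()) - 1)
        drop = active[np.argsort(-loo_acc, kind="stable")[:batch]]
        trial = mask.copy()
        trial[drop] = False
        trial_acc = fit_acc(trial)
        if trial_acc >= current_acc:
            mask = trial
            current_acc = trial_acc
        else:
            break
    return mask


def _slot_matrix(feature_sets: list[FeatureSet], slot: str) -> np.ndarray:
    dims = {fs.vector(slot).shape[0] for fs in feature_sets}
    if len(dims) != 1:
        raise ValueError(f"inconsistent dimensionality in slot {slot!r}: {sorted(dims)}")
    return np.vstack([fs.vector(slot) for fs in feature_sets])


def _validation_split(
    n: int, y: np.ndarray, subjects: np.ndarray | None, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/validation index split, subject-disjoint if possible.

    Tiny inputs (where any split would leave a single-class training
    side) fall back to resubstitution validation.
    """
    rng = np.random.default_rng(seed)
    if subjects is not None:
        uniq = np.unique(subjects)
        if len(uniq) >= 4:
            rng.shuffle(uniq)
            n_val = max(1, int(round(fraction * len(uniq))))
            val_subj = set(uniq[:n_val].tolist())
            val_idx = np.array([i for i in range(n) if subjects[i] in val_subj])
            tr_idx = np.array([i for i in range(n) if subjects[i] not in val_subj])
            if len(np.unique(y[tr_idx])) == 2 and len(val_idx) >= 2:
                return tr_idx, val_idx
    if int(np.min(np.bincount(y))) >= 4 and n >= 10:
        tr_idx, val_idx = train_test_split(
            np.arange(n), test_size=fraction, random_state=seed, stratify=y
        )
        return tr_idx, val_idx
    idx = np.arange(n)
    return idx, idx


def _fit_slot(
    x: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray | None,
    config: EnsembleConfig,
    seed: int,
) -> SlotModel:
    scaler = standardize_fit(x)
    xs = scaler.transform(x)
    tr, val = _validation_split(len(y), y, subjects, config.validation_fraction, seed)
    c, gamma = _grid_search_rbf(xs[tr], y[tr], xs[val], y[val])
    if config.rfe:
        mask = rfe_select(
            xs[tr], y[tr], xs[val], y[val], seed,
            svm_params={"C": c, "gamma": gamma, "kernel": "rbf"},
        )
    else:
        mask = np.ones(x.shape[1], dtype=bool)
    svm = SVC(C=c, gamma=gamma, kernel="rbf")
    svm.fit(xs[:, mask], y)
    return SlotModel(scaler=scaler, mask=mask, svm=svm)


def train_ensemble(
    feature_sets: list[FeatureSet],
    labels: np.ndarray,
    subjects: np.ndarray | None = None,
    config: EnsembleConfig | None = None,
    seed: int = 0,
    external_features: np.ndarray | None = None,
) -> TrainedEnsemble:
    """Train the double-level classifier.

    Parameters
    ----------
    feature_sets : one FeatureSet per smile event.
    labels : binary labels (0 = posed, 1 = spontaneous).
    subjects : optional per-event subject IDs, used for subject-disjoint
        internal validation splits.
    external_features : optional (n, d) matrix feeding a ninth
        first-level classifier (hook for externally computed features).
    """
    config = config or EnsembleConfig()
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes are required for training")
    if np.min(np.bincount(labels)) < 2:
        raise ValueError("at least 2 examples per class are required")
    subjects = None if subjects is None else np.asarray(subjects)

    mats = {slot: _slot_matrix(feature_sets, slot) for slot in config.slots}
    if external_features is not None:
        mats["external"] = np.asarray(external_features, dtype=float)

    slot_models = {
        slot: _fit_slot(x, labels, subjects, config, seed) for slot, x in mats.items()
    }

    # second-level inputs: cross-fitted first-level decision values
    n = len(labels)
    meta = np.zeros((n, len(mats)))
    splitter = StratifiedKFold(n_splits=min(N_CROSSFIT_FOLDS, int(np.min(np.bincount(labels)))),
                               shuffle=True, random_state=seed)
    for tr, te in splitter.split(np.zeros(n), labels):
        for k, (slot, x) in enumerate(mats.items()):
            sub = _fit_slot(x[tr], labels[tr], None if subjects is None else subjects[tr],
                            config, seed)
            meta[te, k] = sub.decision(x[te])
    second = SVC(kernel="poly", degree=POLY_DEGREE, C=1.0, coef0=1.0, gamma="scale")
    second.fit(meta, labels)

    return TrainedEnsemble(
        slot_models=slot_models,
        second_level=second,
        config=config,
        seed=seed,
        fps=feature_sets[0].fps,
        slot_dims={slot: x.shape[1] for slot, x in mats.items()},
    )


def decision_values(
    model: TrainedEnsemble,
    feature_sets: list[FeatureSet],
    external_features: np.ndarray | None = None,
) -> np.ndarray:
    """Second-level decision value for each event (positive = spontaneous)."""
    cols = []
    for slot, sm in model.slot_models.items():
        if slot == "external":
            if external_features is None:
                raise ValueError("model expects external features")
            x = np.asarray(external_features, dtype=float)
        else:
            x = _slot_matrix(feature_sets, slot)
        if x.shape[1] != model.slot_dims[slot]:
            raise ValueError(
                f"slot {slot!r} has {x.shape[1]} features, "
                f"model expects {model.slot_dims[slot]}"
            )
        cols.append(sm.decision(x))
    return model.second_level.decision_function(np.column_stack(cols))


def predict(
    model: TrainedEnsemble,
    fs: FeatureSet,
    external_features: np.ndarray | None = None,
) -> tuple[str, float]:
    """Classify one smile event; returns (label, decision value)."""
    score = float(decision_values(model, [fs], external_features)[0])
    return ("spontaneous" if score > 0 else "posed", score)


@dataclass
class EvaluationReport:
    fold_accuracy: list[float]  # percent
    fold_auc: list[float]
    fold_assignment: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1)) if len(self.fold_accuracy) > 1 else 0.0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0


def cross_validate(
    feature_sets: list[FeatureSet],
    labels: np.ndarray,
    k: int = 10,
    subjects: np.ndarray | None = None,
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Subject-disjoint k-fold evaluation of the full ensemble.

    Each example is tested exactly once; standardization, grid search and
    feature selection see only the training folds.
    """
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if subjects is not None:
        subjects = np.asarray(subjects)
        if len(np.unique(subjects)) < k:
            raise ValueError("fewer subjects than folds; subject-disjoint folding impossible")
        splitter = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels, groups=subjects)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels)

    fold_acc: list[float] = []
    fold_auc: list[float] = []
    assignment = np.full(n, -1, dtype=int)
    for fold, (tr, te) in enumerate(splits):
        assignment[te] = fold
        model = train_ensemble(
            [feature_sets[i] for i in tr],
            labels[tr],
            subjects=None if subjects is None else subjects[tr],
            config=config,
            seed=seed,
        )
        scores = decision_values(model, [feature_sets[i] for i in te])
        pred = (scores > 0).astype(int)
        fold_acc.append(100.0 * float(np.mean(pred == labels[te])))
        fold_auc.append(auc(scores, labels[te]) if len(np.unique(labels[te])) == 2 else np.nan)
    fold_auc = [a for a in fold_auc if not np.isnan(a)]
    return EvaluationReport(fold_accuracy=fold_acc, fold_auc=fold_auc, fold_assignment=assignment)
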