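"""Random-forest fatigue classification under leave-one-subject-out CV.

Each LOSO fold holds out every window of one subject and trains on the
rest; class imbalance is handled inside the training fold only, by one of
three strategies: no correction, class weighting w_c = N / (K * n_c)
(K = 3 classes), or uniform random oversampling with replacement up to an
exact 1:1:1 ratio at the fold's majority-class count. Test folds are
never reweighted or resampled.

Metrics are LOSO point estimates on the predictions pooled across folds:
overall accuracy, macro one-vs-rest ROC AUC (midrank Mann-Whitney
statistic per class, unweighted mean), and the 3x3 confusion matrix.
Impurity-based feature importances are normalized to sum to 1 within each
fold, averaged across folds, and additionally summed per anatomical
segment (left/right arm/leg) and normalized to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .features import CLASSES, FEATURE_IDS, SEGMENT_FEATURES

N_CLASSES = len(CLASSES)
STRATEGIES = ("none", "class_weight", "oversample")


class DegenerateFoldError(ValueError):
    """A training fold is missing a class the strategy needs."""


class LeakageError(RuntimeError):
    """A subject appears in both train and test of one fold."""


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    max_features: str = "sqrt"
    max_depth: int | None = None
    min_leaf: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class ImbalanceStrategy:
    kind: str = "none"          # none | class_weight | oversample
    seed: int = 42
    allow_missing_class: bool = False

    def __post_init__(self) -> None:
        if self.kind not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.kind!r}")


@dataclass
class FoldResult:
    held_out_subject: str
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    probabilities: np.ndarray           # (n_test, 3), columns in CLASSES order
    feature_importances: np.ndarray     # (24,), sums to 1


@dataclass
class EvaluationResult:
    strategy: str
    accuracy: float
    macro_auc: float
    macro_recall: float
    confusion: pd.DataFrame             # rows true, cols predicted, L/M/H
    mean_importances: pd.Series         # index FEATURE_IDS
    segment_importances: pd.Series      # percentages per limb, sums to 100
    folds: list[FoldResult]


def loso_splits(table: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """One (test_subject, train_index, test_index) triple per subject."""
    subjects = list(pd.unique(table["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    splits = []
    for s in subjects:
        test = table.index[table["subject_id"] == s].to_numpy()
        train = table.index[table["subject_id"] != s].to_numpy()
        splits.append((s, train, test))
    return splits


def compute_class_weights(
    counts: dict[str, int], n_classes: int = N_CLASSES
) -> dict[str, float]:
    """Balanced class weights w_c = N / (K * n_c).

    The weighted mass n_c * w_c then equals N/K for every class.
    """
    if any(c <= 0 for c in counts.values()):
        raise DegenerateFoldError(f"zero class count in {counts}")
    total = sum(counts.values())
    return {c: total / (n_classes * n) for c, n in counts.items()}


def oversample_indices(
    labels: np.ndarray, seed: int = 42
) -> np.ndarray:
    """Row indices realizing exact 1:1:1 oversampling with replacement.

    All original rows are retained; each minority class is topped up with
    uniform draws (with replacement) from its own rows until every class
    count equals the majority count. Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    present = [c for c in CLASSES if (labels == c).any()]
    if len(present) < N_CLASSES:
        raise DegenerateFoldError(
            f"training fold missing classes: "
            f"{sorted(set(CLASSES) - set(present))}"
        )
    rng = np.random.default_rng(seed)
    majority = max(int((labels == c).sum()) for c in CLASSES)
    out = [np.arange(len(labels))]
    for c in CLASSES:
        idx = np.flatnonzero(labels == c)
        deficit = majority - len(idx)
        if deficit > 0:
            out.append(rng.choice(idx, size=deficit, replace=True))
    return np.concatenate(out)


def train_and_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    rf: RFConfig = RFConfig(),
    strategy: ImbalanceStrategy = ImbalanceStrategy(),
) -> FoldResult:
    """Fit one fold's forest and predict the held-out subject's windows."""
    shared = set(train["subject_id"]) & set(test["subject_id"])
    if shared:
        raise LeakageError(f"subjects in both train and test: {shared}")

    X_train = train[list(FEATURE_IDS)].to_numpy()
    y_train = train["label"].to_numpy()
    X_test = test[list(FEATURE_IDS)].to_numpy()

    class_weight = None
    if strategy.kind == "class_weight":
        counts = {c: int((y_train == c).sum()) for c in CLASSES}
        if strategy.allow_missing_class:
            counts = {c: n for c, n in counts.items() if n > 0}
            class_weight = compute_class_weights(counts, len(counts))
        else:
            class_weight = compute_class_weights(counts)
    elif strategy.kind == "oversample":
        idx = oversample_indices(y_train, seed=strategy.seed)
        X_train, y_train = X_train[idx], y_train[idx]

    model = RandomForestClassifier(
        n_estimators=rf.n_trees,
        max_features=rf.max_features,
        max_depth=rf.max_depth,
        min_samples_leaf=rf.min_leaf,
        class_weight=class_weight,
        random_state=rf.seed,
        n_jobs=1,
    )
    model.fit(X_train, y_train)

    # Probabilities in fixed Low/Medium/High order, padding classes the
    # fold never saw with zero probability.
    raw = model.predict_proba(X_test)
    proba = np.zeros((len(test), N_CLASSES))
    for j, c in enumerate(model.classes_):
        proba[:, CLASSES.index(c)] = raw[:, j]
    pred = np.array([CLASSES[i] for i in proba.argmax(axis=1)])

    imp = model.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full(len(imp), 1 / len(imp))
    return FoldResult(
        held_out_subject=str(test["subject_id"].iloc[0]),
        true_labels=test["label"].to_numpy(),
        predicted_labels=pred,
        probabilities=proba,
        feature_importances=imp,
    )


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUC via the midrank Mann-Whitney U statistic (ties half credit)."""
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    ranks = rankdata(scores)           # midranks for ties
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def macro_ovr_auc(true_labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Macro one-vs-rest ROC AUC over the classes with both outcomes present.

    Classes lacking either a positive or a negative in ``true_labels`` are
    excluded (and warned about); at least two classes must be present.
    """
    true_labels = np.asarray(true_labels)
    if len(np.unique(true_labels)) < 2:
        raise ValueError("macro OVR AUC undefined for single-class truth")
    aucs = []
    for j, c in enumerate(CLASSES):
        pos = true_labels == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} lacks positives or negatives; "
                          "excluded from macro AUC", stacklevel=2)
            continue
        aucs.append(_binary_auc(probabilities[:, j], pos))
    return float(np.mean(aucs))


def macro_recall(true_labels: np.ndarray, predicted: np.ndarray) -> float:
    """Unweighted mean per-class recall over classes present in truth."""
    true_labels = np.asarray(true_labels)
    recalls = []
    for c in CLASSES:
        mask = true_labels == c
        if mask.any():
            recalls.append(float((predicted[mask] == c).mean()))
    return float(np.mean(recalls))


def confusion_matrix(
    true_labels: np.ndarray, predicted: np.ndarray
) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for t, p in zip(true_labels, predicted):
        mat.loc[t, p] += 1
    return mat


def evaluate(
    table: pd.DataFrame,
    rf: RFConfig = RFConfig(),
    strategy: ImbalanceStrategy = ImbalanceStrategy(),
) -> EvaluationResult:
    """Full LOSO evaluation of one imbalance strategy.

    Runs every fold, pools the held-out predictions, and reports pooled
    accuracy, macro OVR AUC, macro recall, the pooled confusion matrix and
    the fold-averaged (fold-normalized) feature/segment importances.
    """
    folds = []
    for subject, train_idx, test_idx in loso_splits(table):
        try:
            folds.append(
                train_and_predict(
                    table.loc[train_idx], table.loc[test_idx], rf, strategy
                )
            )
        except DegenerateFoldError as exc:
            raise DegenerateFoldError(
                f"fold holding out {subject}: {exc}"
            ) from exc

    y_true = np.concatenate([f.true_labels for f in folds])
    y_pred = np.concatenate([f.predicted_labels for f in folds])
    proba = np.vstack([f.probabilities for f in folds])

    imp = np.vstack([f.feature_importances for f in folds])
    mean_imp = pd.Series(imp.mean(axis=0), index=list(FEATURE_IDS))
    seg = pd.Series(
        {
            limb: float(
                np.mean(
                    [
                        100.0
                        * sum(f.feature_importances[FEATURE_IDS.index(fid)]
                              for fid in fids)
                        for f in folds
                    ]
                )
            )
            for limb, fids in SEGMENT_FEATURES.items()
        }
    )

    return EvaluationResult(
        strategy=strategy.kind,
        accuracy=float((y_true == y_pred).mean()),
        macro_auc=macro_ovr_auc(y_true, proba),
        macro_recall=macro_recall(y_true, y_pred),
        confusion=confusion_matrix(y_true, y_pred),
        mean_importances=mean_imp,
        segment_importances=seg,
        folds=folds,
    )
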