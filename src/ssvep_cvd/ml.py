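"""Class balancing, classification, and cross-validated evaluation.

The cohort is imbalanced (11 normal vs 5 CVD at study scale), so the
minority class is oversampled with SMOTE: each synthetic sample is
``x_new = x_i + lambda * (x_j - x_i)`` with ``x_j`` one of the k nearest
minority neighbors of ``x_i`` and ``lambda ~ U(0, 1)``. Three classifiers
are evaluated with stratified 5-fold cross-validation: an entropy
(information-gain) decision tree, k-nearest-neighbors with Euclidean
distance, and a polynomial-kernel SVM, K(x, x') = (1 + <x, x'>)^d.

Features are z-scored per column (fit on the training fold) before the
distance- and margin-based classifiers, since PSD (µV²/Hz) and CCA ([0, 1])
features differ by orders of magnitude. SMOTE defaults to fold-internal
application (training portion only) to avoid leakage; a ``global`` mode
balances once before splitting for fidelity with balance-first protocols.

CVD is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

POSITIVE_CLASS = "cvd"

#: canonical feature-set column slices over the 16-column combined matrix
FEATURE_SETS = {"psd": slice(0, 8), "cca": slice(8, 16), "psd+cca": slice(0, 16)}


@dataclass
class BalancedSet:
    features: np.ndarray
    labels: np.ndarray
    synthetic_mask: np.ndarray  # True for SMOTE-generated rows


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0


@dataclass
class ClassifierReport:
    classifier: str
    feature_set: str
    fold_accuracies: list[float]  # percent
    mean_accuracy: float  # percent
    sd: float  # percent
    confusion: ConfusionMatrix
    precision: float
    recall: float
    specificity: float
    f1: float
    flags: list[str] = field(default_factory=list)


def smote_augment(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> BalancedSet:
    """Oversample the minority class to the majority count (SMOTE).

    k is clamped (with a warning) to ``minority_size - 1`` when too large;
    a single-sample minority class is an error since no neighbor exists.
    """
    rng = np.random.default_rng(rng)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.tolist()}")
    minority = classes[np.argmin(counts)]
    n_minority, n_majority = counts.min(), counts.max()
    n_new = int(n_majority - n_minority)
    if n_new == 0:
        return BalancedSet(
            features.copy(), labels.copy(), np.zeros(labels.size, dtype=bool)
        )
    if n_minority < 2:
        raise ValueError(
            "SMOTE needs at least 2 minority samples (no neighbor exists for 1)"
        )
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= n_minority:
        warnings.warn(
            f"k={k} >= minority size {n_minority}; clamping to {n_minority - 1}",
            stacklevel=2,
        )
        k = n_minority - 1
    x_min = features[labels == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)  # self included
    neighbor_idx = nn.kneighbors(x_min, return_distance=False)[:, 1:]
    new_rows = np.empty((n_new, features.shape[1]))
    for m in range(n_new):
        i = int(rng.integers(0, n_minority))
        j = int(neighbor_idx[i, rng.integers(0, k)])
        lam = rng.uniform(0.0, 1.0)
        new_rows[m] = x_min[i] + lam * (x_min[j] - x_min[i])
    return BalancedSet(
        features=np.vstack([features, new_rows]),
        labels=np.concatenate([labels, np.full(n_new, minority, dtype=labels.dtype)]),
        synthetic_mask=np.concatenate(
            [np.zeros(labels.size, dtype=bool), np.ones(n_new, dtype=bool)]
        ),
    )


def knn_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Majority vote among the k Euclidean-nearest training rows.

    Vote ties resolve to the tied class with the smallest summed neighbor
    distance, then lexicographically by label.
    """
    train_x = np.asarray(train_x, dtype=float)
    train_y = np.asarray(train_y)
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > train_x.shape[0]:
        raise ValueError(f"k={k} exceeds training size {train_x.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(train_x)
    dists, idx = nn.kneighbors(test_x)
    out = np.empty(test_x.shape[0], dtype=train_y.dtype)
    for i in range(test_x.shape[0]):
        votes: dict = {}
        for d, j in zip(dists[i], idx[i]):
            cnt, dsum = votes.get(train_y[j], (0, 0.0))
            votes[train_y[j]] = (cnt + 1, dsum + d)
        # max count, then min summed distance, then lexicographic label
        out[i] = min(votes, key=lambda c: (-votes[c][0], votes[c][1], str(c)))
    return out


class _KNNModel:
    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, x, y):
        self.x_, self.y_ = np.asarray(x, dtype=float), np.asarray(y)
        return self

    def predict(self, x):
        return knn_predict(self.x_, self.y_, x, k=min(self.k, self.x_.shape[0]))


def dt_fit(train_x, train_y, max_depth: int = 5) -> DecisionTreeClassifier:
    """Information-gain (entropy) decision tree, unpruned, depth-capped."""
    return DecisionTreeClassifier(
        criterion="entropy", max_depth=max_depth, random_state=0
    ).fit(train_x, train_y)


def dt_predict(model: DecisionTreeClassifier, x) -> np.ndarray:
    return model.predict(x)


def svm_fit(train_x, train_y, degree: int = 3, c: float = 1.0) -> SVC:
    """SVM with the inhomogeneous polynomial kernel (1 + <x, x'>)^d."""
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("SVM training requires both classes present")
    return SVC(kernel="poly", degree=degree, gamma=1.0, coef0=1.0, C=c).fit(
        train_x, train_y
    )


def svm_predict(model: SVC, x) -> np.ndarray:
    return model.predict(x)


def make_classifier(name: str, **kwargs):
    """Factory for the three evaluated classifiers: 'dt', 'knn', 'svm'."""
    if name == "dt":
        return DecisionTreeClassifier(
            criterion="entropy",
            max_depth=kwargs.get("max_depth", 5),
            random_state=0,
        )
    if name == "knn":
        return _KNNModel(k=kwargs.get("k", 5))
    if name == "svm":
        return SVC(
            kernel="poly",
            degree=kwargs.get("degree", 3),
            gamma=1.0,
            coef0=1.0,
            C=kwargs.get("c", 1.0),
        )
    raise ValueError(f"unknown classifier {name!r}; use dt, knn, or svm")


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Precision, recall (sensitivity), specificity and F1 from the counts.

    Undefined ratios (zero denominators) are reported as 0.0 and named in
    the ``flags`` list rather than raising.
    """
    flags = []

    def _ratio(num, den, name):
        if den == 0:
            flags.append(f"{name} undefined (zero denominator); reported as 0")
            return 0.0
        return num / den

    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    if (precision + recall) == 0:
        flags.append("f1 undefined (precision + recall = 0); reported as 0")
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "flags": flags,
    }


def select_features(features: np.ndarray, feature_set: str) -> np.ndarray:
    """Slice the combined 16-column matrix down to a named feature set."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(
            f"unknown feature set {feature_set!r}; use {sorted(FEATURE_SETS)}"
        )
    return np.asarray(features, dtype=float)[:, FEATURE_SETS[feature_set]]


def kfold_cv(
    features: np.ndarray,
    labels: np.ndarray,
    classifier="svm",
    feature_set: str = "psd+cca",
    k_folds: int = 5,
    seed: int | None = 0,
    smote_mode: str = "fold_internal",
    smote_k: int = 5,
    standardize: bool = True,
    **clf_kwargs,
) -> ClassifierReport:
    """Stratified k-fold evaluation with optional SMOTE balancing.

    *classifier* is one of the factory names ('dt', 'knn', 'svm') or any
    object with fit/predict. ``fold_internal`` applies SMOTE to the training portion of each fold
    only (no synthetic sample ever reaches a test set); ``global`` balances
    the whole matrix before splitting; ``none`` skips balancing. Accuracy is
    correct/total per held-out fold, in percent; the confusion matrix pools
    all held-out predictions.
    """
    if smote_mode not in ("fold_internal", "global", "none"):
        raise ValueError(f"unknown smote_mode {smote_mode!r}")
    x = select_features(features, feature_set)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("cross-validation requires both classes present")
    rng = np.random.default_rng(seed)
    if smote_mode == "global":
        balanced = smote_augment(x, y, k=smote_k, rng=rng)
        x, y = balanced.features, balanced.labels
    if x.shape[0] < k_folds:
        raise ValueError(f"{x.shape[0]} samples cannot fill {k_folds} folds")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_acc = []
    cm = ConfusionMatrix()
    for train_idx, test_idx in skf.split(x, y):
        x_tr, y_tr = x[train_idx], y[train_idx]
        x_te, y_te = x[test_idx], y[test_idx]
        if np.unique(y_tr).size < 2:
            raise ValueError("a training fold contains a single class; re-stratify")
        if standardize:
            scaler = StandardScaler().fit(x_tr)
            x_tr, x_te = scaler.transform(x_tr), scaler.transform(x_te)
        if smote_mode == "fold_internal":
            n_min = np.unique(y_tr, return_counts=True)[1].min()
            bal = smote_augment(x_tr, y_tr, k=min(smote_k, n_min - 1), rng=rng)
            x_tr, y_tr = bal.features, bal.labels
        model = (
            make_classifier(classifier, **clf_kwargs)
            if isinstance(classifier, str)
            else classifier
        ).fit(x_tr, y_tr)
        pred = model.predict(x_te)
        fold_acc.append(100.0 * float(np.mean(pred == y_te)))
        for truth, p in zip(y_te, pred):
            if truth == POSITIVE_CLASS:
                if p == POSITIVE_CLASS:
                    cm.tp += 1
                else:
                    cm.fn += 1
            else:
                if p == POSITIVE_CLASS:
                    cm.fp += 1
                else:
                    cm.tn += 1
    metrics = confusion_metrics(cm)
    return ClassifierReport(
        classifier=classifier if isinstance(classifier, str) else type(classifier).__name__,
        feature_set=feature_set,
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        sd=float(np.std(fold_acc, ddof=1)) if len(fold_acc) > 1 else 0.0,
        confusion=cm,
        precision=metrics["precision"],
        recall=metrics["recall"],
        specificity=metrics["specificity"],
        f1=metrics["f1"],
        flags=metrics["flags"],
    )
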