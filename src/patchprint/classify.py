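"""K-nearest-neighbors classification with leave-one-recording-per-class
cross-validation.

Samples are the 200-dimensional PAA-reduced, [0,1]-scaled windows (never the
2-D latent embedding).  Each cross-validation fold holds out one recording
per class; per-fold confusion matrices are summed into an overall matrix and

    accuracy = 100 * (diagonal sum) / (total sum)   [percent].

Tie handling is deterministic: a voting tie between classes is broken by the
smaller summed neighbor distance, then lexicographic class order; equal
distances at the k-th rank are resolved by stable sample order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, StageError
from .gating import Recording
from .preprocess import FoldData, PreprocessConfig, make_cv_folds, preprocess_fold


@dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.metric != "euclidean":
            raise ConfigError(f"unsupported metric {self.metric!r}")


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-dimension vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def knn_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: KNNConfig | None = None,
) -> np.ndarray:
    """Majority label among the k nearest training samples, per test sample."""
    config = config or KNNConfig()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train)
    if X_train.shape[0] == 0:
        raise ConfigError("empty training set")
    if X_train.shape[0] < config.k:
        raise ConfigError(f"training set smaller than k={config.k}")
    if X_train.shape[1] != X_test.shape[1]:
        raise ConfigError("train/test dimension mismatch")

    k = config.k
    # squared distances via the Gram-matrix identity (BLAS-backed); clip the
    # tiny negatives that cancellation can produce
    sq_train = np.einsum("ij,ij->i", X_train, X_train)
    sq_test = np.einsum("ij,ij->i", X_test, X_test)
    d2 = sq_test[:, None] + sq_train[None, :] - 2.0 * (X_test @ X_train.T)
    np.clip(d2, 0.0, None, out=d2)
    # k smallest per row with a tie margin; equal distances are then resolved
    # by training-sample order (stable), matching a full stable sort
    n_train = X_train.shape[0]
    m = min(4 * k, n_train)
    part = np.argpartition(d2, m - 1, axis=1)[:, :m] if m < n_train else np.tile(
        np.arange(n_train), (d2.shape[0], 1)
    )
    preds = []
    for row in range(d2.shape[0]):
        idx = part[row]
        order = np.lexsort((idx, d2[row, idx]))  # distance, then stable index
        idx = idx[order][:k]
        labels = y_train[idx]
        classes, votes = np.unique(labels, return_counts=True)
        top = votes.max()
        tied = classes[votes == top]
        if tied.size == 1:
            preds.append(tied[0])
            continue
        # tie-break: smaller summed neighbor distance, then lexicographic
        dist_row = np.sqrt(d2[row, idx])
        sums = {c: dist_row[labels == c].sum() for c in tied}
        best = min(sorted(sums), key=lambda c: sums[c])
        preds.append(best)
    return np.asarray(preds)


@dataclass
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # counts[true, predicted]

    @classmethod
    def empty(cls, classes) -> "ConfusionMatrix":
        classes = tuple(sorted(classes))
        return cls(classes=classes, counts=np.zeros((len(classes), len(classes)), dtype=int))

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        classes = tuple(sorted(classes if classes is not None else set(y_true) | set(y_pred)))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(classes=classes, counts=counts)

    def add(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ConfigError("cannot sum confusion matrices over different classes")
        return ConfusionMatrix(self.classes, self.counts + other.counts)

    def to_json(self) -> dict:
        return {"classes": list(self.classes), "counts": self.counts.tolist()}


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of samples on the confusion-matrix diagonal."""
    total = int(cm.counts.sum())
    if total == 0:
        raise ConfigError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / total


@dataclass
class CVResult:
    per_fold: list[tuple[int, ConfusionMatrix]]
    overall: ConfusionMatrix
    accuracy_pct: float
    mean_fold_accuracy_pct: float

    def to_json(self) -> dict:
        return {
            "per_fold": [
                {"fold_id": fid, **cm.to_json(), "accuracy_pct": accuracy(cm)}
                for fid, cm in self.per_fold
            ],
            "overall": self.overall.to_json(),
            "accuracy_pct": self.accuracy_pct,
            "mean_fold_accuracy_pct": self.mean_fold_accuracy_pct,
        }


def run_cross_validation(
    recordings_by_class: dict[str, list[Recording]],
    preprocess_config: PreprocessConfig | None = None,
    knn_config: KNNConfig | None = None,
) -> CVResult:
    """Full leave-one-recording-per-class cross-validation at one potential.

    For every fold the chain is preprocess_fold -> KNN fit on train windows
    -> predict test windows; fold confusion matrices are summed into the
    overall matrix.  Anomaly filtering, when wanted, is applied to
    ``recordings_by_class`` before calling this.
    """
    preprocess_config = preprocess_config or PreprocessConfig()
    knn_config = knn_config or KNNConfig()
    for label, recs in recordings_by_class.items():
        if len(recs) < 2:
            raise StageError(f"class {label!r} has fewer than 2 recordings")
    by_id = {
        rec.recording_id: rec for recs in recordings_by_class.values() for rec in recs
    }
    groups = {
        label: [rec.recording_id for rec in recs]
        for label, recs in recordings_by_class.items()
    }
    folds = make_cv_folds(groups)
    classes = tuple(sorted(recordings_by_class))
    overall = ConfusionMatrix.empty(classes)
    per_fold = []
    accs = []
    for fold in folds:
        data: FoldData = preprocess_fold(fold, by_id, preprocess_config)
        preds = knn_predict(data.X_train, data.y_train, data.X_test, knn_config)
        cm = ConfusionMatrix.from_predictions(data.y_test, preds, classes)
        per_fold.append((fold.fold_id, cm))
        overall = overall.add(cm)
        accs.append(accuracy(cm))
    return CVResult(
        per_fold=per_fold,
        overall=overall,
        accuracy_pct=accuracy(overall),
        mean_fold_accuracy_pct=float(np.mean(accs)),
    )
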