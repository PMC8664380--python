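"""AU classification in eigenspace: KNN (Euclidean/cosine) and linear SVM.

KNN is the workhorse: after zero-meaning and unit normalization,
Euclidean distance in eigenspace approximates (inverse) image
correlation, so nearest-neighbor matching is an efficient proxy for
template correlation.  Tie rules are fixed so predictions are
deterministic across runs and platforms:

* neighbor-set ties at the k-th radius: include by smallest training-row
  index (stable distance sort);
* vote ties between classes: smallest summed distance among the tied
  classes' neighbors, then the fixed class order of the region.

The SVM alternative is a linear-kernel one-vs-one machine on features
standardized by the training mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .datamodel import AUClass, target_classes
from .eigenfaces import ProjectedFeatures


@dataclass(frozen=True)
class ClassifierConfig:
    kind: str = "knn"  # "knn" | "svm"
    k: int = 1
    metric: str = "euclidean"  # "euclidean" | "cosine" (knn only)
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "knn":
            if self.k < 1:
                raise ValueError(f"k must be >= 1, got {self.k}")
            if self.metric not in ("euclidean", "cosine"):
                raise ValueError(f"unknown metric {self.metric!r}")


def feature_distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    """Distance between two feature vectors.

    euclidean -> ||u - v||_2; cosine -> 1 - u.v / (||u|| ||v||).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch {u.shape} vs {v.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise ValueError("cosine distance undefined for a zero vector")
        return float(1.0 - (u @ v) / (nu * nv))
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class TrainedClassifier:
    config: ClassifierConfig
    train_features: np.ndarray  # (n, N)
    train_labels: np.ndarray  # (n,) of AUClass
    class_order: tuple[AUClass, ...]
    eigen_ref: Optional[str] = None
    _svm: Optional[SVC] = field(default=None, repr=False)
    _scaler: Optional[tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False
    )


def train_classifier(
    features: ProjectedFeatures | np.ndarray,
    labels: Sequence[AUClass],
    config: ClassifierConfig,
    class_order: Optional[tuple[AUClass, ...]] = None,
    eigen_ref: Optional[str] = None,
) -> TrainedClassifier:
    """Fit a classifier on eigenspace weights.

    Requires at least one example of each of the region's three target
    classes; the class order (used for tie-breaking and reports) defaults
    to the fixed target order of the labels' region.
    """
    X = features.weights if isinstance(features, ProjectedFeatures) else features
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(labels), dtype=object)
    if len(X) != len(y):
        raise ValueError("feature/label lengths differ")
    if class_order is None:
        class_order = target_classes(y[0].region)
    present = set(y.tolist())
    if present != set(class_order):
        raise ValueError(
            f"training labels must cover exactly {[c.value for c in class_order]}, "
            f"got {sorted(c.value for c in present)}"
        )
    clf = TrainedClassifier(config, X, y, tuple(class_order), eigen_ref)
    if config.kind == "knn":
        if len(X) < config.k:
            raise ValueError(f"k={config.k} exceeds training size {len(X)}")
    else:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        codes = np.array([class_order.index(c) for c in y])
        svm = SVC(kernel="linear", C=config.svm_c, decision_function_shape="ovo")
        svm.fit((X - mean) / sd, codes)
        clf._svm = svm
        clf._scaler = (mean, sd)
    return clf


def _knn_predict(clf: TrainedClassifier, probes: np.ndarray) -> list[AUClass]:
    cfg = clf.config
    D = cdist(probes, clf.train_features, metric=cfg.metric)
    if cfg.metric == "cosine":
        if (np.linalg.norm(clf.train_features, axis=1) == 0).any() or (
            np.linalg.norm(probes, axis=1) == 0
        ).any():
            raise ValueError("cosine distance undefined for a zero vector")
    class_index = {c: i for i, c in enumerate(clf.class_order)}
    train_codes = np.array([class_index[c] for c in clf.train_labels])
    out: list[AUClass] = []
    for row in D:
        nn = np.argsort(row, kind="stable")[: cfg.k]  # index ties -> smaller row
        votes = np.bincount(train_codes[nn], minlength=len(clf.class_order))
        best = np.flatnonzero(votes == votes.max())
        if len(best) > 1:
            # tie: smallest summed distance among each tied class's neighbors
            sums = np.array(
                [row[nn[train_codes[nn] == c]].sum() for c in best]
            )
            best = best[np.flatnonzero(sums == sums.min())]
        out.append(clf.class_order[int(best[0])])  # then fixed class order
    return out


def predict(
    clf: TrainedClassifier, probes: ProjectedFeatures | np.ndarray
) -> list[AUClass]:
    """Classify probe feature vectors into the region's AU classes."""
    X = probes.weights if isinstance(probes, ProjectedFeatures) else probes
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != clf.train_features.shape[1]:
        raise ValueError(
            f"probe width {X.shape[1]} != training width "
            f"{clf.train_features.shape[1]}"
        )
    if clf.config.kind == "knn":
        return _knn_predict(clf, X)
    mean, sd = clf._scaler  # type: ignore[misc]
    codes = clf._svm.predict((X - mean) / sd)  # type: ignore[union-attr]
    return [clf.class_order[int(c)] for c in codes]
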