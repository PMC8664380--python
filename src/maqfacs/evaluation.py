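"""Validation designs, class balancing, grid search and performance reports.

Training sets are balanced by random undersampling: every class is cut
to the smallest class's frame count, drawn without replacement from a
seeded generator, and the procedure is repeated to give several balanced
sets (the test sets are never undersampled).  Three generalization
designs are supported:

* within-subject: leave one video of a subject out (train on the
  subject's other videos); a partition is kept only if every class has
  at least ``min_train`` training and ``min_test`` test frames
  (defaults 20 / 5);
* across-subject: leave one whole subject out (defaults 150 / 50);
* holdout: repeated stratified 80/20 validation/test splits (default
  100 splits) for tuning on a new population.

Hyperparameters (k, pcExplVar, distance metric, balanced-set index) are
selected by the mean average true-positive rate (TPR) over partitions,
with a deterministic tie-break.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, predict, train_classifier
from .datamodel import AUClass, target_classes
from .eigenfaces import (
    DEFAULT_EIGENVALUE_THRESHOLD,
    fit_eigenfaces,
    project,
    select_num_components,
)
from .preprocess import ImageDatabase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BalancedTrainingSet:
    row_indices: np.ndarray  # indices into an ImageDatabase, sorted, unique
    per_class_count: int
    seed: int
    set_index: int  # 1-based


@dataclass(frozen=True)
class CVPartition:
    design: str  # "within_subject" | "across_subject" | "holdout"
    held_out_unit: str  # video_id, subject_id, or split label
    train_rows: np.ndarray
    test_rows: np.ndarray
    split_id: Optional[int] = None

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_rows, self.test_rows).size:
            raise ValueError("train and test rows overlap")


@dataclass(frozen=True)
class ParameterGrid:
    k_values: tuple[int, ...] = tuple(range(1, 13))
    pc_expl_var_values: tuple[float, ...] = tuple(range(50, 100, 5))
    metrics: tuple[str, ...] = ("euclidean", "cosine")
    balanced_set_indices: Optional[tuple[int, ...]] = None


@dataclass
class PerformanceReport:
    """Confusion matrix (rows = predicted, columns = true) and summaries."""

    confusion: np.ndarray  # (3, 3) counts
    per_class_tpr: np.ndarray  # (3,), NaN where the true class is absent
    avg_tpr: float
    accuracy: float
    n_test: int
    class_order: tuple[AUClass, ...]


def undersample_balanced(
    db: ImageDatabase,
    n_sets: int,
    seed: int,
    class_order: Optional[tuple[AUClass, ...]] = None,
) -> list[BalancedTrainingSet]:
    """Draw balanced training sets from a database.

    Each set keeps every row of the smallest class and a uniform sample
    without replacement of that size from each larger class.  Sets are
    drawn independently; the draw is a pure function of (seed, set_index).
    """
    if class_order is None:
        class_order = target_classes(db.region)
    by_class = {c: db.rows_where(au_class=c) for c in class_order}
    for c, rows in by_class.items():
        if rows.size == 0:
            raise ValueError(f"class {c.value} has no rows to sample from")
    min_count = min(rows.size for rows in by_class.values())
    sets = []
    for set_index in range(1, n_sets + 1):
        rng = np.random.default_rng([seed, set_index])
        chosen: list[np.ndarray] = []
        for c in class_order:
            rows = by_class[c]
            if rows.size == min_count:
                chosen.append(rows)
            else:
                chosen.append(rng.choice(rows, size=min_count, replace=False))
        sets.append(
            BalancedTrainingSet(
                row_indices=np.sort(np.concatenate(chosen)),
                per_class_count=min_count,
                seed=seed,
                set_index=set_index,
            )
        )
    return sets


def _class_counts(db: ImageDatabase, rows: np.ndarray) -> dict[AUClass, int]:
    counts: dict[AUClass, int] = {}
    for r in rows:
        c = db.rows_meta[int(r)].au_class
        counts[c] = counts.get(c, 0) + 1
    return counts


def _meets(counts: dict[AUClass, int], classes: Iterable[AUClass], n: int) -> bool:
    return all(counts.get(c, 0) >= n for c in classes)


def make_within_subject_partitions(
    db: ImageDatabase, min_train: int = 20, min_test: int = 5
) -> list[CVPartition]:
    """Leave-one-video-out within each subject, with inclusion thresholds."""
    classes = target_classes(db.region)
    parts: list[CVPartition] = []
    subjects = sorted({m.subject_id for m in db.rows_meta})
    for subject in subjects:
        videos = sorted(
            {m.video_id for m in db.rows_meta if m.subject_id == subject}
        )
        if len(videos) < 2:
            continue
        for video in videos:
            test = db.rows_where(subject_id=subject, video_id=video)
            train = np.setdiff1d(db.rows_where(subject_id=subject), test)
            if not _meets(_class_counts(db, train), classes, min_train):
                continue
            if not _meets(_class_counts(db, test), classes, min_test):
                continue
            parts.append(
                CVPartition("within_subject", video, train, test)
            )
    if not parts:
        logger.warning("no within-subject partitions met the thresholds")
    return parts


def make_across_subject_partitions(
    db: ImageDatabase, min_train: int = 150, min_test: int = 50
) -> list[CVPartition]:
    """Leave-one-subject-out, with inclusion thresholds."""
    classes = target_classes(db.region)
    parts: list[CVPartition] = []
    all_rows = np.arange(db.n_images)
    for subject in sorted({m.subject_id for m in db.rows_meta}):
        test = db.rows_where(subject_id=subject)
        train = np.setdiff1d(all_rows, test)
        if not _meets(_class_counts(db, train), classes, min_train):
            continue
        if not _meets(_class_counts(db, test), classes, min_test):
            continue
        parts.append(CVPartition("across_subject", subject, train, test))
    if not parts:
        logger.warning("no across-subject partitions met the thresholds")
    return parts


def _largest_remainder_counts(
    counts: Sequence[int], fraction: float
) -> list[int]:
    """Per-class test counts hitting round(total*fraction) exactly."""
    total_target = int(math.floor(sum(counts) * fraction + 0.5))
    exact = [c * fraction for c in counts]
    base = [int(math.floor(e)) for e in exact]
    remainders = [e - b for e, b in zip(exact, base)]
    deficit = total_target - sum(base)
    # assign leftover units by largest remainder; ties -> larger class,
    # then smaller class position (deterministic)
    order = sorted(
        range(len(counts)), key=lambda i: (-remainders[i], -counts[i], i)
    )
    for i in order[:deficit]:
        base[i] += 1
    return base


def make_holdout_splits(
    db: ImageDatabase,
    subject_rows: np.ndarray,
    n_splits: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    unit: str = "holdout",
) -> list[CVPartition]:
    """Repeated stratified validation/test splits of one subject's rows.

    Per-class test counts follow largest-remainder rounding so the
    global test fraction is hit exactly where divisible.  The remaining
    rows form the validation set.  Deterministic given the seed.
    """
    subject_rows = np.asarray(subject_rows, dtype=int)
    classes = target_classes(db.region)
    by_class = []
    for c in classes:
        rows = np.array(
            [r for r in subject_rows if db.rows_meta[int(r)].au_class is c]
        )
        if rows.size < 5:
            raise ValueError(
                f"class {c.value} has {rows.size} rows; too few to stratify"
            )
        by_class.append(rows)
    test_counts = _largest_remainder_counts(
        [r.size for r in by_class], test_fraction
    )
    if any(t == 0 or t >= r.size for t, r in zip(test_counts, by_class)):
        raise ValueError("stratification leaves an empty test or train class")
    parts = []
    for split_id in range(1, n_splits + 1):
        rng = np.random.default_rng([seed, split_id])
        test_parts = []
        for rows, t in zip(by_class, test_counts):
            test_parts.append(rng.choice(rows, size=t, replace=False))
        test = np.sort(np.concatenate(test_parts))
        train = np.setdiff1d(subject_rows, test)
        parts.append(
            CVPartition("holdout", unit, train, test, split_id=split_id)
        )
    return parts


def evaluate_predictions(
    predicted: Sequence[AUClass],
    truth: Sequence[AUClass],
    class_order: tuple[AUClass, ...],
) -> PerformanceReport:
    """Confusion matrix, per-class sensitivity (TPR), mean TPR, accuracy.

    The confusion matrix is predicted x true.  A class absent from the
    truth has undefined TPR: it is reported as NaN and excluded from the
    mean (with a warning; inclusion thresholds normally prevent this).
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth) or not truth:
        raise ValueError("predicted/truth must be equal-length and non-empty")
    index = {c: i for i, c in enumerate(class_order)}
    confusion = np.zeros((len(class_order), len(class_order)), dtype=int)
    for p, t in zip(predicted, truth):
        confusion[index[p], index[t]] += 1
    col_sums = confusion.sum(axis=0)
    tpr = np.full(len(class_order), np.nan)
    for j, total in enumerate(col_sums):
        if total > 0:
            tpr[j] = confusion[j, j] / total
        else:
            logger.warning(
                "class %s absent from test set; TPR undefined",
                class_order[j].value,
            )
    n = int(confusion.sum())
    return PerformanceReport(
        confusion=confusion,
        per_class_tpr=tpr,
        avg_tpr=float(np.nanmean(tpr)),
        accuracy=float(np.trace(confusion) / n),
        n_test=n,
        class_order=class_order,
    )


@dataclass
class GridSearchResult:
    best: dict  # k, pc_expl_var, metric, set_index, score
    surface: pd.DataFrame  # full performance surface

    @property
    def best_score(self) -> float:
        return self.best["score"]


_METRIC_ORDER = {"euclidean": 0, "cosine": 1}


def evaluate_configuration(
    db: ImageDatabase,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    pc_expl_var: float,
    classifier_config: ClassifierConfig,
    eigenvalue_threshold: float = DEFAULT_EIGENVALUE_THRESHOLD,
) -> PerformanceReport:
    """Fit eigenfaces + classifier on train rows, score on test rows."""
    class_order = target_classes(db.region)
    model = fit_eigenfaces(db.matrix[train_rows], eigenvalue_threshold)
    N = select_num_components(model, pc_expl_var)
    train_w = project(model, db.matrix[train_rows], N)
    test_w = project(model, db.matrix[test_rows], N)
    labels = [db.rows_meta[int(r)].au_class for r in train_rows]
    clf = train_classifier(train_w, labels, classifier_config, class_order)
    pred = predict(clf, test_w)
    truth = [db.rows_meta[int(r)].au_class for r in test_rows]
    return evaluate_predictions(pred, truth, class_order)


def grid_search(
    db: ImageDatabase,
    balanced_sets: Sequence[BalancedTrainingSet],
    partitions: Sequence[CVPartition],
    grid: ParameterGrid = ParameterGrid(),
    classifier_kind: str = "knn",
    eigenvalue_threshold: float = DEFAULT_EIGENVALUE_THRESHOLD,
) -> GridSearchResult:
    """Exhaustive hyperparameter search scored by mean average TPR.

    For every grid point the eigenfaces are recomputed on the balanced
    training rows restricted to each partition's training pool, the
    dimensionality is set by pcExplVar, and the classifier is scored on
    the partition's test rows; the score is the mean avg TPR over
    partitions.  Ties break toward smaller k, then smaller pcExplVar,
    then euclidean before cosine, then smaller balanced-set index.
    """
    if not balanced_sets or not partitions:
        raise ValueError("grid search needs balanced sets and partitions")
    class_order = target_classes(db.region)
    set_indices = grid.balanced_set_indices or tuple(
        b.set_index for b in balanced_sets
    )
    sets = {b.set_index: b for b in balanced_sets}
    metrics = grid.metrics if classifier_kind == "knn" else ("euclidean",)
    k_values = grid.k_values if classifier_kind == "knn" else (1,)
    records: dict[tuple, list[float]] = {
        (k, pc, metric, si): []
        for si in set_indices
        for pc in grid.pc_expl_var_values
        for metric in metrics
        for k in k_values
    }
    for si in set_indices:
        bset = sets[si]
        for part in partitions:
            train_rows = np.intersect1d(bset.row_indices, part.train_rows)
            if train_rows.size == 0:
                continue
            model = fit_eigenfaces(db.matrix[train_rows], eigenvalue_threshold)
            labels = [db.rows_meta[int(r)].au_class for r in train_rows]
            truth = [db.rows_meta[int(r)].au_class for r in part.test_rows]
            for pc in grid.pc_expl_var_values:
                N = select_num_components(model, pc)
                train_w = project(model, db.matrix[train_rows], N)
                test_w = project(model, db.matrix[part.test_rows], N)
                for metric, k in itertools.product(metrics, k_values):
                    if k > train_rows.size:
                        continue
                    if classifier_kind == "knn":
                        cfg = ClassifierConfig("knn", k=k, metric=metric)
                    else:
                        cfg = ClassifierConfig("svm")
                    clf = train_classifier(train_w, labels, cfg, class_order)
                    rep = evaluate_predictions(
                        predict(clf, test_w), truth, class_order
                    )
                    records[(k, pc, metric, si)].append(rep.avg_tpr)
    rows = []
    for (k, pc, metric, si), scores in records.items():
        rows.append(
            {
                "k": k,
                "pc_expl_var": pc,
                "metric": metric,
                "set_index": si,
                "avg_tpr": float(np.mean(scores)) if scores else np.nan,
                "n_partitions": len(scores),
            }
        )
    surface = pd.DataFrame(rows)
    valid = surface.dropna(subset=["avg_tpr"])
    if valid.empty:
        raise ValueError("no grid point could be evaluated")
    best_row = min(
        valid.itertuples(),
        key=lambda r: (
            -r.avg_tpr,
            r.k,
            r.pc_expl_var,
            _METRIC_ORDER[r.metric],
            r.set_index,
        ),
    )
    best = {
        "k": int(best_row.k),
        "pc_expl_var": float(best_row.pc_expl_var),
        "metric": best_row.metric,
        "set_index": int(best_row.set_index),
        "score": float(best_row.avg_tpr),
    }
    return GridSearchResult(best=best, surface=surface)


@dataclass
class SubjectLevelReport:
    per_subject: dict[str, PerformanceReport]
    mean_avg_tpr: float
    sem_avg_tpr: float
    mean_accuracy: float
    sem_accuracy: float
    mean_confusion: np.ndarray


def subject_level_report(
    video_reports: Sequence[tuple[str, PerformanceReport]],
) -> SubjectLevelReport:
    """Aggregate unit-level reports per subject, then across subjects.

    Per subject: unweighted means of the unit-level metrics and
    confusion matrices.  Across subjects: mean and standard error.
    """
    if not video_reports:
        raise ValueError("no reports supplied")
    by_subject: dict[str, list[PerformanceReport]] = {}
    for subject, rep in video_reports:
        by_subject.setdefault(subject, []).append(rep)
    per_subject: dict[str, PerformanceReport] = {}
    for subject, reps in sorted(by_subject.items()):
        confusion = np.mean([r.confusion for r in reps], axis=0)
        tpr = np.nanmean([r.per_class_tpr for r in reps], axis=0)
        per_subject[subject] = PerformanceReport(
            confusion=confusion,
            per_class_tpr=tpr,
            avg_tpr=float(np.mean([r.avg_tpr for r in reps])),
            accuracy=float(np.mean([r.accuracy for r in reps])),
            n_test=int(sum(r.n_test for r in reps)),
            class_order=reps[0].class_order,
        )
    tprs = np.array([r.avg_tpr for r in per_subject.values()])
    accs = np.array([r.accuracy for r in per_subject.values()])
    n = len(tprs)
    sem = lambda a: float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return SubjectLevelReport(
        per_subject=per_subject,
        mean_avg_tpr=float(tprs.mean()),
        sem_avg_tpr=sem(tprs),
        mean_accuracy=float(accs.mean()),
        sem_accuracy=sem(accs),
        mean_confusion=np.mean(
            [r.confusion for r in per_subject.values()], axis=0
        ),
    )
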