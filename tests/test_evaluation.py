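"""Balancing, CV designs, stratified splits, reports and grid search."""

from __future__ import annotations

import numpy as np
import pytest

from maqfacs.classify import ClassifierConfig
from maqfacs.datamodel import LOWER_TARGETS, Region, UPPER_TARGETS
from maqfacs.evaluation import (
    ParameterGrid,
    evaluate_configuration,
    evaluate_predictions,
    grid_search,
    make_across_subject_partitions,
    make_holdout_splits,
    make_within_subject_partitions,
    subject_level_report,
    undersample_balanced,
)
from maqfacs.preprocess import ImageDatabase, RowMeta

A, B, C = UPPER_TARGETS


def _db_from_counts(counts, subjects=None, videos=None, n_pixels=1, rng=None):
    """Metadata-only database: class counts (dict), optional per-row
    subject/video assignment callables."""
    meta = []
    i = 0
    for cls, n in counts.items():
        for j in range(n):
            subject = subjects(cls, j) if subjects else "s0"
            video = videos(cls, j) if videos else f"{subject}_v0"
            meta.append(RowMeta(video, i, subject, cls))
            i += 1
    values = (
        rng.normal(size=(i, n_pixels)) if rng is not None
        else np.zeros((i, n_pixels))
    )
    return ImageDatabase(values, meta, Region.UPPER, (1, n_pixels))


class TestUndersampleBalanced:
    def test_published_upper_face_counts(self):
        """Class counts 1213 / 19500 / 150000 balance to 3639 frames."""
        db = _db_from_counts({B: 1213, C: 19500, A: 150000})
        (bset,) = undersample_balanced(db, 1, seed=0)
        assert bset.per_class_count == 1213
        assert bset.row_indices.size == 3639

    def test_published_lower_face_counts(self):
        counts = {
            LOWER_TARGETS[1]: 310,
            LOWER_TARGETS[2]: 15000,
            LOWER_TARGETS[0]: 15000,
        }
        db = _db_from_counts(counts)
        db.region = Region.LOWER
        (bset,) = undersample_balanced(db, 1, seed=0)
        assert bset.row_indices.size == 930

    def test_already_balanced_keeps_every_row(self):
        db = _db_from_counts({A: 5, B: 5, C: 5})
        sets = undersample_balanced(db, 3, seed=1)
        for s in sets:
            assert np.array_equal(s.row_indices, np.arange(15))

    def test_balance_uniqueness_and_seed_reproducibility(self):
        db = _db_from_counts({A: 40, B: 11, C: 25})
        sets1 = undersample_balanced(db, 4, seed=7)
        sets2 = undersample_balanced(db, 4, seed=7)
        other = undersample_balanced(db, 4, seed=8)
        for s1, s2 in zip(sets1, sets2):
            assert np.array_equal(s1.row_indices, s2.row_indices)
            assert len(np.unique(s1.row_indices)) == s1.row_indices.size
            counts = {}
            for r in s1.row_indices:
                cls = db.rows_meta[int(r)].au_class
                counts[cls] = counts.get(cls, 0) + 1
            assert counts == {A: 11, B: 11, C: 11}
        assert any(
            not np.array_equal(s1.row_indices, s3.row_indices)
            for s1, s3 in zip(sets1, other)
        )

    def test_independent_sets_differ(self):
        db = _db_from_counts({A: 200, B: 10, C: 200})
        s1, s2 = undersample_balanced(db, 2, seed=3)
        assert not np.array_equal(s1.row_indices, s2.row_indices)

    def test_empty_class_rejected(self):
        db = _db_from_counts({A: 5, B: 5, C: 5})
        db.rows_meta = [
            RowMeta(m.video_id, m.frame_index, m.subject_id, A)
            for m in db.rows_meta
        ]
        with pytest.raises(ValueError, match="no rows"):
            undersample_balanced(db, 1, seed=0)


class TestWithinSubjectPartitions:
    def test_two_rich_videos_give_two_partitions(self):
        db = _db_from_counts(
            {A: 60, B: 60, C: 60},
            subjects=lambda c, j: "s0",
            videos=lambda c, j: f"s0_v{j % 2}",
        )
        parts = make_within_subject_partitions(db, min_train=20, min_test=5)
        assert len(parts) == 2
        for p in parts:
            assert np.intersect1d(p.train_rows, p.test_rows).size == 0
            held = {db.rows_meta[int(r)].video_id for r in p.test_rows}
            assert held == {p.held_out_unit}

    def test_sparse_test_video_excluded(self):
        # video v2 has only 4 frames of class B -> cannot be held out
        def videos(cls, j):
            if cls is B:
                return ("s0_v2" if j < 4 else f"s0_v{j % 2}")
            return f"s0_v{j % 3}"

        db = _db_from_counts(
            {A: 90, B: 56, C: 90}, subjects=lambda c, j: "s0", videos=videos
        )
        parts = make_within_subject_partitions(db, min_train=20, min_test=5)
        assert sorted(p.held_out_unit for p in parts) == ["s0_v0", "s0_v1"]

    def test_single_video_subject_yields_nothing(self):
        db = _db_from_counts({A: 30, B: 30, C: 30})
        assert make_within_subject_partitions(db) == []


class TestAcrossSubjectPartitions:
    @staticmethod
    def _multi_subject_db(counts_per_subject):
        meta = []
        i = 0
        for subject, counts in counts_per_subject.items():
            for cls, n in counts.items():
                for _ in range(n):
                    meta.append(RowMeta(f"{subject}_v0", i, subject, cls))
                    i += 1
        return ImageDatabase(
            np.zeros((i, 1)), meta, Region.UPPER, (1, 1)
        )

    def test_all_rich_subjects_held_out(self):
        rich = {A: 120, B: 120, C: 120}
        db = self._multi_subject_db({f"s{i}": dict(rich) for i in range(5)})
        parts = make_across_subject_partitions(db, min_train=150, min_test=50)
        assert len(parts) == 5

    def test_poor_subject_never_held_out(self):
        db = self._multi_subject_db(
            {
                "s0": {A: 120, B: 120, C: 120},
                "s1": {A: 120, B: 120, C: 120},
                "s2": {A: 120, B: 49, C: 120},  # 49 < min_test
            }
        )
        parts = make_across_subject_partitions(db, min_train=150, min_test=50)
        assert sorted(p.held_out_unit for p in parts) == ["s0", "s1"]

    def test_partition_count_equals_exhaustive_enumeration(self):
        """Threshold logic agrees with a brute-force oracle on an uneven
        multi-subject layout."""
        layout = {
            "s0": {A: 200, B: 60, C: 200},
            "s1": {A: 200, B: 55, C: 200},
            "s2": {A: 40, B: 200, C: 200},
            "s3": {A: 200, B: 200, C: 200},
        }
        db = self._multi_subject_db(layout)
        min_train, min_test = 150, 50
        expected = []
        for held in layout:
            test_ok = all(layout[held].get(c, 0) >= min_test for c in (A, B, C))
            train_ok = all(
                sum(layout[s].get(c, 0) for s in layout if s != held)
                >= min_train
                for c in (A, B, C)
            )
            if test_ok and train_ok:
                expected.append(held)
        parts = make_across_subject_partitions(db, min_train, min_test)
        assert sorted(p.held_out_unit for p in parts) == sorted(expected)


class TestHoldoutSplits:
    def test_largest_remainder_counts(self):
        """Class counts 25/15/10 at 20% -> test sets of exactly 5/3/2."""
        db = _db_from_counts({A: 25, B: 15, C: 10})
        parts = make_holdout_splits(
            db, np.arange(50), n_splits=10, test_fraction=0.2, seed=2
        )
        for p in parts:
            assert p.test_rows.size == 10
            counts = {}
            for r in p.test_rows:
                cls = db.rows_meta[int(r)].au_class
                counts[cls] = counts.get(cls, 0) + 1
            assert counts == {A: 5, B: 3, C: 2}
            union = np.union1d(p.train_rows, p.test_rows)
            assert np.array_equal(union, np.arange(50))
            assert np.intersect1d(p.train_rows, p.test_rows).size == 0

    def test_indivisible_counts_hit_global_fraction(self):
        db = _db_from_counts({A: 26, B: 16, C: 11})
        (p,) = make_holdout_splits(
            db, np.arange(53), n_splits=1, test_fraction=0.2, seed=0
        )
        assert p.test_rows.size == round(53 * 0.2)

    def test_deterministic_given_seed(self):
        db = _db_from_counts({A: 25, B: 15, C: 10})
        p1 = make_holdout_splits(db, np.arange(50), n_splits=3, seed=9)
        p2 = make_holdout_splits(db, np.arange(50), n_splits=3, seed=9)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.test_rows, b.test_rows)

    def test_too_small_class_rejected(self):
        db = _db_from_counts({A: 25, B: 15, C: 4})
        with pytest.raises(ValueError, match="stratif"):
            make_holdout_splits(db, np.arange(44))


class TestEvaluatePredictions:
    def test_perfect_predictions(self):
        truth = [A] * 5 + [B] * 5 + [C] * 5
        rep = evaluate_predictions(truth, truth, UPPER_TARGETS)
        assert rep.accuracy == 1.0 and rep.avg_tpr == 1.0
        assert np.array_equal(np.diag(rep.confusion), [5, 5, 5])

    def test_worked_confusion_example(self):
        """Confusion (pred x true) [[5,1,2],[0,4,0],[0,0,3]]:
        TPRs (1.0, 0.8, 0.6), mean 0.8, accuracy 12/15."""
        predicted = (
            [A] * 5 + [A] * 1 + [A] * 2 + [B] * 4 + [C] * 3
        )
        truth = [A] * 5 + [B] * 1 + [C] * 2 + [B] * 4 + [C] * 3
        rep = evaluate_predictions(predicted, truth, UPPER_TARGETS)
        assert np.array_equal(
            rep.confusion, [[5, 1, 2], [0, 4, 0], [0, 0, 3]]
        )
        assert np.allclose(rep.per_class_tpr, [1.0, 0.8, 0.6])
        assert rep.avg_tpr == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.8)
        # column sums equal the true class counts
        assert np.array_equal(rep.confusion.sum(axis=0), [5, 5, 5])

    def test_absent_true_class_excluded_from_mean(self):
        rep = evaluate_predictions([A, A, B, B], [A, A, B, B], UPPER_TARGETS)
        assert np.isnan(rep.per_class_tpr[2])
        assert rep.avg_tpr == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_predictions([A], [A, B], UPPER_TARGETS)

    def test_random_predictions_near_chance(self, rng):
        n = 30000
        truth = [UPPER_TARGETS[i] for i in rng.integers(0, 3, n)]
        predicted = [UPPER_TARGETS[i] for i in rng.integers(0, 3, n)]
        rep = evaluate_predictions(predicted, truth, UPPER_TARGETS)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(rep.accuracy - 1 / 3) < 3 * se


class TestSubjectLevelReport:
    def test_single_video_per_subject_is_identity(self):
        rep = evaluate_predictions([A, B, C], [A, B, C], UPPER_TARGETS)
        out = subject_level_report([("s0", rep)])
        assert out.mean_accuracy == rep.accuracy
        assert out.per_subject["s0"].avg_tpr == rep.avg_tpr

    def test_videos_average_within_subject_first(self):
        r1 = evaluate_predictions([A, B, C, A, C], [A, B, C, B, A], UPPER_TARGETS)
        r2 = evaluate_predictions([A, B, C], [A, B, C], UPPER_TARGETS)
        r3 = evaluate_predictions([A, A, A], [A, B, C], UPPER_TARGETS)
        out = subject_level_report([("s0", r1), ("s0", r2), ("s1", r3)])
        s0_acc = (r1.accuracy + r2.accuracy) / 2
        assert out.per_subject["s0"].accuracy == pytest.approx(s0_acc)
        assert out.mean_accuracy == pytest.approx((s0_acc + r3.accuracy) / 2)
        # permutation invariance
        out2 = subject_level_report([("s1", r3), ("s0", r2), ("s0", r1)])
        assert out2.mean_avg_tpr == pytest.approx(out.mean_avg_tpr)


class TestGridSearch:
    @staticmethod
    def _feature_db(rng, n_per_class=30, separation=6.0):
        """Two-factor pixel data: class separation only appears with >= 2
        retained components."""
        meta, rows = [], []
        i = 0
        for si, subject in enumerate(["s0", "s1", "s2"]):
            for cls_idx, cls in enumerate(UPPER_TARGETS):
                for _ in range(n_per_class):
                    # dominant nuisance factor on pixel 0, class signal on 1-2
                    nuisance = rng.normal(scale=20.0)
                    signal = np.zeros(2)
                    if cls_idx:
                        signal[cls_idx - 1] = separation
                    px = np.concatenate(
                        [[nuisance], signal + rng.normal(scale=1.0, size=2)]
                    )
                    rows.append(px)
                    meta.append(RowMeta(f"{subject}_v0", i, subject, cls))
                    i += 1
        return ImageDatabase(np.array(rows), meta, Region.UPPER, (1, 3))

    def test_single_point_grid(self, rng):
        db = self._feature_db(rng)
        sets = undersample_balanced(db, 1, seed=0)
        parts = make_across_subject_partitions(db, min_train=30, min_test=10)
        grid = ParameterGrid(
            k_values=(3,), pc_expl_var_values=(95.0,), metrics=("euclidean",)
        )
        result = grid_search(db, sets, parts, grid)
        assert result.best["k"] == 3
        assert result.best["pc_expl_var"] == 95.0
        assert len(result.surface) == 1

    def test_multifactor_data_needs_enough_components(self, rng):
        """The nuisance factor dominates PC1, so grid points that retain a
        single component stay near chance while >= 3-component points win;
        verified against an exhaustively computed surface."""
        db = self._feature_db(rng)
        sets = undersample_balanced(db, 2, seed=0)
        parts = make_across_subject_partitions(db, min_train=30, min_test=10)
        grid = ParameterGrid(
            k_values=(1, 5),
            pc_expl_var_values=(50.0, 99.0),
            metrics=("euclidean",),
        )
        result = grid_search(db, sets, parts, grid)
        surf = result.surface
        lo = surf[surf.pc_expl_var == 50.0].avg_tpr.max()
        hi = surf[surf.pc_expl_var == 99.0].avg_tpr.max()
        assert hi > lo + 0.2
        assert result.best["pc_expl_var"] == 99.0
        # the reported winner equals independent re-evaluation (no leakage)
        best = result.best
        bset = {s.set_index: s for s in sets}[best["set_index"]]
        scores = []
        for part in parts:
            tr = np.intersect1d(bset.row_indices, part.train_rows)
            rep = evaluate_configuration(
                db, tr, part.test_rows, best["pc_expl_var"],
                ClassifierConfig("knn", k=best["k"], metric=best["metric"]),
            )
            scores.append(rep.avg_tpr)
        assert np.mean(scores) == pytest.approx(best["score"])

    def test_tie_breaks_toward_smaller_k(self, rng):
        # deterministic, perfectly separable -> many grid points tie at 1.0
        db = self._feature_db(rng, separation=50.0)
        sets = undersample_balanced(db, 1, seed=0)
        parts = make_across_subject_partitions(db, min_train=30, min_test=10)
        grid = ParameterGrid(
            k_values=(1, 3, 5), pc_expl_var_values=(99.0,),
            metrics=("euclidean",),
        )
        result = grid_search(db, sets, parts, grid)
        assert result.best["k"] == 1


def test_train_test_disjoint_in_all_designs(upper_db):
    for parts in (
        make_within_subject_partitions(upper_db, min_train=5, min_test=2),
        make_across_subject_partitions(upper_db, min_train=10, min_test=4),
        make_holdout_splits(upper_db, np.arange(upper_db.n_images), n_splits=5),
    ):
        assert parts
        for p in parts:
            assert np.intersect1d(p.train_rows, p.test_rows).size == 0
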