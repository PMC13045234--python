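import numpy as np
import pandas as pd
import pytest

from throatsense import synthgen
from throatsense.evaluation import (
    EvaluationReport,
    FoldReport,
    SplitPlan,
    confusion_matrix,
    evaluate_fold,
    make_split,
)
from throatsense.recognizer import FeatureDataset


def _manifest(n_subjects, reps):
    rows = []
    for s in range(n_subjects):
        for e in synthgen.EMOTIONS:
            for t in range(5):
                for r in range(reps):
                    rows.append(dict(
                        recording_id=synthgen.recording_id(s, e, t, r),
                        subject_id=s, emotion=e, sentence_id=t, repetition=r, seed=0,
                    ))
    return pd.DataFrame(rows)


class TestMakeSplit:
    def test_900_300_protocol(self):
        manifest = _manifest(4, 10)
        plan = make_split(manifest, held_out_subject=3, seed=0)
        assert len(plan.train_ids) + len(plan.val_ids) == 900
        assert len(plan.test_ids) == 300
        assert len(plan.val_ids) == round(0.2 * 900)

    def test_test_set_balanced(self):
        manifest = _manifest(4, 10)
        plan = make_split(manifest, 3, seed=0)
        held = manifest[manifest.recording_id.isin(plan.test_ids)]
        assert (held.groupby("emotion").size() == 50).all()
        assert (held.groupby("sentence_id").size() == 60).all()

    def test_two_subject_minimal(self):
        manifest = _manifest(2, 1)
        plan = make_split(manifest, 1, seed=5)
        assert len(plan.test_ids) == 30
        assert len(plan.train_ids) + len(plan.val_ids) == 30

    def test_deterministic(self):
        manifest = _manifest(3, 2)
        p1 = make_split(manifest, 0, seed=9)
        p2 = make_split(manifest, 0, seed=9)
        assert p1.train_ids == p2.train_ids
        assert p1.val_ids == p2.val_ids

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError, match="unknown subject"):
            make_split(_manifest(2, 1), 5, seed=0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_split(_manifest(1, 1), 0, seed=0)

    def test_no_overlap_validated(self):
        with pytest.raises(ValueError, match="disjoint"):
            SplitPlan(0, ["a", "b"], ["b"], ["c"], 0.2, 0)


class _ConstantModel:
    """Test double: predicts a fixed class pair for every input."""

    def __init__(self, emotion_idx=0, text_idx=0):
        self.e, self.t = emotion_idx, text_idx


def _fake_dataset(n_per_emotion=10):
    n = 6 * n_per_emotion
    feats = np.zeros((n, 40, 128), dtype=np.float32)
    ye = np.repeat(np.arange(6), n_per_emotion)
    yt = np.arange(n) % 5
    return FeatureDataset(feats, ye, yt, np.zeros(n, dtype=int))


class TestEvaluateFold:
    def test_perfect_predictor_diagonal(self, monkeypatch):
        ds = _fake_dataset()
        import throatsense.evaluation as ev

        monkeypatch.setattr(
            ev, "predict_labels",
            lambda trained, feats: (ds.emotion_labels, ds.text_labels),
        )
        report = evaluate_fold(object(), ds)
        assert report.emotion_accuracy == 1.0
        assert report.text_accuracy == 1.0
        assert np.all(report.emotion_confusion == np.diag(np.full(6, 10)))

    def test_all_one_class_accuracy_one_sixth(self, monkeypatch):
        ds = _fake_dataset()
        import throatsense.evaluation as ev

        monkeypatch.setattr(
            ev, "predict_labels",
            lambda trained, feats: (np.zeros(len(ds), dtype=int), np.zeros(len(ds), dtype=int)),
        )
        report = evaluate_fold(object(), ds)
        assert report.emotion_accuracy == pytest.approx(1 / 6)

    def test_uniform_random_near_chance(self, monkeypatch):
        rng = np.random.default_rng(0)
        ds = _fake_dataset(n_per_emotion=50)
        import throatsense.evaluation as ev

        monkeypatch.setattr(
            ev, "predict_labels",
            lambda trained, feats: (
                rng.integers(0, 6, len(ds)), rng.integers(0, 5, len(ds))
            ),
        )
        report = evaluate_fold(object(), ds)
        n, p = len(ds), 1 / 6
        ci = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(report.emotion_accuracy - p) < ci

    def test_absent_class_precision_is_missing(self, monkeypatch):
        ds = _fake_dataset()
        keep = ds.emotion_labels != 5  # drop Surprise from the test set
        ds = ds.subset(np.flatnonzero(keep))
        import throatsense.evaluation as ev

        monkeypatch.setattr(
            ev, "predict_labels",
            lambda trained, feats: (ds.emotion_labels, ds.text_labels),
        )
        report = evaluate_fold(object(), ds)
        assert report.emotion_precision["Surprise"] is None
        assert report.emotion_precision["Angry"] == 1.0

    def test_marginals_equal_label_counts(self, monkeypatch):
        rng = np.random.default_rng(3)
        ds = _fake_dataset()
        import throatsense.evaluation as ev

        monkeypatch.setattr(
            ev, "predict_labels",
            lambda trained, feats: (
                rng.integers(0, 6, len(ds)), rng.integers(0, 5, len(ds))
            ),
        )
        report = evaluate_fold(object(), ds)
        np.testing.assert_array_equal(
            report.emotion_confusion.sum(axis=1),
            np.bincount(ds.emotion_labels, minlength=6),
        )
        np.testing.assert_array_equal(
            report.text_confusion.sum(axis=1),
            np.bincount(ds.text_labels, minlength=5),
        )


class TestLosoStructure:
    def test_folds_partition_corpus(self):
        manifest = _manifest(4, 2)
        all_test = []
        for s in range(4):
            plan = make_split(manifest, s, seed=1)
            all_test.extend(plan.test_ids)
        assert sorted(all_test) == sorted(manifest.recording_id)

    def test_confusion_matrix_helper(self):
        m = confusion_matrix([0, 1, 1, 2], [0, 1, 2, 2], 3)
        assert m[0, 0] == 1 and m[1, 1] == 1 and m[1, 2] == 1 and m[2, 2] == 1
        assert m.sum() == 4

    def test_report_serialization(self):
        fold = FoldReport(
            held_out_subject=0,
            emotion_confusion=np.eye(6, dtype=int) * 5,
            text_confusion=np.eye(5, dtype=int) * 6,
            emotion_accuracy=1.0, text_accuracy=1.0,
            emotion_precision={e: 1.0 for e in synthgen.EMOTIONS},
            text_precision={str(i): 1.0 for i in range(5)},
            n_test=30,
        )
        report = EvaluationReport(
            folds=[fold], mean_emotion_accuracy=1.0, sd_emotion_accuracy=0.0,
            mean_text_accuracy=1.0, sd_text_accuracy=0.0, seed=0,
        )
        d = report.to_dict()
        assert d["folds"][0]["emotion_accuracy"] == 1.0
        md = report.to_markdown()
        assert "held-out subject 0" in md
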