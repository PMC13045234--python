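"""Leave-one-subject-out cross-validation and reporting.

Each fold holds out every recording of one subject; the remaining
subjects' recordings are split 80/20 into training and validation.
Confusion matrices use fixed class orders: emotions alphabetically,
sentences by id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recognizer import (
    FeatureDataset,
    ModelConfig,
    TrainedModel,
    build_model,
    predict_labels,
    train,
)
from .synthgen import EMOTIONS

__all__ = [
    "SplitPlan",
    "FoldReport",
    "EvaluationReport",
    "make_split",
    "evaluate_fold",
    "run_loso",
    "confusion_matrix",
]

VAL_FRACTION = 0.2


@dataclass
class SplitPlan:
    held_out_subject: int
    train_ids: list
    val_ids: list
    test_ids: list
    val_fraction: float
    split_seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split sets must be pairwise disjoint")


@dataclass
class FoldReport:
    held_out_subject: int
    emotion_confusion: np.ndarray  # (6, 6) rows = true class
    text_confusion: np.ndarray  # (5, 5)
    emotion_accuracy: float
    text_accuracy: float
    emotion_precision: dict  # class name -> precision or None when undefined
    text_precision: dict
    n_test: int


@dataclass
class EvaluationReport:
    folds: list  # FoldReport per held-out subject
    mean_emotion_accuracy: float
    sd_emotion_accuracy: float
    mean_text_accuracy: float
    sd_text_accuracy: float
    seed: int

    def to_dict(self) -> dict:
        return dict(
            seed=self.seed,
            mean_emotion_accuracy=self.mean_emotion_accuracy,
            sd_emotion_accuracy=self.sd_emotion_accuracy,
            mean_text_accuracy=self.mean_text_accuracy,
            sd_text_accuracy=self.sd_text_accuracy,
            folds=[
                dict(
                    held_out_subject=f.held_out_subject,
                    emotion_accuracy=f.emotion_accuracy,
                    text_accuracy=f.text_accuracy,
                    emotion_confusion=f.emotion_confusion.tolist(),
                    text_confusion=f.text_confusion.tolist(),
                    emotion_precision=f.emotion_precision,
                    text_precision=f.text_precision,
                    n_test=f.n_test,
                )
                for f in self.folds
            ],
        )

    def to_markdown(self) -> str:
        lines = [
            "# Evaluation report",
            "",
            f"Mean emotion accuracy: {self.mean_emotion_accuracy:.4f} "
            f"± {self.sd_emotion_accuracy:.4f}",
            f"Mean text accuracy: {self.mean_text_accuracy:.4f} "
            f"± {self.sd_text_accuracy:.4f}",
            "",
        ]
        for f in self.folds:
            lines += [
                f"## Fold: held-out subject {f.held_out_subject} (n={f.n_test})",
                f"emotion accuracy {f.emotion_accuracy:.4f}, "
                f"text accuracy {f.text_accuracy:.4f}",
                "",
                "Emotion confusion (rows = true):",
                "",
                _matrix_md(f.emotion_confusion, list(EMOTIONS)),
                "",
                "Text confusion (rows = true):",
                "",
                _matrix_md(f.text_confusion, [f"t{i}" for i in range(5)]),
                "",
            ]
        return "\n".join(lines)


def _matrix_md(m: np.ndarray, names: list) -> str:
    head = "| | " + " | ".join(names) + " |"
    sep = "|---" * (len(names) + 1) + "|"
    rows = [
        "| " + names[i] + " | " + " | ".join(str(int(v)) for v in m[i]) + " |"
        for i in range(len(names))
    ]
    return "\n".join([head, sep] + rows)


def make_split(manifest: pd.DataFrame, held_out_subject: int, seed: int) -> SplitPlan:
    """Deterministic leave-one-subject-out split of a corpus manifest."""
    subjects = set(manifest["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    if held_out_subject not in subjects:
        raise ValueError(
            f"unknown subject {held_out_subject}; manifest has {sorted(subjects)}"
        )
    test_mask = manifest["subject_id"] == held_out_subject
    test_ids = manifest.loc[test_mask, "recording_id"].tolist()
    pool = manifest.loc[~test_mask, "recording_id"].tolist()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    n_val = int(round(VAL_FRACTION * len(pool)))
    val_ids = [pool[i] for i in order[:n_val]]
    train_ids = [pool[i] for i in order[n_val:]]
    return SplitPlan(
        held_out_subject=held_out_subject, train_ids=train_ids, val_ids=val_ids,
        test_ids=test_ids, val_fraction=VAL_FRACTION, split_seed=seed,
    )


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return m


def _precision(m: np.ndarray, names) -> dict:
    out = {}
    for j, name in enumerate(names):
        if m[j].sum() == 0:  # class absent from the test set
            out[str(name)] = None
            continue
        denom = m[:, j].sum()
        out[str(name)] = float(m[j, j] / denom) if denom else 0.0
    return out


def evaluate_fold(trained: TrainedModel, test_set: FeatureDataset) -> FoldReport:
    """Confusion matrices and accuracies on one held-out subject."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    pe, pt = predict_labels(trained, test_set.features)
    me = confusion_matrix(test_set.emotion_labels, pe, 6)
    mt = confusion_matrix(test_set.text_labels, pt, 5)
    subject = int(test_set.subject_ids[0])
    return FoldReport(
        held_out_subject=subject,
        emotion_confusion=me,
        text_confusion=mt,
        emotion_accuracy=float(np.trace(me) / me.sum()),
        text_accuracy=float(np.trace(mt) / mt.sum()),
        emotion_precision=_precision(me, EMOTIONS),
        text_precision=_precision(mt, range(5)),
        n_test=len(test_set),
    )


def run_loso(
    dataset: FeatureDataset,
    manifest: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    verbose: bool = False,
) -> EvaluationReport:
    """One fold per subject; returns per-fold reports plus mean ± SD."""
    subjects = sorted(set(int(s) for s in dataset.subject_ids))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    id_to_idx = {rid: i for i, rid in enumerate(dataset.recording_ids)}
    folds = []
    for subject in subjects:
        plan = make_split(manifest, subject, seed)
        tr = dataset.subset([id_to_idx[r] for r in plan.train_ids])
        va = dataset.subset([id_to_idx[r] for r in plan.val_ids])
        te = dataset.subset([id_to_idx[r] for r in plan.test_ids])
        import dataclasses

        fold_config = dataclasses.replace(config, seed=seed + subject)
        model = build_model(fold_config)
        trained = train(model, tr, va, fold_config, verbose=verbose)
        folds.append(evaluate_fold(trained, te))
    acc_e = np.array([f.emotion_accuracy for f in folds])
    acc_t = np.array([f.text_accuracy for f in folds])
    return EvaluationReport(
        folds=folds,
        mean_emotion_accuracy=float(acc_e.mean()),
        sd_emotion_accuracy=float(acc_e.std(ddof=0)),
        mean_text_accuracy=float(acc_t.mean()),
        sd_text_accuracy=float(acc_t.std(ddof=0)),
        seed=seed,
    )
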