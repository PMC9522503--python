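"""Metrics, confusion matrices and subject-level cross-validation plans.

Scoring agreement between expert and model hypnograms uses the field's
standard summary statistics computed from the pooled 5x5 confusion matrix
(rows = expert label, columns = model output, stage order W, N1, N2, N3, REM):

    ACC   = trace / total
    Pre_i = TP_i / column_i,  Rec_i = TP_i / row_i,
    F1_i  = 2 Pre_i Rec_i / (Pre_i + Rec_i)
    MF1   = unweighted mean of the five F1_i
    kappa = (p0 - pe) / (1 - pe),  pe = sum_i row_i * col_i / M^2

Classes absent from both rows and columns report Pre/Rec/F1 = 0 with a
warning (relevant on small synthetic runs).  Cross-validation is always at
the subject level: both nights of a subject stay in the same split.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .stages import N_STAGES, STAGES


@dataclasses.dataclass
class ConfusionMatrix:
    """5x5 counts, rows = expert label, columns = model output."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_STAGES, N_STAGES) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 5x5 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclasses.dataclass
class MetricReport:
    """Overall and per-class agreement statistics (fractions, not percent)."""

    accuracy: float
    macro_f1: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    def rounded(self) -> dict:
        """Display rounding: percentages to 1 decimal, kappa to 2 decimals."""
        return {
            "ACC": round(self.accuracy * 100, 1),
            "MF1": round(self.macro_f1 * 100, 1),
            "kappa": round(self.kappa, 2),
            "per_class": {
                STAGES[i]: {
                    "Pre": round(self.precision[i] * 100, 1),
                    "Rec": round(self.recall[i] * 100, 1),
                    "F1": round(self.f1[i] * 100, 1),
                }
                for i in range(N_STAGES)
            },
        }

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
        }


def confusion(true: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    """Count matrix: counts[i, j] = #{n : true_n = i, predicted_n = j}."""
    true = np.asarray(true, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if true.shape != predicted.shape:
        raise ValueError(f"length mismatch: {true.shape} vs {predicted.shape}")
    return ConfusionMatrix(_sk_confusion(true, predicted, labels=np.arange(N_STAGES)))


def metrics(cm: ConfusionMatrix | np.ndarray) -> MetricReport:
    """Compute the report from confusion counts (see module docstring)."""
    counts = (cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)).astype(float)
    if counts.shape != (N_STAGES, N_STAGES):
        raise ValueError("expected a 5x5 confusion matrix")
    M = counts.sum()
    if M <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pre = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        rec = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        denom = pre + rec
        f1 = np.where(denom > 0, 2 * pre * rec / np.where(denom > 0, denom, 1), 0.0)
    empty = (col == 0) & (row == 0)
    if empty.any():
        warnings.warn(
            f"classes with zero support report Pre/Rec/F1 = 0: "
            f"{[STAGES[i] for i in np.nonzero(empty)[0]]}",
            stacklevel=2,
        )
    p0 = tp.sum() / M
    pe = float((row * col).sum()) / (M * M)
    kappa = (p0 - pe) / (1 - pe) if pe < 1 else 1.0
    return MetricReport(
        accuracy=float(p0),
        macro_f1=float(f1.mean()),
        kappa=float(kappa),
        precision=pre,
        recall=rec,
        f1=f1,
    )


@dataclasses.dataclass
class FoldPlan:
    """Per-fold subject assignment to train/validation/test."""

    folds: list[dict[str, list[str]]]  # subject ids per split
    recordings_by_subject: dict[str, list[str]]

    def recording_split(self, fold: int) -> dict[str, list[str]]:
        """Recording ids per split for one fold."""
        return {
            split: [
                rec
                for subj in self.folds[fold][split]
                for rec in self.recordings_by_subject[subj]
            ]
            for split in ("train", "validation", "test")
        }


def make_folds(
    recordings: Mapping[str, str],
    k: int,
    n_validation_subjects: int = 4,
    seed: int = 0,
) -> FoldPlan:
    """Subject-level k-fold plan (leave-one-or-more-subjects-out).

    ``recordings`` maps recording_id -> subject_id; all recordings of a
    subject are co-assigned.  Subjects are shuffled once with ``seed``, test
    subjects are the i-th of k near-equal chunks, validation subjects are the
    next ``n_validation_subjects`` in cyclic order, and the rest train.  Test
    chunks partition the subjects across folds.
    """
    by_subject: dict[str, list[str]] = {}
    for rec, subj in recordings.items():
        by_subject.setdefault(str(subj), []).append(str(rec))
    subjects = sorted(by_subject)
    if k > len(subjects):
        raise ValueError(f"k={k} folds but only {len(subjects)} subjects")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_validation_subjects + (len(subjects) + k - 1) // k >= len(subjects):
        raise ValueError("not enough subjects for the requested validation size")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    chunks = [list(c) for c in np.array_split(np.asarray(order, dtype=object), k)]
    folds = []
    for i, test in enumerate(chunks):
        rest = [s for s in order if s not in set(test)]
        validation = rest[:n_validation_subjects]
        train = rest[n_validation_subjects:]
        folds.append(
            {"train": train, "validation": validation, "test": [str(s) for s in test]}
        )
    return FoldPlan(folds=folds, recordings_by_subject=by_subject)


def plot_hypnogram(true, predicted, path=None, recording_id: str = ""):
    """Expert-vs-model hypnogram plot (optional; requires matplotlib).

    Stages are drawn on the conventional axis with Wake on top and deeper
    sleep lower.  Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [0, 4, 1, 2, 3]  # display depth: W, REM, N1, N2, N3
    depth = np.empty(N_STAGES, dtype=int)
    depth[order] = np.arange(N_STAGES)
    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    for ax, labels, title in zip(axes, (true, predicted), ("expert", "model")):
        ax.step(np.arange(len(labels)), -depth[np.asarray(labels)], where="post")
        ax.set_yticks(-np.arange(N_STAGES))
        ax.set_yticklabels([STAGES[i] for i in order])
        ax.set_ylabel(title)
    axes[1].set_xlabel("epoch")
    if recording_id:
        axes[0].set_title(recording_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def pooled_confusion(cms: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Sum per-fold confusion matrices (metric additivity over folds)."""
    total = ConfusionMatrix(np.zeros((N_STAGES, N_STAGES), dtype=np.int64))
    for cm in cms:
        total = total + cm
    return total
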