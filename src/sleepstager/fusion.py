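"""Adjacent-epoch temporal context: accuracy-weighted fusion of predictions.

Each branch emits, for epoch n, a backward prediction P(y_{n-1}|x_n), a
classification P(y_n|x_n) and a forward prediction P(y_{n+1}|x_n).  Deciding
epoch n therefore has three sources: the previous epoch's forward prediction
P(y_n|x_{n-1}), the epoch's own classification P(y_n|x_n), and the next
epoch's backward prediction P(y_n|x_{n+1}).  They are combined as

    P(y_n) = (1/3) * sum_{i=n-1}^{n+1} alpha_i P(y_n|x_i),
    alpha_i = (PreACC(x_i) / ACC(x_n))^2,  alpha_n = 1,

where PreACC/ACC are the prediction/classification accuracies measured on the
validation split, and the label is the argmax of the fused score.  At
recording boundaries the missing neighbor term is dropped and 1/3 becomes
1/(number of present terms).  The two branches are fused independently and
then merged (arithmetic mean of the fused score vectors by default,
elementwise geometric mean behind a flag) before the final argmax.

With all alpha = 1 the scheme reduces to a balanced (unweighted) average of
the available sources, and with fusion disabled each epoch is decided by its
own classification alone.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .stages import N_STAGES


@dataclasses.dataclass
class FusionWeights:
    """Weights alpha = (PreACC/ACC)^2 for the three decision sources."""

    alpha_backward: float  # weight on P(y_n | x_{n-1})
    alpha_current: float  # fixed 1
    alpha_forward: float  # weight on P(y_n | x_{n+1})
    pre_acc_backward: float = float("nan")
    acc_current: float = float("nan")
    pre_acc_forward: float = float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_backward, self.alpha_current, self.alpha_forward])


@dataclasses.dataclass
class FusedScore:
    """Non-negative fused 5-vector and its argmax label for one epoch."""

    scores: np.ndarray
    label: int


def compute_weights(
    pre_acc_backward: float, acc_current: float, pre_acc_forward: float
) -> FusionWeights:
    """Squared accuracy-ratio weights.

    ``pre_acc_backward`` is the accuracy of predicting an epoch from its
    *previous* neighbor (weight on P(y_n|x_{n-1})); ``pre_acc_forward`` that
    from the *next* neighbor.  All accuracies must lie in (0, 1].
    """
    for name, v in (
        ("pre_acc_backward", pre_acc_backward),
        ("acc_current", acc_current),
        ("pre_acc_forward", pre_acc_forward),
    ):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    return FusionWeights(
        alpha_backward=(pre_acc_backward / acc_current) ** 2,
        alpha_current=1.0,
        alpha_forward=(pre_acc_forward / acc_current) ** 2,
        pre_acc_backward=pre_acc_backward,
        acc_current=acc_current,
        pre_acc_forward=pre_acc_forward,
    )


def balanced_weights() -> FusionWeights:
    """The alpha = (1, 1, 1) configuration (balanced fusion)."""
    return FusionWeights(1.0, 1.0, 1.0)


def argmax_with_prevalence(scores: np.ndarray, prevalence: np.ndarray | None = None) -> np.ndarray:
    """Row-wise argmax; exact ties go to the stage more prevalent in training
    (then to the lowest stage index)."""
    scores = np.atleast_2d(scores)
    if prevalence is None:
        return scores.argmax(axis=1)
    prevalence = np.asarray(prevalence, dtype=float)
    best = scores.max(axis=1, keepdims=True)
    tied_prev = np.where(scores == best, prevalence, -np.inf)
    return tied_prev.argmax(axis=1)


def fuse_epoch(
    p_from_prev: np.ndarray | None,
    p_from_self: np.ndarray | None,
    p_from_next: np.ndarray | None,
    weights: FusionWeights,
    prevalence: np.ndarray | None = None,
) -> FusedScore:
    """Fuse the three decision sources for one epoch.

    Absent sources (recording boundaries) are dropped and the averaging
    factor becomes 1/(number of present terms).
    """
    terms = [
        (weights.alpha_backward, p_from_prev),
        (weights.alpha_current, p_from_self),
        (weights.alpha_forward, p_from_next),
    ]
    present = [(a, np.asarray(p, dtype=float)) for a, p in terms if p is not None]
    if not present:
        raise ValueError("all three fusion inputs are absent")
    score = sum(a * p for a, p in present) / len(present)
    label = int(argmax_with_prevalence(score[None, :], prevalence)[0])
    return FusedScore(scores=score, label=label)


def fuse_branch_sequence(context_probs: np.ndarray, weights: FusionWeights) -> np.ndarray:
    """Fuse one branch's per-epoch context triples over a whole recording.

    ``context_probs`` is (n, 3, 5) in head order (backward, current, forward).
    Epoch n pulls P(y_n|x_{n-1}) from the forward head of epoch n-1 and
    P(y_n|x_{n+1}) from the backward head of epoch n+1.  Returns (n, 5)
    fused scores.
    """
    probs = np.asarray(context_probs, dtype=float)
    if probs.ndim != 3 or probs.shape[1:] != (3, N_STAGES):
        raise ValueError(f"expected (n, 3, {N_STAGES}) context probabilities, got {probs.shape}")
    n = probs.shape[0]
    a_b, a_c, a_f = weights.alpha_backward, weights.alpha_current, weights.alpha_forward
    num = a_c * probs[:, 1, :]
    count = np.ones((n, 1))
    if n > 1:
        num[1:] += a_b * probs[:-1, 2, :]  # forward head of previous epoch
        count[1:] += 1
        num[:-1] += a_f * probs[1:, 0, :]  # backward head of next epoch
        count[:-1] += 1
    return num / count


def fuse_recording(
    branch_probs: Sequence[np.ndarray],
    branch_weights: Sequence[FusionWeights],
    merge: str = "mean",
    prevalence: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch weighted fusion, then cross-branch merge, then argmax.

    Parameters
    ----------
    branch_probs
        One (n, 3, 5) context-probability array per branch (TCN, CNN), all of
        equal length n.
    branch_weights
        Matching :class:`FusionWeights` per branch.
    merge
        'mean' (arithmetic, default) or 'geometric' elementwise merge of the
        per-branch fused score vectors.

    Returns
    -------
    labels (n,), merged scores (n, 5)
    """
    if len(branch_probs) != len(branch_weights) or not branch_probs:
        raise ValueError("need one FusionWeights per branch")
    lengths = {np.asarray(p).shape[0] for p in branch_probs}
    if len(lengths) != 1:
        raise ValueError(f"branch sequences have mismatched lengths: {sorted(lengths)}")
    fused = [fuse_branch_sequence(p, w) for p, w in zip(branch_probs, branch_weights)]
    if merge == "mean":
        scores = np.mean(fused, axis=0)
    elif merge == "geometric":
        scores = np.exp(np.mean(np.log(np.clip(fused, 1e-300, None)), axis=0))
    else:
        raise ValueError(f"merge must be 'mean' or 'geometric', got {merge!r}")
    labels = argmax_with_prevalence(scores, prevalence)
    return labels, scores


class ContextFusion(BaseEstimator):
    """Estimator wrapper: calibrate fusion weights, then fuse recordings.

    ``mode``: 'weighted' (squared accuracy ratios), 'balanced' (alpha = 1),
    or 'none' (self-classification only).  ``fit`` consumes the validation
    accuracies recorded by each branch and the training labels (for
    prevalence-based tie-breaking).
    """

    def __init__(self, mode: str = "weighted", merge: str = "mean"):
        self.mode = mode
        self.merge = merge

    def fit(self, branch_accuracies: Sequence[tuple[float, float, float]], y_train=None):
        """``branch_accuracies``: per branch (pre_acc_prev, acc_current,
        pre_acc_next) measured on the validation split."""
        if self.mode not in ("weighted", "balanced", "none"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if self.mode == "weighted":
            self.weights_ = [compute_weights(*acc) for acc in branch_accuracies]
        else:
            self.weights_ = [balanced_weights() for _ in branch_accuracies]
        if y_train is not None:
            y_train = np.asarray(y_train, dtype=np.int64)
            self.prevalence_ = np.bincount(y_train, minlength=N_STAGES).astype(float)
        else:
            self.prevalence_ = None
        return self

    def transform(self, branch_probs: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Fuse one recording's branch outputs -> (labels, scores)."""
        if self.mode == "none":
            scores = np.mean([np.asarray(p)[:, 1, :] for p in branch_probs], axis=0)
            return argmax_with_prevalence(scores, self.prevalence_), scores
        return fuse_recording(
            branch_probs, self.weights_, merge=self.merge, prevalence=self.prevalence_
        )
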