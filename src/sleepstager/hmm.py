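"""Long-epoch temporal context: HMM fine-tuning of fused hypnograms.

The fused per-epoch labels are treated as the *observation* sequence of a
hidden Markov model whose hidden states are the true sleep stages.  The
transition matrix is estimated from bigram counts of the training-set labels
(never pooled across recording boundaries), the emission matrix from the
training-set confusion matrix (row = true stage, column = observed label,
row-normalized), and the initial distribution from the empirical stage
frequencies.  A recording's labels are partitioned into consecutive windows
of length L (default 17) and each window is replaced by its Viterbi-decoded
maximum-likelihood state path, which corrects isolated, transiently
implausible stages inside homogeneous runs (e.g. a single REM epoch inside a
long Wake run becomes Wake under self-dominant transitions).

All decoding is in log space with deterministic ties broken toward the lowest
stage index in the fixed (W, N1, N2, N3, REM) order.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .stages import N_STAGES

DEFAULT_SMOOTHING = 1e-6
DEFAULT_WINDOW_LENGTH = 17


@dataclasses.dataclass
class HmmParameters:
    """Transition/emission/initial parameters plus the decoding window length."""

    transition: np.ndarray  # (S,S) P(true_t | true_{t-1}); S = 5 stages
    emission: np.ndarray  # (S,S) P(observed | true)
    initial: np.ndarray  # (S,)
    window_length: int = DEFAULT_WINDOW_LENGTH

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        n = self.transition.shape[0]
        for name, m in (("transition", self.transition), ("emission", self.emission)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-9):
                raise ValueError(f"{name} rows must be non-negative and sum to 1")
        if self.initial.shape != (n,) or abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError(f"initial must be a {n}-vector distribution")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


def estimate_transition(
    train_labels: Sequence[np.ndarray], smoothing: float = DEFAULT_SMOOTHING
) -> np.ndarray:
    """Row-normalized bigram counts over the training label sequences.

    Bigrams never cross recording boundaries; additive ``smoothing`` is added
    to every cell before normalization.  A stage never observed as a bigram
    source gets a uniform outgoing row (no evidence either way).
    """
    counts = np.zeros((N_STAGES, N_STAGES))
    for seq in train_labels:
        seq = np.asarray(seq, dtype=np.int64)
        if seq.size >= 2:
            np.add.at(counts, (seq[:-1], seq[1:]), 1)
    if counts.sum() == 0:
        raise ValueError("no bigrams: need at least one sequence of length >= 2")
    counts = counts + smoothing
    rowsum = counts.sum(axis=1, keepdims=True)
    empty = rowsum.ravel() == 0
    counts[empty] = 1.0 / N_STAGES
    rowsum[empty] = 1.0
    return counts / rowsum


def estimate_emission(
    train_confusion: np.ndarray, smoothing: float = DEFAULT_SMOOTHING
) -> np.ndarray:
    """P(observed label | true stage) from a (true x predicted) count matrix."""
    counts = np.asarray(train_confusion, dtype=float)
    if counts.shape != (N_STAGES, N_STAGES) or np.any(counts < 0):
        raise ValueError("confusion matrix must be 5x5 with non-negative counts")
    counts = counts + smoothing
    rowsum = counts.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError("a true-stage row is empty and smoothing is 0")
    return counts / rowsum


def estimate_initial(train_labels: Sequence[np.ndarray], smoothing: float = DEFAULT_SMOOTHING) -> np.ndarray:
    """Empirical stage frequencies of the training labels."""
    counts = np.zeros(N_STAGES)
    for seq in train_labels:
        counts += np.bincount(np.asarray(seq, dtype=np.int64), minlength=N_STAGES)
    counts += smoothing
    if counts.sum() == 0:
        raise ValueError("no labels")
    return counts / counts.sum()


def viterbi(obs: np.ndarray, params: HmmParameters) -> np.ndarray:
    """Maximum-likelihood hidden stage path for an observed label sequence.

    Log-space dynamic program; ties break toward the lowest stage index (both
    in the running maximum and in the final state).  Raises if the sequence
    has zero probability under every path (prevented by smoothing).
    """
    obs = np.asarray(obs, dtype=np.int64)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    with np.errstate(divide="ignore"):
        log_tr = np.log(params.transition)
        log_em = np.log(params.emission)
        log_init = np.log(params.initial)
    T = obs.size
    S = params.n_states
    delta = log_init + log_em[:, obs[0]]
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_tr  # (from, to)
        back[t] = cand.argmax(axis=0)  # argmax -> lowest index on ties
        delta = cand[back[t], np.arange(S)] + log_em[:, obs[t]]
    if not np.isfinite(delta.max()):
        raise ValueError("observation sequence has zero probability under all state paths")
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_log_likelihood(states: np.ndarray, obs: np.ndarray, params: HmmParameters) -> float:
    """Joint log-likelihood of a given hidden path and the observations."""
    states = np.asarray(states, dtype=np.int64)
    obs = np.asarray(obs, dtype=np.int64)
    with np.errstate(divide="ignore"):
        ll = np.log(params.initial[states[0]]) + np.log(params.emission[states[0], obs[0]])
        ll += np.sum(np.log(params.transition[states[:-1], states[1:]]))
        ll += np.sum(np.log(params.emission[states[1:], obs[1:]]))
    return float(ll)


def fine_tune_sequence(fused: np.ndarray, params: HmmParameters) -> np.ndarray:
    """Windowed Viterbi fine-tuning of one recording's fused labels.

    The sequence is cut into consecutive windows of ``params.window_length``
    (final remainder window may be shorter); each window is decoded
    independently and replaces the fused labels.  Length is preserved.
    """
    fused = np.asarray(fused, dtype=np.int64)
    if fused.size == 0:
        raise ValueError("empty label sequence")
    L = params.window_length
    out = np.empty_like(fused)
    for start in range(0, fused.size, L):
        out[start : start + L] = viterbi(fused[start : start + L], params)
    return out


def select_window_length(
    validation_fused: Sequence[np.ndarray],
    validation_truth: Sequence[np.ndarray],
    params: HmmParameters,
    candidates: Sequence[int],
) -> int:
    """Candidate window length maximizing validation accuracy after
    fine-tuning; ties go to the smallest candidate."""
    if not candidates:
        raise ValueError("no candidate window lengths")
    best_len, best_acc = None, -1.0
    for L in sorted(candidates):
        p = dataclasses.replace(params, window_length=int(L))
        correct = total = 0
        for fused, truth in zip(validation_fused, validation_truth):
            decoded = fine_tune_sequence(np.asarray(fused), p)
            correct += int((decoded == np.asarray(truth)).sum())
            total += len(truth)
        acc = correct / max(1, total)
        if acc > best_acc:
            best_len, best_acc = int(L), acc
    return best_len


class HmmFineTuner(BaseEstimator):
    """Estimator wrapper around HMM parameter estimation + windowed decoding.

    ``fit`` consumes the training label sequences and the training confusion
    matrix of the upstream classifier; ``predict`` fine-tunes label sequences.
    """

    def __init__(self, window_length: int = DEFAULT_WINDOW_LENGTH, smoothing: float = DEFAULT_SMOOTHING):
        self.window_length = window_length
        self.smoothing = smoothing

    def fit(self, train_label_sequences: Sequence[np.ndarray], train_confusion: np.ndarray):
        self.params_ = HmmParameters(
            transition=estimate_transition(train_label_sequences, self.smoothing),
            emission=estimate_emission(train_confusion, self.smoothing),
            initial=estimate_initial(train_label_sequences, self.smoothing),
            window_length=self.window_length,
        )
        return self

    def predict(self, label_sequences: Sequence[np.ndarray] | np.ndarray):
        single = isinstance(label_sequences, np.ndarray) and np.asarray(label_sequences).ndim == 1
        seqs = [label_sequences] if single else list(label_sequences)
        out = [fine_tune_sequence(np.asarray(s), self.params_) for s in seqs]
        return out[0] if single else out
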