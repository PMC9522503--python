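"""The two one-to-many branch classifiers and their training machinery.

Each branch maps a single epoch to *three* 5-class distributions — a backward
prediction P(y_{n-1}|x_n), the classification P(y_n|x_n), and a forward
prediction P(y_{n+1}|x_n) — and is trained with the summed multitask
cross-entropy so the network is penalized for both misclassification and
misprediction:

    E_i = sum_{j in {n-1, n, n+1}} y_j . log(p_j),
    E = -(1/N) sum_i E_i + (lambda/2) ||theta||^2.

The temporal branch is a dilated causal TCN over the standardized 3000-sample
signal; its receptive field w = 1 + (k-1)(b^n - 1)/(b-1) must reach 3000 so
one output position can see the whole epoch (k=7, n=5, b=5 gives w = 4687).
The spectral branch is a one-layer CNN over the 29x20 filter-bank spectrogram
with kernels spanning the full frequency axis and global 1-max pooling.

Both are exposed as scikit-learn style classifiers (`fit` / `predict_proba` /
`predict_context_proba`); boundary epochs simply drop the missing neighbor
subtask from the loss.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .stages import N_STAGES


# ---------------------------------------------------------------------------
# configs


@dataclasses.dataclass
class TcnConfig:
    """TCN hyperparameters; defaults cover a 3000-sample epoch (w = 4687)."""

    kernel_size: int = 7
    n_layers: int = 5
    dilation_base: int = 5
    n_filters: int = 50
    dropout_rate: float = 0.2
    head_pool: str = "last"

    def __post_init__(self) -> None:
        if self.kernel_size < self.dilation_base:
            raise ValueError(
                "kernel_size must be >= dilation_base for a hole-free receptive field"
            )


@dataclasses.dataclass
class CnnConfig:
    """1-max-pooling CNN hyperparameters.

    ``n_filters_total`` filters are split as evenly as possible across the
    kernel widths (e.g. 400 -> 133/133/134); every kernel spans the full
    20-bin frequency axis.
    """

    kernel_widths: tuple[int, ...] = (3, 5, 7)
    n_filters_total: int = 400
    n_freq: int = 20
    dropout_rate: float = 0.2


@dataclasses.dataclass
class MultitaskLossConfig:
    l2_lambda: float = 1e-3

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


# ---------------------------------------------------------------------------
# receptive-field algebra


def receptive_field(kernel_size: int, n_layers: int, dilation_base: int) -> int:
    """Receptive width of a stack of ``n`` dilated causal convs.

    Layer i uses dilation b^i, so w = 1 + sum_{i=0}^{n-1} (k-1) b^i
    = 1 + (k-1)(b^n - 1)/(b - 1) for b > 1 and 1 + n(k-1) for b = 1.
    """
    k, n, b = kernel_size, n_layers, dilation_base
    if k < 1 or n < 1 or b < 1:
        raise ValueError("kernel_size, n_layers and dilation_base must be >= 1")
    if b == 1:
        return 1 + n * (k - 1)
    return 1 + (k - 1) * (b**n - 1) // (b - 1)


def min_layers(target_length: int, kernel_size: int, dilation_base: int) -> int:
    """Smallest layer count whose receptive field covers ``target_length``."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if target_length == 1:
        return 1
    if kernel_size < 2:
        raise ValueError(
            "kernel_size 1 has a pointwise receptive field; it can never "
            f"cover {target_length} samples"
        )
    n = 1
    while receptive_field(kernel_size, n, dilation_base) < target_length:
        n += 1
    return n


# ---------------------------------------------------------------------------
# loss (probability-space operation)


def multitask_loss(
    outputs: np.ndarray,
    targets: np.ndarray,
    config: MultitaskLossConfig | None = None,
    parameters: dict[str, np.ndarray] | None = None,
) -> float:
    """Summed three-subtask cross-entropy plus L2 penalty.

    ``outputs``: (B, 3, 5) probability triples (backward, current, forward);
    ``targets``: (B, 3, 5) one-hot rows, with an all-zero row marking a
    missing neighbor subtask at a recording boundary (dropped from the sum).
    """
    config = config or MultitaskLossConfig()
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must share a (B, 3, 5) shape")
    rowsum = targets.sum(axis=-1)
    onehot_ok = ((targets == 0) | (targets == 1)).all() and np.isin(rowsum, (0.0, 1.0)).all()
    if not onehot_ok:
        raise ValueError("targets must be one-hot rows (all-zero marks a missing subtask)")
    picked = (targets * np.log(np.clip(outputs, 1e-12, None))).sum(axis=-1)
    loss = -picked.sum() / outputs.shape[0]
    if parameters is not None:
        loss += _nn.l2_penalty(parameters, config.l2_lambda)
    return float(loss)


def context_targets(y: np.ndarray, groups: np.ndarray | None) -> np.ndarray:
    """Per-epoch (y_{n-1}, y_n, y_{n+1}) integer targets, -1 where the
    neighbor lies outside the epoch's recording."""
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    t = np.full((n, 3), -1, dtype=np.int64)
    t[:, 1] = y
    groups = np.zeros(n) if groups is None else np.asarray(groups)
    same_prev = np.zeros(n, dtype=bool)
    same_prev[1:] = groups[1:] == groups[:-1]
    t[same_prev, 0] = y[np.nonzero(same_prev)[0] - 1]
    same_next = np.zeros(n, dtype=bool)
    same_next[:-1] = groups[:-1] == groups[1:]
    t[same_next, 2] = y[np.nonzero(same_next)[0] + 1]
    return t


# ---------------------------------------------------------------------------
# branch estimators


class _BranchClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery for the two one-to-many branches."""

    # subclasses set these
    _input_ndim: int

    def _build_net(self, rng_seed):
        raise NotImplementedError

    def _check_X(self, X) -> np.ndarray:
        raise NotImplementedError

    def fit(
        self,
        X,
        y,
        groups: np.ndarray | None = None,
        X_val=None,
        y_val=None,
        groups_val: np.ndarray | None = None,
    ):
        """Train with Adam on the multitask loss; keep the parameters of the
        epoch with the best validation classification accuracy.

        If no explicit validation split is given, the last
        ``validation_fraction`` of recordings (groups) is held out.
        """
        X = self._check_X(X)
        y = np.asarray(y, dtype=np.int64)
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if groups is None:
            groups = np.zeros(y.size, dtype=int)
        groups = np.asarray(groups)
        if X_val is None:
            X, y, groups, X_val, y_val, groups_val = _holdout_by_group(
                X, y, groups, self.validation_fraction
            )
        else:
            X_val = self._check_X(X_val)
            y_val = np.asarray(y_val, dtype=np.int64)
            if groups_val is None:
                groups_val = np.zeros(y_val.size, dtype=int)
        if y_val.size == 0 or y.size == 0:
            raise ValueError("empty train or validation split")

        rng = np.random.default_rng(self.seed)
        net = self._build_net(rng)
        targets = context_targets(y, groups)
        opt = _nn.AdamOptimizer(lr=self.learning_rate)
        n = X.shape[0]
        best = (-1.0, copy.deepcopy(net.params), 0)
        history = []
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits, cache = net.forward(X[idx], train=True, rng=rng, return_cache=True)
                loss, dlogits = _nn.multitask_logits_loss(logits, targets[idx])
                loss += _nn.l2_penalty(net.params, self.l2_lambda)
                grads = net.backward(cache, dlogits)
                _nn.add_l2_grads(grads, net.params, self.l2_lambda)
                opt.step(net.params, grads)
                losses.append(loss)
            val_acc = _classification_accuracy(net, X_val, y_val, self.batch_eval)
            history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc})
            if val_acc > best[0]:
                best = (val_acc, copy.deepcopy(net.params), epoch)
        net.params = best[1]
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best[2]
        self.classes_ = np.arange(N_STAGES)
        # accuracies the weighted-fusion stage needs, measured on validation
        probs = self._context_proba(net, X_val)
        vt = context_targets(y_val, groups_val)
        self.acc_current_ = _masked_acc(probs[:, 1], vt[:, 1])
        # PreACC of the previous epoch: forward head predicting y_{n+1}
        self.pre_acc_prev_ = _masked_acc(probs[:, 2], vt[:, 2])
        # PreACC of the next epoch: backward head predicting y_{n-1}
        self.pre_acc_next_ = _masked_acc(probs[:, 0], vt[:, 0])
        self.validation_accuracy_ = best[0]
        return self

    def _context_proba(self, net, X, batch: int | None = None) -> np.ndarray:
        batch = batch or self.batch_eval
        out = []
        for start in range(0, X.shape[0], batch):
            out.append(_nn.softmax(net.forward(X[start : start + batch]), axis=-1))
        return np.concatenate(out) if out else np.empty((0, 3, N_STAGES))

    def predict_context_proba(self, X) -> np.ndarray:
        """(n, 3, 5) probabilities: backward, current, forward heads."""
        check_is_fitted(self, "net_")
        return self._context_proba(self.net_, self._check_X(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.predict_context_proba(X)[:, 1, :]

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def _holdout_by_group(X, y, groups, fraction):
    uniq = list(dict.fromkeys(groups.tolist()))  # stable order
    n_val = max(1, int(round(len(uniq) * fraction))) if len(uniq) > 1 else 0
    if n_val == 0:
        # single recording: hold out the tail epochs
        cut = max(1, int(round(y.size * (1 - fraction))))
        return X[:cut], y[:cut], groups[:cut], X[cut:], y[cut:], groups[cut:]
    val_groups = set(uniq[-n_val:])
    mask = np.asarray([g in val_groups for g in groups])
    return X[~mask], y[~mask], groups[~mask], X[mask], y[mask], groups[mask]


def _classification_accuracy(net, X, y, batch: int) -> float:
    correct = 0
    for start in range(0, X.shape[0], batch):
        logits = net.forward(X[start : start + batch])
        correct += int((logits[:, 1, :].argmax(axis=1) == y[start : start + batch]).sum())
    return correct / max(1, y.size)


def _masked_acc(probs: np.ndarray, targets: np.ndarray) -> float:
    mask = targets >= 0
    if not mask.any():
        return float("nan")
    return float((probs[mask].argmax(axis=1) == targets[mask]).mean())


class TcnBranchClassifier(_BranchClassifier):
    """Dilated causal TCN over standardized raw epochs (n, 3000)."""

    def __init__(
        self,
        kernel_size: int = 7,
        n_layers: int = 5,
        dilation_base: int = 5,
        n_filters: int = 50,
        dropout_rate: float = 0.2,
        head_pool: str = "last",
        l2_lambda: float = 1e-3,
        batch_size: int = 20,
        learning_rate: float = 1e-4,
        n_epochs: int = 10,
        validation_fraction: float = 0.2,
        batch_eval: int = 128,
        input_length: int = 3000,
        seed: int = 0,
    ):
        self.kernel_size = kernel_size
        self.n_layers = n_layers
        self.dilation_base = dilation_base
        self.n_filters = n_filters
        self.dropout_rate = dropout_rate
        self.head_pool = head_pool
        self.l2_lambda = l2_lambda
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.validation_fraction = validation_fraction
        self.batch_eval = batch_eval
        self.input_length = input_length
        self.seed = seed

    def _build_net(self, rng):
        return _nn.TcnNetwork(
            kernel_size=self.kernel_size,
            n_layers=self.n_layers,
            dilation_base=self.dilation_base,
            n_filters=self.n_filters,
            dropout_rate=self.dropout_rate,
            head_pool=self.head_pool,
            seed=rng,
        )

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ValueError(
                f"TCN branch expects (n, {self.input_length}) standardized "
                f"epochs, got {X.shape}"
            )
        return X


class CnnBranchClassifier(_BranchClassifier):
    """1-max-pooling CNN over filter-bank spectrograms (n, frames, 20)."""

    def __init__(
        self,
        kernel_widths: tuple[int, ...] = (3, 5, 7),
        n_filters_total: int = 400,
        n_freq: int = 20,
        dropout_rate: float = 0.2,
        l2_lambda: float = 1e-3,
        batch_size: int = 20,
        learning_rate: float = 1e-4,
        n_epochs: int = 10,
        validation_fraction: float = 0.2,
        batch_eval: int = 512,
        seed: int = 0,
    ):
        self.kernel_widths = kernel_widths
        self.n_filters_total = n_filters_total
        self.n_freq = n_freq
        self.dropout_rate = dropout_rate
        self.l2_lambda = l2_lambda
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.validation_fraction = validation_fraction
        self.batch_eval = batch_eval
        self.seed = seed

    def _build_net(self, rng):
        return _nn.CnnNetwork(
            kernel_widths=tuple(self.kernel_widths),
            n_filters_total=self.n_filters_total,
            n_freq=self.n_freq,
            dropout_rate=self.dropout_rate,
            seed=rng,
        )

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[2] != self.n_freq:
            raise ValueError(
                f"CNN branch expects (n, frames, {self.n_freq}) spectrograms, "
                f"got {X.shape}"
            )
        return X


# ---------------------------------------------------------------------------
# functional wrappers


def tcn_forward(std_epochs: np.ndarray, net: _nn.TcnNetwork) -> np.ndarray:
    """Deterministic inference: (n, 3000) -> (n, 3, 5) probability triples."""
    X = np.atleast_2d(np.asarray(std_epochs, dtype=np.float32))
    return _nn.softmax(net.forward(X), axis=-1)


def cnn_forward(fb_specs: np.ndarray, net: _nn.CnnNetwork) -> np.ndarray:
    """Deterministic inference: (n, frames, 20) -> (n, 3, 5) triples."""
    X = np.asarray(fb_specs, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    return _nn.softmax(net.forward(X), axis=-1)


def train_branch(X, y, branch: str = "cnn", groups=None, seed: int = 0, **hyperparams):
    """Train one branch ('tcn' or 'cnn') and return the fitted classifier."""
    cls = {"tcn": TcnBranchClassifier, "cnn": CnnBranchClassifier}.get(branch)
    if cls is None:
        raise ValueError(f"branch must be 'tcn' or 'cnn', got {branch!r}")
    est = cls(seed=seed, **hyperparams)
    return est.fit(X, y, groups=groups)
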