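"""Minimal NumPy neural-network core for the two branch networks.

Implements exactly the pieces the sleep-staging branches need — dilated causal
1-D convolutions with residual temporal blocks (TCN), a valid 2-D convolution
over spectrograms whose kernels span the full frequency axis followed by
global 1-max pooling, inverted dropout, three-headed softmax output
(backward / current / forward one-to-many context), the summed multitask
cross-entropy with L2 regularization, and Adam — with hand-written backward
passes.  Everything is float32 and deterministic for a fixed seed on a single
CPU thread.

Parameter containers are plain ``dict[str, np.ndarray]``; gradients mirror the
same keys.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

HEADS = ("backward", "current", "forward")  # predicts y_{n-1}, y_n, y_{n+1}


# ---------------------------------------------------------------------------
# primitives


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout mask: 0 with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0:
        return np.ones(shape, dtype=DTYPE)
    return (rng.random(shape, dtype=np.float32) >= rate).astype(DTYPE) / DTYPE(1.0 - rate)


def causal_conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray, dilation: int):
    """Causal dilated conv: ``y[t] = b + sum_j W[..., j] @ x[t - (k-1-j)*d]``.

    x: (B, Cin, T); W: (Cout, Cin, k); returns y (B, Cout, T) and the im2col
    matrix (cached for backward).  Left zero padding of (k-1)*d keeps input
    and output lengths equal and the stack strictly causal; the whole conv is
    one (B*T, Cin*k) @ (Cin*k, Cout) matmul.
    """
    B, Cin, T = x.shape
    Cout, _, k = W.shape
    pad = (k - 1) * dilation
    xp = np.zeros((B, Cin, T + pad), dtype=DTYPE)
    xp[:, :, pad:] = x
    s = xp.strides
    # cols[b, c, j, t] = xp[b, c, j*d + t]: tap j sees (k-1-j)*d steps back
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(B, Cin, k, T), strides=(s[0], s[1], s[2] * dilation, s[2])
    )
    colm = np.ascontiguousarray(cols.transpose(0, 3, 1, 2)).reshape(B * T, Cin * k)
    Wm = W.reshape(Cout, Cin * k)
    y = (colm @ Wm.T).reshape(B, T, Cout).transpose(0, 2, 1) + b[None, :, None]
    return np.ascontiguousarray(y), colm


def causal_conv1d_backward(
    dy: np.ndarray, colm: np.ndarray, W: np.ndarray, dilation: int, in_channels: int
):
    """Gradients of :func:`causal_conv1d`: returns (dx, dW, db)."""
    B, Cout, T = dy.shape
    Cin, k = in_channels, W.shape[2]
    pad = (k - 1) * dilation
    dym = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * T, Cout)
    Wm = W.reshape(Cout, Cin * k)
    dW = (dym.T @ colm).reshape(Cout, Cin, k)
    db = dy.sum(axis=(0, 2))
    dcols = (dym @ Wm).reshape(B, T, Cin, k)
    dxp = np.zeros((B, Cin, T + pad), dtype=DTYPE)
    for j in range(k):
        dxp[:, :, j * dilation : j * dilation + T] += dcols[:, :, :, j].transpose(0, 2, 1)
    return dxp[:, :, pad:], dW, db


def conv1x1(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Pointwise channel-mixing conv: x (B,Cin,T), W (Cout,Cin)."""
    return np.tensordot(x, W, axes=([1], [1])).transpose(0, 2, 1)


def one_max_pool(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global 1-max pooling over the time axis of feature maps (B, T, F).

    Returns (pooled (B,F), argmax (B,F)).  First-position ties win.
    """
    arg = a.argmax(axis=1)
    pooled = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
    return pooled, arg


# ---------------------------------------------------------------------------
# multitask loss


def multitask_logits_loss(
    logits: np.ndarray, targets: np.ndarray, n_classes: int = 5
) -> tuple[float, np.ndarray]:
    """Summed three-subtask cross-entropy from logits.

    logits: (B, 3, C); targets: (B, 3) integer classes, -1 marking a missing
    neighbor subtask (recording boundary) which is dropped from the sum.
    Returns the batch-mean loss and dlogits (already divided by B).
    """
    B = logits.shape[0]
    probs = softmax(logits, axis=-1)
    mask = targets >= 0
    safe = np.where(mask, targets, 0)
    picked = np.take_along_axis(probs, safe[:, :, None], axis=-1)[..., 0]
    logp = np.log(np.clip(picked, 1e-12, None))
    loss = -(logp * mask).sum() / B
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, safe[:, :, None], 1.0, axis=-1)
    dlogits = (probs - onehot) * mask[:, :, None] / B
    return float(loss), dlogits.astype(DTYPE)


def l2_penalty(params: dict[str, np.ndarray], lam: float) -> float:
    """(lam/2) * ||theta||^2 over weight matrices (biases excluded)."""
    if lam <= 0:
        return 0.0
    return 0.5 * lam * sum(float((v**2).sum()) for k, v in params.items() if not k.endswith("_b"))


def add_l2_grads(grads: dict[str, np.ndarray], params: dict[str, np.ndarray], lam: float) -> None:
    if lam <= 0:
        return
    for k, v in params.items():
        if not k.endswith("_b"):
            grads[k] = grads[k] + lam * v


# ---------------------------------------------------------------------------
# optimizer


class AdamOptimizer:
    """Adam with bias correction, keyed to a parameter dict."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self._m:
                self._m[k] = np.zeros_like(params[k])
                self._v[k] = np.zeros_like(params[k])
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1**self.t)
            vhat = self._v[k] / (1 - b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)


# ---------------------------------------------------------------------------
# heads


def init_heads(n_features: int, n_classes: int, params: dict[str, np.ndarray]) -> None:
    """Three zero-initialized softmax heads (uniform output before training)."""
    for h in HEADS:
        params[f"head_{h}_W"] = np.zeros((n_features, n_classes), dtype=DTYPE)
        params[f"head_{h}_b"] = np.zeros(n_classes, dtype=DTYPE)


def heads_forward(h: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """h (B,F) -> logits (B, 3, C) in HEADS order."""
    return np.stack(
        [h @ params[f"head_{name}_W"] + params[f"head_{name}_b"] for name in HEADS],
        axis=1,
    )


def heads_backward(dlogits: np.ndarray, h: np.ndarray, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> np.ndarray:
    dh = np.zeros_like(h)
    for i, name in enumerate(HEADS):
        dl = dlogits[:, i, :]
        grads[f"head_{name}_W"] = h.T @ dl
        grads[f"head_{name}_b"] = dl.sum(axis=0)
        dh += dl @ params[f"head_{name}_W"].T
    return dh


# ---------------------------------------------------------------------------
# TCN branch


class TcnNetwork:
    """Dilated causal TCN with residual temporal blocks and 3 softmax heads.

    Block *i* (i = 0..n_layers-1) uses dilation ``dilation_base ** i`` and
    holds two dilated causal convolutions, each followed by ReLU and dropout,
    plus a residual connection (pointwise conv where channel counts differ);
    the block output is ReLU(residual + conv path).  The head summarizes the
    feature sequence by its final time step by default ('last'; the causal
    receptive field covers the whole epoch) or by a global average ('mean').
    """

    def __init__(
        self,
        kernel_size: int = 7,
        n_layers: int = 5,
        dilation_base: int = 5,
        n_filters: int = 50,
        dropout_rate: float = 0.2,
        head_pool: str = "last",
        n_classes: int = 5,
        seed: int | np.random.Generator = 0,
    ):
        if kernel_size < dilation_base:
            raise ValueError(
                f"kernel_size ({kernel_size}) must be >= dilation_base "
                f"({dilation_base}) for a hole-free receptive field"
            )
        if head_pool not in ("last", "mean"):
            raise ValueError(f"head_pool must be 'last' or 'mean', got {head_pool!r}")
        self.kernel_size = kernel_size
        self.n_layers = n_layers
        self.dilation_base = dilation_base
        self.n_filters = n_filters
        self.dropout_rate = dropout_rate
        self.head_pool = head_pool
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i in range(n_layers):
            for j in (1, 2):
                cin = c_in if j == 1 else n_filters
                scale = np.sqrt(2.0 / (cin * kernel_size))
                self.params[f"b{i}_conv{j}_W"] = (
                    rng.standard_normal((n_filters, cin, kernel_size)) * scale
                ).astype(DTYPE)
                self.params[f"b{i}_conv{j}_b"] = np.zeros(n_filters, dtype=DTYPE)
            if c_in != n_filters:
                self.params[f"b{i}_res_W"] = (
                    rng.standard_normal((n_filters, c_in)) * np.sqrt(1.0 / c_in)
                ).astype(DTYPE)
            c_in = n_filters
        init_heads(n_filters, n_classes, self.params)

    def dilation(self, i: int) -> int:
        return self.dilation_base**i

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
        return_sequence: bool = False,
    ):
        """X (B, T) standardized samples -> logits (B, 3, n_classes)."""
        p = self.params
        x = np.ascontiguousarray(X, dtype=DTYPE)[:, None, :]  # (B,1,T)
        cache: dict = {"inputs": [], "drop": [], "relu": [], "res": []}
        rate = self.dropout_rate if train else 0.0
        for i in range(self.n_layers):
            d = self.dilation(i)
            layer = {"x": x}
            z1, col1 = causal_conv1d(x, p[f"b{i}_conv1_W"], p[f"b{i}_conv1_b"], d)
            m1 = z1 > 0
            a1 = z1 * m1
            dm1 = dropout_mask(a1.shape, rate, rng) if rate > 0 else None
            a1d = a1 * dm1 if dm1 is not None else a1
            z2, col2 = causal_conv1d(a1d, p[f"b{i}_conv2_W"], p[f"b{i}_conv2_b"], d)
            m2 = z2 > 0
            a2 = z2 * m2
            dm2 = dropout_mask(a2.shape, rate, rng) if rate > 0 else None
            a2d = a2 * dm2 if dm2 is not None else a2
            res = conv1x1(x, p[f"b{i}_res_W"]) if f"b{i}_res_W" in p else x
            pre = a2d + res
            mo = pre > 0
            out = pre * mo
            layer.update(col1=col1, m1=m1, dm1=dm1, a1d=a1d, col2=col2, m2=m2, dm2=dm2, mo=mo)
            cache["inputs"].append(layer)
            x = out
        if return_sequence:
            return x
        if self.head_pool == "last":
            h = x[:, :, -1]
        else:
            h = x.mean(axis=2)
        logits = heads_forward(h, p)
        if return_cache:
            cache["h"] = h
            cache["seq_shape"] = x.shape
            return logits, cache
        return logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dh = heads_backward(dlogits, cache["h"], p, grads)
        B, C, T = cache["seq_shape"]
        dx = np.zeros((B, C, T), dtype=DTYPE)
        if self.head_pool == "last":
            dx[:, :, -1] = dh
        else:
            dx += dh[:, :, None] / T
        for i in reversed(range(self.n_layers)):
            layer = cache["inputs"][i]
            d = self.dilation(i)
            dpre = dx * layer["mo"]
            da2d = dpre
            da2 = da2d * layer["dm2"] if layer["dm2"] is not None else da2d
            dz2 = da2 * layer["m2"]
            da1d, dW2, db2 = causal_conv1d_backward(
                dz2, layer["col2"], p[f"b{i}_conv2_W"], d, self.n_filters
            )
            grads[f"b{i}_conv2_W"] = dW2
            grads[f"b{i}_conv2_b"] = db2
            da1 = da1d * layer["dm1"] if layer["dm1"] is not None else da1d
            dz1 = da1 * layer["m1"]
            cin = layer["x"].shape[1]
            dxin, dW1, db1 = causal_conv1d_backward(
                dz1, layer["col1"], p[f"b{i}_conv1_W"], d, cin
            )
            grads[f"b{i}_conv1_W"] = dW1
            grads[f"b{i}_conv1_b"] = db1
            if f"b{i}_res_W" in p:
                xin = layer["x"]
                grads[f"b{i}_res_W"] = np.tensordot(dpre, xin, axes=([0, 2], [0, 2]))
                dxin = dxin + np.tensordot(p[f"b{i}_res_W"], dpre, axes=([0], [1])).transpose(1, 0, 2)
            else:
                dxin = dxin + dpre
            dx = dxin
        return grads


# ---------------------------------------------------------------------------
# 1-max-pooling CNN branch


class CnnNetwork:
    """One conv layer with mixed kernel widths over the spectrogram, global
    1-max pooling per feature map, dropout, and 3 softmax heads.

    Kernels span the full frequency axis (the filter-bank dimension), so each
    feature map is a 1-D sequence over time frames; 1-max pooling keeps the
    single most prominent activation per map.
    """

    def __init__(
        self,
        kernel_widths: tuple[int, ...] = (3, 5, 7),
        n_filters_total: int = 400,
        n_freq: int = 20,
        dropout_rate: float = 0.2,
        n_classes: int = 5,
        seed: int | np.random.Generator = 0,
    ):
        self.kernel_widths = tuple(kernel_widths)
        self.n_filters_total = n_filters_total
        self.n_freq = n_freq
        self.dropout_rate = dropout_rate
        self.n_classes = n_classes
        n_sizes = len(self.kernel_widths)
        base = n_filters_total // n_sizes
        self.filters_per_width = [base] * n_sizes
        self.filters_per_width[-1] += n_filters_total - base * n_sizes
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for w, f in zip(self.kernel_widths, self.filters_per_width):
            fan_in = w * n_freq
            self.params[f"conv{w}_W"] = (
                rng.standard_normal((fan_in, f)) * np.sqrt(2.0 / fan_in)
            ).astype(DTYPE)
            self.params[f"conv{w}_b"] = np.zeros(f, dtype=DTYPE)
        init_heads(n_filters_total, n_classes, self.params)

    def _columns(self, X: np.ndarray, w: int) -> np.ndarray:
        """(B, T, F) -> (B, T-w+1, w*F) sliding windows along time."""
        win = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)  # (B,T',F,w)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            X.shape[0], X.shape[1] - w + 1, w * X.shape[2]
        )

    def feature_maps(self, X: np.ndarray) -> list[np.ndarray]:
        """Post-ReLU conv feature maps, one (B, T-w+1, F_w) array per width."""
        X = np.asarray(X, dtype=DTYPE)
        maps = []
        for w in self.kernel_widths:
            cols = self._columns(X, w)
            maps.append(relu(cols @ self.params[f"conv{w}_W"] + self.params[f"conv{w}_b"]))
        return maps

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """X (B, n_frames, n_freq) -> logits (B, 3, n_classes)."""
        X = np.asarray(X, dtype=DTYPE)
        if X.ndim != 3 or X.shape[2] != self.n_freq:
            raise ValueError(
                f"expected spectrograms (B, frames, {self.n_freq}), got {X.shape}"
            )
        p = self.params
        pooled, cache_layers = [], []
        for w in self.kernel_widths:
            if X.shape[1] < w:
                raise ValueError(f"spectrogram has {X.shape[1]} frames < kernel width {w}")
            cols = self._columns(X, w)
            z = cols @ p[f"conv{w}_W"] + p[f"conv{w}_b"]  # (B,T',F)
            m = z > 0
            a = z * m
            pool, arg = one_max_pool(a)
            pooled.append(pool)
            cache_layers.append({"cols": cols, "m": m, "arg": arg, "tlen": a.shape[1]})
        h = np.concatenate(pooled, axis=1)  # (B, n_filters_total)
        dm = dropout_mask(h.shape, self.dropout_rate, rng) if train and self.dropout_rate > 0 else None
        hd = h * dm if dm is not None else h
        logits = heads_forward(hd, p)
        if return_cache:
            return logits, {"layers": cache_layers, "h": h, "dm": dm, "hd": hd}
        return logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dhd = heads_backward(dlogits, cache["hd"], p, grads)
        dh = dhd * cache["dm"] if cache["dm"] is not None else dhd
        start = 0
        for w, f, layer in zip(self.kernel_widths, self.filters_per_width, cache["layers"]):
            dpool = dh[:, start : start + f]  # (B,F)
            start += f
            da = np.zeros((dpool.shape[0], layer["tlen"], f), dtype=DTYPE)
            np.put_along_axis(da, layer["arg"][:, None, :], dpool[:, None, :], axis=1)
            dz = da * layer["m"]
            cols = layer["cols"]
            grads[f"conv{w}_W"] = np.tensordot(cols, dz, axes=([0, 1], [0, 1]))
            grads[f"conv{w}_b"] = dz.sum(axis=(0, 1))
        return grads
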