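"""Minimal 1-D convolutional network in numpy.

Forward/backward passes for: valid-mode 1-D convolution, ReLU,
non-overlapping max pooling, fixed-bin average pooling, dense layers, and a
weighted softmax cross-entropy head, trained with Adam.  Written for
CPU-sized single-molecule trace classification; all randomness flows
through an explicit numpy Generator so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1DNet", "softmax", "weighted_cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    probs: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted-mean cross entropy and its gradient w.r.t. the logits."""
    n = len(y)
    w = class_weights[y]
    wsum = w.sum()
    p_true = np.clip(probs[np.arange(n), y], 1e-12, None)
    loss = float((-w * np.log(p_true)).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    # x: (B, C, L); W: (F, C, k) -> y: (B, F, L-k+1)
    k = W.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (B,C,L',k)
    y = np.tensordot(win, W, axes=([1, 3], [1, 2]))  # (B, L', F)
    y = np.ascontiguousarray(y.transpose(0, 2, 1)) + b[None, :, None]
    return y, win


def _conv_backward(dy: np.ndarray, win: np.ndarray, W: np.ndarray, in_len: int):
    # dy: (B, F, L'); win: (B, C, L', k)
    k = W.shape[2]
    dW = np.tensordot(dy, win, axes=([0, 2], [0, 2]))  # (F, C, k)
    db = dy.sum(axis=(0, 2))
    pad = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
    win_dy = np.lib.stride_tricks.sliding_window_view(pad, k, axis=2)  # (B,F,L,k)
    dx = np.tensordot(win_dy, W[:, :, ::-1], axes=([1, 3], [0, 2]))  # (B, L, C)
    return np.ascontiguousarray(dx.transpose(0, 2, 1))[:, :, :in_len], dW, db


def _maxpool_forward(x: np.ndarray, p: int):
    B, F, L = x.shape
    Lp = L // p
    xr = x[:, :, : Lp * p].reshape(B, F, Lp, p)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return y, (idx, x.shape, p)


def _maxpool_backward(dy: np.ndarray, cache):
    idx, shape, p = cache
    B, F, L = shape
    Lp = L // p
    dxr = np.zeros((B, F, Lp, p), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
    dx = np.zeros(shape, dtype=dy.dtype)
    dx[:, :, : Lp * p] = dxr.reshape(B, F, Lp * p)
    return dx


def _avgpool_forward(x: np.ndarray, p: int):
    B, F, L = x.shape
    Lp = L // p
    y = x[:, :, : Lp * p].reshape(B, F, Lp, p).mean(axis=3)
    return y, (x.shape, p)


def _avgpool_backward(dy: np.ndarray, cache):
    shape, p = cache
    B, F, L = shape
    Lp = L // p
    dx = np.zeros(shape, dtype=dy.dtype)
    dx[:, :, : Lp * p] = np.repeat(dy / p, p, axis=2)
    return dx


class Conv1DNet:
    """Conv blocks (conv -> ReLU -> max pool) + average-pool head + dense stack.

    Parameters mirror :class:`~smstoich.cnn.ArchitectureSpec`: a list of
    ``(kernel_size, n_filters)`` conv blocks each followed by non-overlapping
    max pooling of ``pool_size``, an average-pooling head that reduces the
    remaining time axis to about ``head_bins`` bins, then fully connected
    layers ending in ``n_classes`` logits.
    """

    def __init__(
        self,
        input_length: int,
        conv_blocks: list[tuple[int, int]],
        dense: list[int],
        n_classes: int,
        pool_size: int,
        head_bins: int,
        rng: np.random.Generator,
    ):
        if not conv_blocks:
            raise ValueError("need at least one conv block")
        self.input_length = input_length
        self.conv_blocks = [tuple(cb) for cb in conv_blocks]
        self.dense = list(dense)
        self.n_classes = n_classes
        self.pool_size = pool_size

        self.params: dict[str, np.ndarray] = {}
        L, C = input_length, 1
        for i, (k, f) in enumerate(self.conv_blocks):
            if L < k:
                raise ValueError("trace too short for conv stack")
            fan_in = C * k
            self.params[f"Wc{i}"] = (rng.standard_normal((f, C, k)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(f, dtype=np.float32)
            L = (L - k + 1) // pool_size
            C = f
            if L < 1:
                raise ValueError("trace too short for pooling stack")
        self.head_pool = max(1, L // head_bins)
        feat = C * (L // self.head_pool)
        widths = [feat, *self.dense, n_classes]
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            if a == 0 or b == 0:
                # width-zero layer: a degenerate classifier that can never learn
                pass
            self.params[f"Wd{i}"] = (rng.standard_normal((a, b)) * np.sqrt(2.0 / max(a, 1))).astype(np.float32)
            self.params[f"bd{i}"] = np.zeros(b, dtype=np.float32)
        self.n_dense = len(widths) - 1
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Logits for X of shape (B, L)."""
        if X.shape[1] != self.input_length:
            raise ValueError(
                f"input length {X.shape[1]} != model input length {self.input_length}"
            )
        x = X[:, None, :].astype(np.float32)
        cache = [] if want_cache else None
        for i in range(len(self.conv_blocks)):
            y, win = _conv_forward(x, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            mask = y > 0
            y *= mask
            y, mp = _maxpool_forward(y, self.pool_size)
            if want_cache:
                cache.append(("conv", i, win, mask, mp, x.shape[2]))
            x = y
        x, ap = _avgpool_forward(x, self.head_pool)
        B = x.shape[0]
        h = x.reshape(B, -1)
        if want_cache:
            cache.append(("head", ap, x.shape))
        for i in range(self.n_dense):
            z = h @ self.params[f"Wd{i}"] + self.params[f"bd{i}"]
            if i < self.n_dense - 1:
                mask = z > 0
                zr = z * mask
            else:
                mask, zr = None, z
            if want_cache:
                cache.append(("dense", i, h, mask))
            h = zr
        return (h, cache) if want_cache else h

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        d = dlogits
        ci = len(cache) - 1
        for i in range(self.n_dense - 1, -1, -1):
            tag, idx, h, mask = cache[ci]
            ci -= 1
            assert tag == "dense" and idx == i
            grads[f"Wd{i}"] = h.T @ d
            grads[f"bd{i}"] = d.sum(axis=0)
            d = d @ self.params[f"Wd{i}"].T
            if i > 0:
                prev_mask = cache[ci][3]
                if prev_mask is not None:
                    d = d * prev_mask
        tag, ap, shape = cache[ci]
        ci -= 1
        assert tag == "head"
        d = _avgpool_backward(d.reshape(shape), ap)
        for i in range(len(self.conv_blocks) - 1, -1, -1):
            tag, idx, win, mask, mp, in_len = cache[ci]
            ci -= 1
            assert tag == "conv" and idx == i
            d = _maxpool_backward(d, mp)
            d = d * mask
            d, dW, db = _conv_backward(d, win, self.params[f"Wc{i}"], in_len)
            grads[f"Wc{i}"] = dW
            grads[f"bc{i}"] = db
        return grads

    def adam_step(self, grads: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(self.params[k].dtype)

    # -- inference ------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            out.append(softmax(self.forward(X[i : i + batch_size]).astype(np.float64)))
        return np.concatenate(out, axis=0) if out else np.empty((0, self.n_classes))

    # -- (de)serialization ----------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)
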