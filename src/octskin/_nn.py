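"""Minimal CNN engine: im2col convolutions, pooling, dense layers, RMSprop.

Layers implement ``forward(x, train)`` / ``backward(dy)`` on float32 NCHW
tensors and expose ``params`` / ``grads`` lists.  Only what the patch
classifier family needs is implemented: valid/same stride-1 convolutions,
max/average pooling with floor- or ceil-rounded output sizes (ceil windows
are clipped at the border and averages count only real elements), ReLU,
inverted dropout, dense layers, and a fused softmax + cross-entropy head.

Determinism: all randomness flows through explicitly passed
``numpy.random.Generator`` instances; single-threaded numpy arithmetic is
reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "Pool2D",
    "ReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "softmax",
    "cross_entropy",
    "RMSprop",
    "conv_output_size",
    "pool_output_size",
]


def conv_output_size(n: int, kernel: int, padding: str) -> int:
    """Spatial output size of a stride-1 convolution."""
    if padding == "valid":
        out = n - kernel + 1
    elif padding == "same":
        out = n
    else:
        raise ValueError(f"unknown padding {padding!r}")
    return out


def pool_output_size(n: int, kernel: int, stride: int, rounding: str) -> int:
    """Pooling output size on unpadded input: floor-or-ceil((n - k)/s) + 1."""
    if rounding == "floor":
        out = (n - kernel) // stride + 1
    elif rounding == "ceil":
        out = -((n - kernel) // -stride) + 1
    else:
        raise ValueError(f"unknown pool rounding {rounding!r}")
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)


class Conv2D(Layer):
    """Stride-1 2-D convolution (cross-correlation) + bias, NCHW."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: str, rng: np.random.Generator, name: str = "conv"):
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.padding = c_in, c_out, kernel, padding
        self.name = name
        fan_in = c_in * kernel * kernel
        self.w = glorot_uniform(rng, (fan_in, c_out), fan_in, c_out)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None
        self.need_dx = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        if self.padding == "same":
            p0 = (k - 1) // 2
            p1 = k - 1 - p0
            x = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
        b_sz, c, h, w = x.shape
        oh, ow = h - k + 1, w - k + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"{self.name}: output size would be < 1 (input {h}x{w}, kernel {k})")
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (B,C,oh,ow,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b_sz * oh * ow, c * k * k)
        out = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(b_sz, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._xshape is not None
        b_sz, _, oh, ow = dy.shape
        k, c = self.kernel, self.c_in
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.grads[0][...] = self._cols.T @ dy_flat
        self.grads[1][...] = dy_flat.sum(axis=0)
        if not self.need_dx:
            self._cols = None
            return np.empty(0, dtype=np.float32)
        dcols = (dy_flat @ self.w.T).reshape(b_sz, oh, ow, c, k, k)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for dj in range(k):
            for dk in range(k):
                dx[:, :, dj : dj + oh, dk : dk + ow] += dcols[:, :, :, :, dj, dk].transpose(0, 3, 1, 2)
        self._cols = None
        if self.padding == "same":
            p0 = (k - 1) // 2
            h, w = self._xshape[2] - (k - 1), self._xshape[3] - (k - 1)
            dx = dx[:, :, p0 : p0 + h, p0 : p0 + w]
        return dx


class Pool2D(Layer):
    """Max or average pooling with floor/ceil output rounding.

    Ceil rounding lets the last window hang over the border; such windows
    are clipped, and averages divide by the number of real elements.
    """

    def __init__(self, kind: str, kernel: int, stride: int, rounding: str, name: str = "pool"):
        super().__init__()
        if kind not in ("max", "avg"):
            raise ValueError(f"unknown pool type {kind!r}")
        self.kind, self.kernel, self.stride, self.rounding = kind, kernel, stride, rounding
        self.name = name
        self._cache: dict | None = None

    @property
    def _fast(self) -> bool:
        # non-overlapping full windows: slice arithmetic, no window tensors
        return self.kernel == self.stride and self.rounding == "floor"

    def _forward_fast(self, x: np.ndarray, train: bool) -> np.ndarray:
        b_sz, c, h, w = x.shape
        k = self.kernel
        oh, ow = h // k, w // k
        if oh < 1 or ow < 1:
            raise ValueError(f"{self.name}: output size would be < 1")
        if self.kind == "max":
            out = x[:, :, 0 : oh * k : k, 0 : ow * k : k].copy()
            for dj in range(k):
                for dk in range(k):
                    if dj == 0 and dk == 0:
                        continue
                    np.maximum(out, x[:, :, dj : oh * k : k, dk : ow * k : k], out=out)
        else:
            out = np.zeros((b_sz, c, oh, ow), dtype=np.float32)
            for dj in range(k):
                for dk in range(k):
                    out += x[:, :, dj : oh * k : k, dk : ow * k : k]
            out /= k * k
        if train:
            self._cache = {"fast": True, "x": x if self.kind == "max" else None,
                           "out": out if self.kind == "max" else None,
                           "shape": x.shape}
        return out

    def _backward_fast(self, dy: np.ndarray) -> np.ndarray:
        cache = self._cache
        k = self.kernel
        oh, ow = dy.shape[2], dy.shape[3]
        dx = np.zeros(cache["shape"], dtype=np.float32)
        if self.kind == "max":
            x, out = cache["x"], cache["out"]
            assigned = np.zeros(dy.shape, dtype=bool)
            for dj in range(k):
                for dk in range(k):
                    sl = x[:, :, dj : oh * k : k, dk : ow * k : k]
                    take = (sl == out) & ~assigned  # first-match tie rule
                    dx[:, :, dj : oh * k : k, dk : ow * k : k] += dy * take
                    assigned |= take
        else:
            g = (dy / (k * k)).astype(np.float32)
            for dj in range(k):
                for dk in range(k):
                    dx[:, :, dj : oh * k : k, dk : ow * k : k] += g
        self._cache = None
        return dx

    def _indices(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        out = pool_output_size(n, self.kernel, self.stride, self.rounding)
        if out < 1:
            raise ValueError(f"{self.name}: output size would be < 1")
        starts = np.arange(out) * self.stride
        idx = starts[:, None] + np.arange(self.kernel)[None, :]  # (out, k)
        valid = idx < n
        return np.minimum(idx, n - 1), valid

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self._fast:
            return self._forward_fast(x, train)
        b_sz, c, h, w = x.shape
        ridx, rvalid = self._indices(h)
        cidx, cvalid = self._indices(w)
        oh, ow = ridx.shape[0], cidx.shape[0]
        k = self.kernel
        # (B, C, oh, k, ow, k) -> (B, C, oh, ow, k*k)
        win = x[:, :, ridx, :][:, :, :, :, cidx]
        win = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3, 5)).reshape(b_sz, c, oh, ow, k * k)
        # validity of window element (dj, dk) at output (i, j)
        vmask = (rvalid[:, None, :, None] & cvalid[None, :, None, :]).reshape(oh, ow, k * k)
        if self.kind == "max":
            masked = np.where(vmask[None, None], win, -np.inf)
            arg = masked.argmax(axis=-1)
            out = masked.max(axis=-1)
            if train:
                self._cache = {"arg": arg, "shape": x.shape, "ridx": ridx, "cidx": cidx, "rvalid": rvalid, "cvalid": cvalid}
        else:
            counts = vmask.sum(axis=-1).astype(np.float32)  # (oh, ow)
            out = np.where(vmask[None, None], win, 0.0).sum(axis=-1) / counts[None, None]
            if train:
                self._cache = {"counts": counts, "shape": x.shape, "ridx": ridx, "cidx": cidx, "rvalid": rvalid, "cvalid": cvalid}
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        if self._cache.get("fast"):
            return self._backward_fast(dy)
        cache = self._cache
        k = self.kernel
        ridx, cidx = cache["ridx"], cache["cidx"]
        rvalid, cvalid = cache["rvalid"], cache["cvalid"]
        dx = np.zeros(cache["shape"], dtype=np.float32)
        if self.kind == "max":
            gw = np.zeros(dy.shape + (k * k,), dtype=np.float32)
            np.put_along_axis(gw, cache["arg"][..., None], dy[..., None].astype(np.float32), axis=-1)
        else:
            gavg = (dy / cache["counts"][None, None]).astype(np.float32)
        for dj in range(k):
            rsel = np.flatnonzero(rvalid[:, dj])
            if rsel.size == 0:
                continue
            for dk in range(k):
                csel = np.flatnonzero(cvalid[:, dk])
                if csel.size == 0:
                    continue
                if self.kind == "max":
                    contrib = gw[:, :, rsel[:, None], csel[None, :], dj * k + dk]
                else:
                    contrib = gavg[:, :, rsel[:, None], csel[None, :]]
                dx[:, :, ridx[rsel, dj][:, None], cidx[csel, dk][None, :]] += contrib
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training mode with a supplied rng."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        assert self.rng is not None, "Dropout needs an rng in training mode"
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        super().__init__()
        self.name = name
        self.w = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy.  For one-hot targets this equals the
    KL divergence from the target to the prediction, so the two configured
    loss choices share both value and gradient here."""
    return float(-(onehot * np.log(probs + eps)).sum(axis=-1).mean())


class RMSprop:
    """RMSprop as in the common Keras defaults (rho=0.9, eps=1e-7)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
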