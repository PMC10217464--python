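"""Minimal CPU neural-network engine for small 3D volumes.

Layers operate on float32 arrays shaped ``(N, C, D, H, W)`` and implement
``forward(x, train)`` / ``backward(dout)`` with gradients accumulated next
to their parameters.  Convolutions are expressed as per-offset matrix
products so the heavy lifting lands in BLAS without im2col memory blow-up;
everything is exactly reproducible given the initialisation seed and
single-threaded execution.
"""

from __future__ import annotations

import numpy as np


def _offset_view(xp: np.ndarray, o: tuple[int, int, int], shape_sp) -> np.ndarray:
    """View of the padded array shifted by kernel offset ``o`` (0-based)."""
    return xp[:, :,
              o[0] : o[0] + shape_sp[0],
              o[1] : o[1] + shape_sp[1],
              o[2] : o[2] + shape_sp[2]]


def _corr3d(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Same-padding cross-correlation: (N,C,D,H,W) x (F,C,k,k,k) -> (N,F,D,H,W).

    Shift-and-add: one (F,C) x (C, N*V) matrix product per kernel offset,
    which keeps peak memory at the size of the input rather than the
    k^3-fold im2col expansion.
    """
    k = W.shape[2]
    p = k // 2
    n, _, d, h, w = x.shape
    f = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    acc = np.zeros((f, n, d, h, w), np.float32)
    for oz in range(k):
        for oy in range(k):
            for ox in range(k):
                xv = _offset_view(xp, (oz, oy, ox), (d, h, w))
                acc += np.tensordot(W[:, :, oz, oy, ox], xv, axes=([1], [1]))
    return np.ascontiguousarray(acc.transpose(1, 0, 2, 3, 4))


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 same-padding convolution."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        fan_in = in_ch * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He initialisation
        self.params["W"] = (rng.normal(0, scale, (out_ch, in_ch, kernel, kernel, kernel))
                            .astype(np.float32))
        self.params["b"] = np.zeros(out_ch, np.float32)
        self.kernel = kernel

    def forward(self, x, train=True):
        self._x = x
        out = _corr3d(x, self.params["W"])
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, dout):
        x, W = self._x, self.params["W"]
        k, p = self.kernel, self.kernel // 2
        sp = x.shape[2:]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        dW = np.empty_like(W)
        dxp = np.zeros(xp.shape, np.float32)
        for oz in range(k):
            for oy in range(k):
                for ox in range(k):
                    xv = _offset_view(xp, (oz, oy, ox), sp)
                    dW[:, :, oz, oy, ox] = np.tensordot(
                        dout, xv, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
                    dxv = _offset_view(dxp, (oz, oy, ox), sp)
                    dxv += np.tensordot(W[:, :, oz, oy, ox], dout, axes=([0], [1])
                                        ).transpose(1, 0, 2, 3, 4)
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        return np.ascontiguousarray(dxp[:, :, p:-p or None, p:-p or None, p:-p or None])


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class MaxPool3D(Layer):
    """2x2x2 max pooling with stride 2, floor rounding (trailing odd slices dropped)."""

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :, : d2 * 2, : h2 * 2, : w2 * 2]
        blocks = xc.reshape(n, c, d2, 2, h2, 2, w2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d2, h2, w2, 8)
        self._arg = blocks.argmax(axis=-1)
        return np.ascontiguousarray(blocks.max(axis=-1))

    def backward(self, dout):
        n, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        scat = np.zeros((n, c, d2, h2, w2, 8), dout.dtype)
        np.put_along_axis(scat, self._arg[..., None], dout[..., None], axis=-1)
        scat = scat.reshape(n, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros(self._in_shape, dout.dtype)
        dx[:, :, : d2 * 2, : h2 * 2, : w2 * 2] = scat.reshape(n, c, d2 * 2, h2 * 2, w2 * 2)
        return dx


class UpsampleTo(Layer):
    """Nearest-neighbour 2x up-sampling, then edge-replication/crop to a target shape.

    The target may differ from the doubled shape by at most one trailing
    slice per axis — exactly the mismatch left by floor-rounding pooling of
    odd axes on the encoder side.
    """

    def __init__(self, target: tuple[int, int, int]):
        super().__init__()
        self.target = target

    def forward(self, x, train=True):
        self._in_shape = x.shape
        y = x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
        self._mid_shape = y.shape
        for ax, t in zip((2, 3, 4), self.target):
            cur = y.shape[ax]
            if t > cur:
                if t - cur > 1:
                    raise ValueError(f"target {self.target} too far from doubled {y.shape[2:]}")
                last = np.take(y, [-1], axis=ax)
                y = np.concatenate([y, last], axis=ax)
            elif t < cur:
                y = np.take(y, np.arange(t), axis=ax)
        return np.ascontiguousarray(y)

    def backward(self, dout):
        d = dout
        for ax, t in zip((2, 3, 4), self.target):
            mid = self._mid_shape[ax]
            if t > mid:  # replicated last slice: fold its gradient back
                extra = np.take(d, [-1], axis=ax)
                d = np.take(d, np.arange(mid), axis=ax)
                idx = [slice(None)] * 5
                idx[ax] = slice(mid - 1, mid)
                d[tuple(idx)] += extra
            elif t < mid:  # cropped slices received no gradient
                pad = [(0, 0)] * 5
                pad[ax] = (0, mid - t)
                d = np.pad(d, pad)
        n, c = d.shape[:2]
        dd, hh, ww = self._in_shape[2:]
        d = d.reshape(n, c, dd, 2, hh, 2, ww, 2)
        return d.sum(axis=(3, 5, 7))


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, np.float32)
        self.params["beta"] = np.zeros(channels, np.float32)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum, self.eps = momentum, eps
        self._initialized = False

    def forward(self, x, train=True):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self._initialized:
                # seed the running statistics so short trainings still get a
                # sane inference mode
                self.running_mean, self.running_var = mean.copy(), var.copy()
                self._initialized = True
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        self._std = np.sqrt(var + self.eps).reshape(shape)
        self._xhat = (x - mean.reshape(shape)) / self._std
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, dout):
        axes = (0, 2, 3, 4)
        m = dout.size / dout.shape[1]
        shape = (1, -1, 1, 1, 1)
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=axes).astype(np.float32)
        g = self.params["gamma"].reshape(shape)
        dxhat = dout * g
        return (dxhat - dxhat.mean(axis=axes).reshape(shape)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape)) / self._std


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0, scale, (n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, np.float32)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train=True):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[n].size for layer, n in self.parameters())


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(logits) and its gradient in logits."""
    z, t = logits.astype(np.float64), targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - t) / z.size
    return float(loss), grad.astype(np.float32)


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m[id(layer)][name]
            v = self.v[id(layer)][name]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
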