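"""Minimal numpy layers with hand-written backprop for the frame classifier.

Only what the dilated temporal-convolution classifier needs: 1-D
convolutions (im2col), ReLU, dense layers, a weighted masked softmax
cross-entropy, and Adam.  Shapes follow the convention (batch, channels,
time).  Every layer caches what its backward pass needs; ``params()``
exposes (weight, gradient) pairs for the optimizer.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution over the last axis, valid or same padding.

    x: (B, C_in, T) -> y: (B, C_out, T_out).  Dilation enlarges the
    effective kernel; stride only with valid padding.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        dilation: int = 1,
        pad: str = "valid",
    ) -> None:
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.stride = stride
        self.dilation = dilation
        self.pad = pad
        self.kernel = kernel
        self._cache = None
        self.compute_dx = True

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _pad_width(self) -> int:
        if self.pad == "valid":
            return 0
        eff = (self.kernel - 1) * self.dilation
        return eff // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self._pad_width()
        if p:
            x_pad = np.pad(x, ((0, 0), (0, 0), (p, p)))
        else:
            x_pad = x
        eff = (self.kernel - 1) * self.dilation + 1
        t_out = (x_pad.shape[2] - eff) // self.stride + 1
        idx = (
            np.arange(t_out)[:, None] * self.stride
            + np.arange(self.kernel)[None, :] * self.dilation
        )  # (T_out, K)
        cols = x_pad[:, :, idx]  # (B, C_in, T_out, K)
        y = np.einsum("bcok,dck->bdo", cols, self.W, optimize=True) + self.b[None, :, None]
        self._cache = (cols, idx, x_pad.shape, p)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, idx, pad_shape, p = self._cache
        self.gW[...] = np.einsum("bdo,bcok->dck", grad, cols, optimize=True)
        self.gb[...] = grad.sum(axis=(0, 2))
        if not self.compute_dx:
            return None
        dcols = np.einsum("bdo,dck->bcok", grad, self.W, optimize=True)
        b, c = pad_shape[0], pad_shape[1]
        dx_flat = np.zeros((b * c, pad_shape[2]))
        flat_idx = idx.reshape(-1)
        np.add.at(
            dx_flat,
            (np.arange(b * c)[:, None], flat_idx[None, :]),
            dcols.reshape(b * c, -1),
        )
        dx = dx_flat.reshape(pad_shape)
        if p:
            dx = dx[:, :, p:-p]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dense(Layer):
    """x: (B, F_in) -> (B, F_out)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T


class MeanPoolTime(Layer):
    """(B, C, T) -> (B, C), mean over the time axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._t, axis=2) / self._t


class ResidualDilatedBlock(Layer):
    """y = x + conv1x1(relu(conv_k_dilated(x))), same padding, stride 1."""

    def __init__(self, width: int, kernel: int, dilation: int, rng: np.random.Generator) -> None:
        self.conv = Conv1D(width, width, kernel, rng, dilation=dilation, pad="same")
        self.relu = ReLU()
        self.proj = Conv1D(width, width, 1, rng, pad="valid")

    def params(self):
        return self.conv.params() + self.proj.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.proj.forward(self.relu.forward(self.conv.forward(x)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        inner = self.conv.backward(self.relu.backward(self.proj.backward(grad)))
        return grad + inner


class Adam:
    """Adam over a list of (param, grad) pairs (updated in place)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Masked weighted softmax cross-entropy.

    logits: (T, K); targets: (T,) with -1 = masked.  Returns (loss, dlogits)
    where the per-frame losses are weighted by ``class_weights[target]`` and
    normalized by the total weight.
    """
    t = targets >= 0
    probs = softmax(logits, axis=1)
    dlogits = np.zeros_like(logits)
    if not np.any(t):
        return 0.0, dlogits
    idx = np.nonzero(t)[0]
    tgt = targets[idx]
    w = class_weights[tgt]
    total_w = w.sum()
    if total_w <= 0:
        return 0.0, dlogits
    logp = np.log(np.maximum(probs[idx, tgt], 1e-12))
    loss = float(-(w * logp).sum() / total_w)
    grad = probs[idx] * w[:, None]
    grad[np.arange(len(idx)), tgt] -= w
    dlogits[idx] = grad / total_w
    return loss, dlogits
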