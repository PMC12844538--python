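"""Minimal 1-D neural-network layers with manual backpropagation.

Implements exactly the building blocks the fusion regressor needs — dense
layers, 1-D convolutions (full, depthwise with a depth multiplier, and
pointwise), ELU, average pooling, dropout and Adam — on plain numpy arrays.
Every layer caches its forward inputs and exposes ``backward(dy)`` returning
the gradient with respect to its input while accumulating parameter
gradients; correctness is pinned by central-difference gradient checks in the
test suite.

Array convention: convolutional layers take (batch, channels, length);
dense layers take (batch, features).  All convolutions use "same" padding
(left pad (k-1)//2, right pad k//2) so the length axis is preserved.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve, oaconvolve

from .errors import ShapeError


def _pad_lr(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


class Layer:
    """Base layer: no parameters, identity behaviour."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> dict:
        return {}

    def gradients(self) -> dict:
        return {}


class Dense(Layer):
    #: multiplier on the optimizer's weight decay for this layer's W
    wd_scale = 1.0

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if x.ndim != 2 or x.shape[1] != self.W.shape[0]:
            raise ShapeError(
                f"Dense: expected input (batch, {self.W.shape[0]}), got {x.shape}"
            )
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def gradients(self):
        return {"W": self.dW, "b": self.db}


class Conv1d(Layer):
    """Standard cross-channel 1-D convolution, "same" padding, stride 1.

    A kernel size of 1 makes this the pointwise (channel-mixing) convolution,
    computed as a plain matmul; longer kernels run through FFT convolution,
    which is exact to floating-point accuracy and fast on long signals.

    Forward: y[b,o,l] = b[o] + sum_{c,t} W[o,c,t] * xpad[b,c,l+t]
    with xpad padded by ((k-1)//2, k//2).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((c_out, c_in, k)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def forward(self, x, train=False):
        c_out, c_in, k = self.W.shape
        if x.ndim != 3 or x.shape[1] != c_in:
            raise ShapeError(f"Conv1d: expected (batch, {c_in}, length), got {x.shape}")
        self._x = x
        if k == 1:
            y = np.einsum("bcl,oc->bol", x, self.W[:, :, 0], optimize=True)
            return y + self.b[None, :, None]
        pl, pr = _pad_lr(k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._xp = xp
        # cross-correlation = convolution with the flipped kernel; 'valid'
        # over the padded input returns exactly the L "same" outputs
        w_flip = np.ascontiguousarray(self.W.transpose(1, 0, 2)[None, :, :, ::-1])
        full = fftconvolve(xp[:, :, None, :], w_flip, mode="valid", axes=3)  # (B, C_in, C_out, L)
        y = full.sum(axis=1)
        return y + self.b[None, :, None]

    def backward(self, dy):
        c_out, c_in, k = self.W.shape
        x = self._x
        L = x.shape[2]
        self.db = dy.sum(axis=(0, 2))
        if k == 1:
            self.dW = np.einsum("bol,bcl->oc", dy, x, optimize=True)[:, :, None]
            return np.einsum("bol,oc->bcl", dy, self.W[:, :, 0], optimize=True)
        pl, _ = _pad_lr(k)
        xp = self._xp
        # dW[o,c,t] = sum_{b,l} dy[b,o,l] xp[b,c,l+t]  (correlation, valid)
        dy_flip = np.ascontiguousarray(dy[:, None, :, ::-1])
        dw_full = oaconvolve(xp[:, :, None, :], dy_flip, mode="valid", axes=3)  # (B, C_in, C_out, k)
        self.dW = dw_full.sum(axis=0).transpose(1, 0, 2).astype(self.W.dtype)
        # dxp[b,c,i] = sum_{o,t} dy[b,o,i-t] W[o,c,t]  (true convolution, full)
        dx_full = fftconvolve(
            dy[:, None, :, :], self.W.transpose(1, 0, 2)[None], mode="full", axes=3
        )  # (B, C_in, C_out, L+k-1)
        dxp = dx_full.sum(axis=2)
        return np.ascontiguousarray(dxp[:, :, pl : pl + L]).astype(x.dtype)

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def gradients(self):
        return {"W": self.dW, "b": self.db}


class DepthwiseConv1d(Layer):
    """Per-channel 1-D convolution with an integer depth multiplier.

    Input channel c produces output channels c*mult .. c*mult+mult-1, so
    "16 filters after 8 channels" is realised as multiplier 2.  Same padding;
    FFT-based like Conv1d.
    """

    def __init__(self, c_in: int, multiplier: int, k: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / k)
        self.W = (rng.standard_normal((c_in, multiplier, k)) * scale).astype(dtype)
        self.b = np.zeros(c_in * multiplier, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.multiplier = multiplier

    @property
    def c_out(self) -> int:
        return self.W.shape[0] * self.multiplier

    def forward(self, x, train=False):
        c_in, mult, k = self.W.shape
        if x.ndim != 3 or x.shape[1] != c_in:
            raise ShapeError(
                f"DepthwiseConv1d: expected (batch, {c_in}, length), got {x.shape}"
            )
        pl, pr = _pad_lr(k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._xp = xp
        self._in_len = x.shape[2]
        w_flip = np.ascontiguousarray(self.W[None, :, :, ::-1])
        y = fftconvolve(xp[:, :, None, :], w_flip, mode="valid", axes=3)  # (B, C, mult, L)
        b_sz = x.shape[0]
        y = y.reshape(b_sz, c_in * mult, self._in_len)
        return y + self.b[None, :, None]

    def backward(self, dy):
        c_in, mult, k = self.W.shape
        pl, _ = _pad_lr(k)
        L = self._in_len
        xp = self._xp
        dyr = dy.reshape(dy.shape[0], c_in, mult, L)
        self.db = dy.sum(axis=(0, 2))
        dyr_flip = np.ascontiguousarray(dyr[:, :, :, ::-1])
        dw_full = oaconvolve(xp[:, :, None, :], dyr_flip, mode="valid", axes=3)  # (B, C, mult, k)
        self.dW = dw_full.sum(axis=0).astype(self.W.dtype)
        dx_full = fftconvolve(dyr, self.W[None], mode="full", axes=3)  # (B, C, mult, L+k-1)
        dxp = dx_full.sum(axis=2)
        return np.ascontiguousarray(dxp[:, :, pl : pl + L]).astype(dy.dtype)

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def gradients(self):
        return {"W": self.dW, "b": self.db}


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def forward(self, x, train=False):
        y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        self._x_pos = x > 0
        self._y = y
        return y

    def backward(self, dy):
        return dy * np.where(self._x_pos, 1.0, self._y + 1.0)


class AvgPool1d(Layer):
    """Non-overlapping average pooling along the length axis (tail dropped)."""

    def __init__(self, factor: int):
        if factor < 1:
            raise ShapeError(f"AvgPool1d: factor must be >= 1, got {factor}")
        self.factor = factor

    @staticmethod
    def out_len(length: int, factor: int) -> int:
        return length // factor

    def forward(self, x, train=False):
        f = self.factor
        b_sz, c, L = x.shape
        lo = L // f
        if lo < 1:
            raise ShapeError(f"AvgPool1d: length {L} shorter than pool factor {f}")
        self._in_shape = x.shape
        return x[:, :, : lo * f].reshape(b_sz, c, lo, f).mean(axis=3)

    def backward(self, dy):
        f = self.factor
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        lo = dy.shape[2]
        dx[:, :, : lo * f] = np.repeat(dy / f, f, axis=2)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode.

    The mask generator is injected by the trainer (``rng`` attribute) so the
    whole run is reproducible from one seed.
    """

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ShapeError(f"Dropout: rate must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_parameters(self):
        """Yield (unique_name, layer, param_name) for every trainable tensor."""
        for i, layer in enumerate(self.layers):
            for name in layer.parameters():
                yield f"{i}.{type(layer).__name__}.{name}", layer, name
            if isinstance(layer, Sequential):  # pragma: no cover - not nested here
                raise ShapeError("nested Sequential not supported")

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def n_parameters(self) -> int:
        return sum(
            layer.parameters()[name].size for _, layer, name in self.named_parameters()
        )

    def state_dict(self) -> dict:
        return {
            name: layer.parameters()[pname].copy()
            for name, layer, pname in self.named_parameters()
        }

    def load_state_dict(self, state: dict) -> None:
        for name, layer, pname in self.named_parameters():
            layer.parameters()[pname][...] = state[name]


class Adam:
    """Adam optimizer over one or more Sequential modules.

    ``weight_decay`` applies decoupled L2 shrinkage (AdamW-style) to weight
    matrices only, never to biases — the main defence against overfitting the
    wide dense layers on small training sets.
    """

    def __init__(self, modules, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.modules = list(modules)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def _slots(self):
        for mi, module in enumerate(self.modules):
            for name, layer, pname in module.named_parameters():
                wd_scale = getattr(layer, "wd_scale", 1.0) if pname == "W" else 0.0
                yield (
                    f"{mi}:{name}",
                    layer.parameters()[pname],
                    layer.gradients()[pname],
                    wd_scale,
                )

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for key, param, grad, wd_scale in self._slots():
            if key not in self.m:
                self.m[key] = np.zeros_like(param)
                self.v[key] = np.zeros_like(param)
            m, v = self.m[key], self.v[key]
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            if wd_scale and self.weight_decay:
                param -= self.lr * self.weight_decay * wd_scale * param
            param -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
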