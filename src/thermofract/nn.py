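"""Numpy CNN engine: layers, backprop, and the Adam optimizer.

Implements exactly the layer zoo the blueprint in
:mod:`thermofract.architecture` needs — 3x3 same-padding stride-1
convolution, per-channel batch normalization, ReLU, 2x2/stride-2 max
pooling with floor rounding, inverted dropout, a dense layer, and
softmax/cross-entropy — together with full reverse-mode gradients.
Convolution is evaluated as an im2col matrix product; pooling gradients
are routed through the stored argmax, and the odd trailing row/column a
floor-pool discards receives zero gradient.

Weights use Glorot-uniform initialization from a seeded generator, so a
network is bit-reproducible from its seed.  Correctness of every gradient
is established by finite-difference checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import ArchitectureSpec, LayerSpec

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
    "Network",
    "Adam",
]


class Layer:
    """Minimal layer protocol: forward/backward plus parameter access."""

    name = "layer"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv2D(Layer):
    """3x3 convolution, stride 1, same (zero) padding, bias per filter."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 name: str = "conv", dtype=np.float32):
        self.name = name
        k = 3
        fan_in, fan_out = in_channels * k * k, out_channels * k * k
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.weight = rng.uniform(-limit, limit, (out_channels, in_channels, k, k)).astype(dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (N, C, H, W, 3, 3) view -> (N*H*W, C*9) im2col matrix
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        self._cols = cols
        self._xshape = x.shape
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        out = cols @ wmat.T + self.bias
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, oc, h, w = dout.shape
        _, c, _, _ = self._xshape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, oc)
        self.dweight = (dmat.T @ self._cols).reshape(self.weight.shape)
        self.dbias = dmat.sum(axis=0)
        wmat = self.weight.reshape(oc, -1)
        dcols = (dmat @ wmat).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=dout.dtype)
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [
            {"name": f"{self.name}.weight", "value": self.weight, "grad": lambda: self.dweight,
             "set": lambda v: setattr(self, "weight", v)},
            {"name": f"{self.name}.bias", "value": self.bias, "grad": lambda: self.dbias,
             "set": lambda v: setattr(self, "bias", v)},
        ]


class BatchNorm2D(Layer):
    """Per-channel standardization with learnable scale (gamma) and offset (beta)."""

    def __init__(self, channels: int, name: str = "batchnorm", eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * ivar[:, None, None]
        if training:
            self._xhat = xhat
            self._ivar = ivar
            self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dout):
        xhat, ivar, m = self._xhat, self._ivar, self._m
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = (self.gamma * ivar)[:, None, None]
        dx = (g / m) * (m * dout - self.dbeta[:, None, None] - xhat * self.dgamma[:, None, None])
        self._xhat = None
        return dx

    def params(self):
        return [
            {"name": f"{self.name}.gamma", "value": self.gamma, "grad": lambda: self.dgamma,
             "set": lambda v: setattr(self, "gamma", v)},
            {"name": f"{self.name}.beta", "value": self.beta, "grad": lambda: self.dbeta,
             "set": lambda v: setattr(self, "beta", v)},
        ]


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 window, stride 2, floor rounding: an odd last row/column is dropped."""

    def __init__(self, name: str = "maxpool"):
        self.name = name

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        xr = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._xshape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxc = dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = dxc
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at evaluation."""

    def __init__(self, rate: float, rng: np.random.Generator, name: str = "dropout"):
        if not (0.0 < rate < 1.0):
            raise ValueError("dropout rate must be in (0, 1)")
        self.name = name
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 name: str = "fc", dtype=np.float32):
        self.name = name
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = rng.uniform(-limit, limit, (in_features, out_features)).astype(dtype)
        self.bias = np.zeros(out_features, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout):
        self.dweight = self._x.T @ dout
        self.dbias = dout.sum(axis=0)
        dx = dout @ self.weight.T
        self._x = None
        return dx

    def params(self):
        return [
            {"name": f"{self.name}.weight", "value": self.weight, "grad": lambda: self.dweight,
             "set": lambda v: setattr(self, "weight", v)},
            {"name": f"{self.name}.bias", "value": self.bias, "grad": lambda: self.dbias,
             "set": lambda v: setattr(self, "bias", v)},
        ]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class Network:
    """Executable network instantiated from an :class:`ArchitectureSpec`.

    Input is a batch of 100x100 single-channel images, shape (N, 100, 100)
    or (N, 1, 100, 100); output of :meth:`forward` is the (N, 2) logits,
    of :meth:`predict_proba` the softmax class probabilities.  The softmax
    and classification stages of the blueprint are realized by
    :meth:`predict_proba` / :meth:`predict` rather than as weight layers.
    """

    def __init__(self, arch: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        self.arch = arch
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        self.input_mean: np.ndarray | float = 0.0
        self.input_sd: np.ndarray | float = 1.0
        for spec in arch.layers:
            if spec.kind == "conv2d":
                self.layers.append(Conv2D(spec.in_channels, spec.filters, self.rng,
                                          name=spec.name, dtype=dtype))
            elif spec.kind == "batchnorm":
                self.layers.append(BatchNorm2D(spec.channels, name=spec.name, dtype=dtype))
            elif spec.kind == "relu":
                self.layers.append(ReLU(name=spec.name))
            elif spec.kind == "maxpool":
                self.layers.append(MaxPool2(name=spec.name))
            elif spec.kind == "dropout":
                self.layers.append(Dropout(spec.rate, self.rng, name=spec.name))
            elif spec.kind == "fully_connected":
                self.layers.append(Dense(spec.in_features, spec.out_features, self.rng,
                                         name=spec.name, dtype=dtype))
            elif spec.kind in ("input", "softmax", "classification"):
                continue
            else:
                raise ValueError(f"unknown layer kind {spec.kind!r}")

    # -- execution ---------------------------------------------------------
    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != self.arch.input_shape[2] or \
                x.shape[2:] != tuple(self.arch.input_shape[:2]):
            raise ValueError(
                f"expected batch of {self.arch.input_shape} images, got {x.shape}")
        return (x - self.input_mean) / self.input_sd

    def set_input_standardization(self, mean, sd) -> None:
        """Per-pixel affine rescaling applied to every input batch."""
        self.input_mean = np.asarray(mean, dtype=self.dtype)
        sd = np.asarray(sd, dtype=self.dtype)
        self.input_sd = np.where(sd > 0, sd, 1.0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self._prepare(x)
        self._preflatten_shape = None
        for layer in self.layers:
            if isinstance(layer, Dense) and h.ndim == 4:
                self._preflatten_shape = h.shape
                h = h.reshape(h.shape[0], -1)
            h = layer.forward(h, training=training)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if isinstance(layer, Dense) and self._preflatten_shape is not None:
                g = g.reshape(self._preflatten_shape)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = [softmax(self.forward(x[i : i + batch_size]))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Class index per image; fracture (1) iff p(fracture) strictly exceeds
        the threshold, so an exact 0.5/0.5 tie resolves to non-fracture."""
        return (self.predict_proba(x)[:, 1] > threshold).astype(int)

    # -- parameter access --------------------------------------------------
    def params(self) -> list[dict]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def num_params_by_layer(self) -> dict[str, int]:
        """Enumerated learnable-parameter counts from the live weight arrays."""
        counts: dict[str, int] = {}
        for layer in self.layers:
            n = sum(p["value"].size for p in layer.params())
            if n:
                counts[layer.name] = n
        return counts

    def total_num_params(self) -> int:
        return sum(self.num_params_by_layer().values())

    def zero_weights(self) -> None:
        for p in self.params():
            p["value"][...] = 0.0


class Adam:
    """Adam with bias-corrected first/second moments (beta 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: list[dict], learning_rate: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.params = params
        self.lr = learning_rate
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p["value"], dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p["value"], dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p["grad"]().astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p["value"] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p["value"].dtype)
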