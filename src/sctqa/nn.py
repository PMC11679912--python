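"""Minimal convolutional-network engine (numpy, manual backprop).

Provides exactly what the cascade estimators need: 2D convolution
(im2col), 2x2 max pooling, ReLU, dense layers, softmax cross-entropy and
MSE losses, and an Adam optimizer with separate L1 and L2 penalties
applied to weights (not biases).  Everything is seeded and deterministic.

Two backbones are built on top of it:

* ``tiny`` — 3 conv blocks (8/16/32 channels) and a small dense head on
  32x32 inputs; trains in minutes on one CPU.
* ``vgg16`` — the classic 13-conv + 3-dense stack, with a width
  multiplier; provided for full-scale use, impractical to train at desk
  scale.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: ``params``/``grads`` are dicts of aligned arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3-style convolution, stride 1, 'same' zero padding, via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k * k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, _, h, w = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = gmat.T @ self._cols
        self.grads["b"] = gmat.sum(axis=0)
        dcols = (gmat @ self.params["W"]).reshape(n, h, w, self.c_in, self.k, self.k)
        p = self.pad
        dxp = np.zeros((n, self.c_in, h + 2 * p, w + 2 * p))
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        # argmax mask for backprop; ties route the gradient to every maximum
        self._mask = xr == out[:, :, :, None, :, None]
        self._in_shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        gr = g[:, :, :, None, :, None] * self._mask
        return gr.reshape(n, c, h, w)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2; preserves mean intensity, which
    suits amplitude-estimation heads better than max pooling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self) -> list[tuple[str, Layer, str]]:
        """(unique key, layer, param name) for every trainable array."""
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"{i}.{name}", layer, name))
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {key: layer.params[name].copy() for key, layer, name in self.parameters()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameters():
            layer.params[name] = state[key].copy()

    def weight_norms(self) -> tuple[float, float]:
        """(sum |W|, sum W^2) over weight matrices (biases excluded)."""
        l1 = l2 = 0.0
        for key, layer, name in self.parameters():
            if name == "W":
                w = layer.params[name]
                l1 += float(np.abs(w).sum())
                l2 += float((w**2).sum())
        return l1, l2


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    logits: np.ndarray, classes: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.mean(np.log(p[np.arange(n), classes] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), classes] -= 1.0
    return loss, grad / n


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L1+L2 penalties added to weight gradients (not biases)."""

    def __init__(
        self,
        network: Network,
        lr: float = 5e-5,
        l1: float = 4e-4,
        l2: float = 4e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.net = network
        self.lr, self.l1, self.l2 = lr, l1, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def penalty(self) -> float:
        """Current regularization term: l1*sum|W| + l2*sum W^2."""
        n1, n2 = self.net.weight_norms()
        return self.l1 * n1 + self.l2 * n2

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, layer, name in self.net.parameters():
            g = layer.grads[name]
            if name == "W":
                w = layer.params[name]
                g = g + self.l1 * np.sign(w) + 2.0 * self.l2 * w
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g**2 - v)
            layer.params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

def build_tiny(input_size: tuple[int, int], out_dim: int, seed: int) -> Network:
    """3 conv blocks + small dense head; input must be divisible by 8."""
    h, w = input_size
    if h % 8 or w % 8:
        raise ValueError(f"tiny backbone needs dims divisible by 8, got {input_size}")
    rng = np.random.default_rng(seed)
    feat = 32 * (h // 8) * (w // 8)
    return Network(
        [
            Conv2D(1, 8, 3, rng),
            ReLU(),
            AvgPool2(),
            Conv2D(8, 16, 3, rng),
            ReLU(),
            AvgPool2(),
            Conv2D(16, 32, 3, rng),
            ReLU(),
            AvgPool2(),
            Flatten(),
            Dense(feat, 64, rng),
            ReLU(),
            Dense(64, out_dim, rng),
        ]
    )


_VGG16_CFG = [64, 64, "P", 128, 128, "P", 256, 256, 256, "P", 512, 512, 512, "P", 512, 512, 512, "P"]


def build_vgg16(
    input_size: tuple[int, int],
    out_dim: int,
    seed: int,
    width_mult: float = 1.0,
    dense_width: int = 4096,
) -> Network:
    """13 convolutional layers + 3 dense layers (VGG-16 topology).

    ``width_mult`` scales every channel count for reduced-width variants;
    input dims must be divisible by 32 (five pooling stages).
    """
    h, w = input_size
    if h % 32 or w % 32:
        raise ValueError(f"vgg16 backbone needs dims divisible by 32, got {input_size}")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    c_in = 1
    for item in _VGG16_CFG:
        if item == "P":
            layers.append(MaxPool2())
        else:
            c_out = max(1, int(item * width_mult))
            layers.extend([Conv2D(c_in, c_out, 3, rng), ReLU()])
            c_in = c_out
    feat = c_in * (h // 32) * (w // 32)
    layers.extend(
        [
            Flatten(),
            Dense(feat, dense_width, rng),
            ReLU(),
            Dense(dense_width, dense_width, rng),
            ReLU(),
            Dense(dense_width, out_dim, rng),
        ]
    )
    return Network(layers)


def build_backbone(name: str, input_size: tuple[int, int], out_dim: int, seed: int) -> Network:
    if name == "tiny":
        return build_tiny(input_size, out_dim, seed)
    if name in ("vgg16", "vgg16-like"):
        return build_vgg16(input_size, out_dim, seed)
    raise ValueError(f"unknown backbone: {name!r} (expected 'tiny' or 'vgg16')")


def clone_state(state: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return copy.deepcopy(state)
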