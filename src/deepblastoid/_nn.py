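"""Minimal NumPy neural-network stack used by the classifier harness.

Implements exactly what the training recipe needs: 2-D convolution
(im2col), ReLU, 2x2 max pooling, dense layers, softmax cross-entropy,
global-norm gradient clipping and AdamW (decoupled weight decay) with a
per-layer learning-rate multiplier for the classification head. float32
throughout; all randomness comes from an explicit Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "clip_grad_norm",
    "AdamW",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, ho, wo, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    # (n*ho*wo, c*k*k)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    xpad = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            xpad[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += cols[
                :, :, :, :, i, j
            ]
    return xpad[:, :, pad : pad + h, pad : pad + w] if pad else xpad


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' padding, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = cin * k * k
        self.k, self.pad = k, k // 2
        self.params = {
            "W": rng.normal(0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)).astype(np.float32),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, ho, wo = _im2col(x, self.k, 1, self.pad)
        self._cols = cols
        W = self.params["W"]
        out = cols @ W.reshape(W.shape[0], -1).T + self.params["b"]
        n = x.shape[0]
        return out.reshape(n, ho, wo, W.shape[0]).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, cout, ho, wo = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        W = self.params["W"]
        self.grads["W"][...] = (dflat.T @ self._cols).reshape(W.shape)
        self.grads["b"][...] = dflat.sum(axis=0)
        dcols = dflat @ W.reshape(cout, -1)
        return _col2im(dcols, self._x_shape, self.k, 1, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes by batch statistics; evaluation mode uses the
    running averages, so inference is deterministic.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(c, dtype=np.float32), "beta": np.zeros(c, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)[None, :, None, None]
            self._xhat = (x - mean[None, :, None, None]) / self._std
            return self.params["gamma"][None, :, None, None] * self._xhat + self.params["beta"][None, :, None, None]
        std = np.sqrt(self.running_var + self.eps)[None, :, None, None]
        xhat = (x - self.running_mean[None, :, None, None]) / std
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"][...] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std
        return dx

    def extra_state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_extra_state(self, state: dict[str, np.ndarray]) -> None:
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self._xr = xr
        out = xr.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._xr == self._out[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        d = dout[:, :, :, None, :, None] * mask
        n, c, hh, _, ww, _ = d.shape
        return d.reshape(n, c, hh * 2, ww * 2)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": rng.normal(0, np.sqrt(2.0 / fin), size=(fin, fout)).astype(np.float32),
            "b": np.zeros(fout, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def train(self) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = True

    def eval(self) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = False

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {
            f"{i}.{name}": layer.params[name]
            for i, layer in enumerate(self.layers)
            for name in layer.params
        }
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "extra_state"):
                for name, value in layer.extra_state().items():
                    state[f"{i}.{name}"] = value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if hasattr(layer, "load_extra_state"):
                layer.load_extra_state(
                    {k.split(".", 1)[1]: state[k] for k in state if k.startswith(f"{i}.") and k.split(".", 1)[1] in ("running_mean", "running_var")}
                )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer targets and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


def clip_grad_norm(net: Sequential, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most max_norm."""
    sq = 0.0
    for layer, name in net.parameters():
        g = layer.grads[name]
        sq += float((g.astype(np.float64) ** 2).sum())
    norm = np.sqrt(sq)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for layer, name in net.parameters():
            layer.grads[name] *= scale
    return float(norm)


class AdamW:
    """Adam with decoupled weight decay.

    ``lr_multipliers`` maps id(layer) to a factor applied to the learning
    rate of that layer's parameters (used to train the classification head
    faster than the backbone). Biases are excluded from weight decay.
    """

    def __init__(
        self,
        net: Sequential,
        lr: float = 3e-4,
        weight_decay: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        lr_multipliers: dict[int, float] | None = None,
    ) -> None:
        self.net = net
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.lr_multipliers = lr_multipliers or {}
        self.t = 0
        self.m = {id(l) * 31 + hash(n): np.zeros_like(l.params[n]) for l, n in net.parameters()}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for layer, name in self.net.parameters():
            key = id(layer) * 31 + hash(name)
            g = layer.grads[name]
            m = self.m[key]
            v = self.v[key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            lr = self.lr * self.lr_multipliers.get(id(layer), 1.0)
            update = lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p = layer.params[name]
            if self.wd and name == "W":
                p -= lr * self.wd * p
            p -= update
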