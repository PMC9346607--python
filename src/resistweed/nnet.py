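"""Minimal CPU convolutional-network engine (numpy, manual backprop).

Implements exactly the pieces the resistance classifier needs: 2-D
convolution (im2col), ReLU, max pooling, global average pooling, dense
layers, inverted dropout, residual blocks, softmax cross-entropy, and Adam
with decoupled weight decay. Everything is float64 numpy; forward and
backward passes are deterministic given the generator used for
initialization and dropout.

This is not a general autodiff framework; layers cache what their backward
pass needs and must be called forward-then-backward per batch.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "Residual",
    "Sequential",
    "softmax_cross_entropy",
    "Adam",
]


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv2d(Layer):
    """3x3-style convolution with 'same' zero padding (He-initialized)."""

    def __init__(self, in_c: int, out_c: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 skip_input_grad: bool = False) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_c * k * k))
        self.params["W"] = rng.normal(0.0, scale, (out_c, in_c, k, k))
        self.params["b"] = np.zeros(out_c)
        self.k, self.stride, self.in_c, self.out_c = k, stride, in_c, out_c
        self.pad = k // 2
        self.skip_input_grad = skip_input_grad  # set on the network's first layer

    def _cols(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (n, c, oh, ow, k, k)
        return win

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        cols = self._cols(x)  # (n, c, oh, ow, k, k)
        n, c, oh, ow = cols.shape[0], cols.shape[1], cols.shape[2], cols.shape[3]
        # flatten to a BLAS matmul: (n*oh*ow, c*k*k) @ (c*k*k, out_c)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * oh * ow, c * self.k * self.k
        )
        self._cols2 = cols2
        self._out_hw = (oh, ow)
        W2 = self.params["W"].reshape(self.out_c, -1)
        y = cols2 @ W2.T
        y = y.reshape(n, oh, ow, self.out_c).transpose(0, 3, 1, 2)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        n, c, h, w = self._x_shape
        oh, ow = self._out_hw
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(
            n * oh * ow, self.out_c
        )
        dW = dy2.T @ self._cols2
        self.grads["W"] = dW.reshape(W.shape)
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        if self.skip_input_grad:
            return None  # first layer: nothing consumes dx
        dy_nhwc = dy2.reshape(n, oh, ow, self.out_c)
        # accumulate in NHWC (contiguous inner axis), transpose once at the end
        dxp = np.zeros((n, h + 2 * self.pad, w + 2 * self.pad, c), dtype=dy.dtype)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                contrib = dy_nhwc @ W[:, :, ki, kj]  # (n, oh, ow, c)
                dxp[:, ki : ki + s * oh : s, kj : kj + s * ow : s, :] += contrib
        if self.pad:
            dxp = dxp[:, self.pad : -self.pad, self.pad : -self.pad, :]
        return dxp.transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel = stride = k); crops remainders."""

    def __init__(self, k: int = 2) -> None:
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        oh, ow = h // k, w // k
        x = x[:, :, : oh * k, : ow * k]
        self._x_shape = (n, c, h, w)
        blocks = x.reshape(n, c, oh, k, ow, k)
        y = blocks.max(axis=(3, 5))
        self._argmask = blocks == y[:, :, :, None, :, None]
        # break ties: keep only the first max per block
        flat = self._argmask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
        first = np.cumsum(flat, axis=-1) == 1
        flat &= first
        self._argmask = flat.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        k = self.k
        oh, ow = h // k, w // k
        dblocks = self._argmask * dy[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w))
        dx[:, :, : oh * k, : ow * k] = dblocks.reshape(n, c, oh, k, ow, k).reshape(
            n, c, oh * k, ow * k
        )
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_f), (in_f, out_f))
        self.params["b"] = np.zeros(out_f)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time or rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        """Yield (layer, name, array) triples for the optimizer."""
        for layer in self.layers:
            if isinstance(layer, (Sequential, Residual)):
                yield from layer.parameters()
            else:
                for name in layer.params:
                    yield layer, name

    def n_params(self) -> int:
        total = 0
        for layer in self.layers:
            total += layer.n_params()
        return total


class Residual(Layer):
    """y = ReLU(main(x) + shortcut(x)); shortcut is identity or a 1x1 conv."""

    def __init__(self, main: Sequential, shortcut: Layer | None = None) -> None:
        super().__init__()
        self.main = main
        self.shortcut = shortcut

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        m = self.main.forward(x, train=train)
        s = self.shortcut.forward(x, train=train) if self.shortcut is not None else x
        y = m + s
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        dx_main = self.main.backward(dy)
        dx_short = self.shortcut.backward(dy) if self.shortcut is not None else dy
        return dx_main + dx_short

    def parameters(self):
        yield from self.main.parameters()
        if self.shortcut is not None:
            for name in self.shortcut.params:
                yield self.shortcut, name

    def n_params(self) -> int:
        total = self.main.n_params()
        if self.shortcut is not None:
            total += self.shortcut.n_params()
        return total


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with decoupled weight decay (decay skips biases)."""

    def __init__(self, model: Sequential, lr: float = 1e-4, weight_decay: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        for layer, name in self.model.parameters():
            p = layer.params[name]
            g = layer.grads.get(name)
            if g is None:
                continue
            key = id(p)
            if key not in self.state:
                self.state[key] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self.state[key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and name == "W":
                p -= self.lr * self.wd * p
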