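"""Minimal numpy neural-net layers with manual backprop and Adam.

Just enough machinery for the small residual CNN classifier: 2-D
convolution (1-D inputs are handled as height-1 images), batch
normalization, ReLU, global average pooling, fully connected layers, and
softmax cross-entropy. Shapes follow the (batch, channels, height, width)
convention. Everything is float64 and deterministic given the seeding rng.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "GlobalAvgPool", "Linear",
    "ResidualBlock", "Sequential", "softmax", "cross_entropy_grad", "Adam",
]


class Layer:
    """Base: layers store params/grads in dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def walk(self):
        yield self


class Conv2d(Layer):
    """Strided 2-D convolution (cross-correlation) with explicit padding.

    ``padding`` is ((top, bottom), (left, right)); even kernels use the
    asymmetric pad ((0,1),(0,1)) to preserve spatial size at stride 1.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 stride: int = 1, padding: tuple | str = "same",
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        kh, kw = kernel
        if padding == "same":
            padding = ((kh - 1) // 2, kh // 2), ((kw - 1) // 2, kw // 2)
        self.kh, self.kw, self.stride, self.pad = kh, kw, stride, padding
        rng = rng or np.random.default_rng()
        fan_in = c_in * kh * kw
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kh, kw))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        (pt, pb), (pl, pr) = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        self._xp_shape = xp.shape
        self._xp = xp
        b_, _, hp, wp = xp.shape
        s = self.stride
        h_out = (hp - self.kh) // s + 1
        w_out = (wp - self.kw) // s + 1
        w = self.params["w"]
        out = np.zeros((b_, w.shape[0], h_out, w_out))
        for ki in range(self.kh):
            for kj in range(self.kw):
                xs = xp[:, :, ki: ki + s * h_out: s, kj: kj + s * w_out: s]
                out += np.tensordot(w[:, :, ki, kj], xs, axes=([1], [1])).transpose(1, 0, 2, 3)
        return out + self.params["b"][None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        s = self.stride
        xp = self._xp
        h_out, w_out = g.shape[2], g.shape[3]
        w = self.params["w"]
        dw = np.zeros_like(w)
        dxp = np.zeros(self._xp_shape)
        for ki in range(self.kh):
            for kj in range(self.kw):
                xs = xp[:, :, ki: ki + s * h_out: s, kj: kj + s * w_out: s]
                dw[:, :, ki, kj] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, ki: ki + s * h_out: s, kj: kj + s * w_out: s] += np.tensordot(
                    w[:, :, ki, kj], g, axes=([0], [1])).transpose(1, 0, 2, 3)
        self.grads["w"] = dw
        self.grads["b"] = g.sum(axis=(0, 2, 3))
        (pt, pb), (pl, pr) = self.pad
        h, wdt = dxp.shape[2] - pt - pb, dxp.shape[3] - pl - pr
        return dxp[:, :, pt: pt + h, pl: pl + wdt]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, x.shape[0] * x.shape[2] * x.shape[3], training)
        return self.params["gamma"][None, :, None, None] * xhat + \
            self.params["beta"][None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std, n, training = self._cache
        gamma = self.params["gamma"]
        self.grads["gamma"] = (g * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = g.sum(axis=(0, 2, 3))
        gx = g * gamma[None, :, None, None]
        if not training:
            return gx / std[None, :, None, None]
        mean_gx = gx.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx_xhat = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gx - mean_gx - xhat * mean_gx_xhat) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None,
                 init_scale: float | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in) if init_scale is None else init_scale
        self.params["w"] = rng.normal(0.0, scale, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["w"].T


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def walk(self):
        for layer in self.layers:
            yield from layer.walk()


class ResidualBlock(Layer):
    """y = relu(F(x) + skip(x)); F = conv-BN-relu-conv-BN.

    ``skip`` is the identity unless channels or stride change, in which case
    a 1x1 projection convolution (plus BN) matches the shapes.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 stride: int = 1, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, kernel, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, kernel, stride=1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.relu_out = ReLU()
        self.project = None
        if c_in != c_out or stride != 1:
            self.project = Sequential(
                Conv2d(c_in, c_out, (1, 1), stride=stride, rng=rng),
                BatchNorm2d(c_out),
            )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        f = self.conv1.forward(x, training)
        f = self.bn1.forward(f, training)
        f = self.relu1.forward(f, training)
        f = self.conv2.forward(f, training)
        f = self.bn2.forward(f, training)
        skip = x if self.project is None else self.project.forward(x, training)
        return self.relu_out.forward(f + skip, training)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(g)
        gf = self.bn2.backward(g)
        gf = self.conv2.backward(gf)
        gf = self.relu1.backward(gf)
        gf = self.bn1.backward(gf)
        gf = self.conv1.backward(gf)
        gs = g if self.project is None else self.project.backward(g)
        return gf + gs

    def walk(self):
        yield from self.conv1.walk()
        yield from self.bn1.walk()
        yield from self.conv2.walk()
        yield from self.bn2.walk()
        if self.project is not None:
            yield from self.project.walk()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = y.size
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Adam:
    def __init__(self, root: Layer, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.root, self.lr, self.b1, self.b2, self.eps = root, lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    def step(self) -> None:
        self.t += 1
        for layer in self.root.walk():
            st = self.state.setdefault(id(layer), {})
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                m, v = st.get(name, (np.zeros_like(p), np.zeros_like(p)))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                st[name] = (m, v)
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
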