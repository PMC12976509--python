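"""NumPy building blocks for the patch classifier.

Plain-NumPy implementations of the handful of layers the residual patch
classifier needs: stride-1 3x3 convolution via im2col, batch normalization,
ReLU, 2x2 max pooling, global average pooling, a linear head, softmax
cross-entropy and the Adam optimizer.  Everything runs single-threaded on CPU
and is deterministic given the initialization seed and data order.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def im2col(x: np.ndarray, k: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (b, c, k, k, oh, ow), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    cols = np.ascontiguousarray(view.transpose(0, 4, 5, 1, 2, 3)).reshape(b * oh * ow, c * k * k)
    return cols, (oh, ow)


def col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int, oh: int, ow: int) -> np.ndarray:
    b, c, h, w = x_shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(b, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + oh, j : j + ow] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    """Base: layers expose ``params``/``grads`` dicts for the optimizer."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def state(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k][...] = v


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 same-padding convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k * k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, (oh, ow) = im2col(x, self.k, self.pad)
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, x.shape, oh, ow)
        b = x.shape[0]
        return out.reshape(b, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        dyr = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads["W"] = (dyr.T @ cols).astype(DTYPE)
        self.grads["b"] = dyr.sum(axis=0).astype(DTYPE)
        dcols = dyr @ self.params["W"]
        return col2im(dcols, x_shape, self.k, self.pad, oh, ow)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, x.shape)
        return (self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        axes = (0, 2, 3)
        self.grads["gamma"] = (dy * xhat).sum(axis=axes).astype(DTYPE)
        self.grads["beta"] = dy.sum(axis=axes).astype(DTYPE)
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes)[None, :, None, None]
            - xhat * (dxhat * xhat).mean(axis=axes)[None, :, None, None]
        ) / std[None, :, None, None]
        return dx

    def state(self) -> dict[str, np.ndarray]:
        return {**self.params, "running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = state[k]
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : 2 * h2, : 2 * w2]
        xr = x.reshape(b, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = (b, c, h, w, h2, w2)
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w, h2, w2 = self._in_shape
        dxr = np.zeros((b, c, h2, w2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros((b, c, h, w), dtype=dy.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dxr.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, 2 * h2, 2 * w2)
        )
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in)).astype(DTYPE)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = (dy.T @ self._x).astype(DTYPE)
        self.grads["b"] = dy.sum(axis=0).astype(DTYPE)
        return dy @ self.params["W"]


class ResBlock(Layer):
    """Identity-skip residual block: x + BN(conv(ReLU(BN(conv(x))))),
    followed by ReLU."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.conv_a = Conv2d(c, c, 3, rng)
        self.bn_a = BatchNorm2d(c)
        self.relu_a = ReLU()
        self.conv_b = Conv2d(c, c, 3, rng)
        self.bn_b = BatchNorm2d(c)

    def sublayers(self) -> list[Layer]:
        return [self.conv_a, self.bn_a, self.conv_b, self.bn_b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = self.conv_a.forward(x, train)
        z = self.bn_a.forward(z, train)
        z = self.relu_a.forward(z, train)
        z = self.conv_b.forward(z, train)
        z = self.bn_b.forward(z, train)
        out = x + z
        self._mask = out > 0
        return out * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._mask
        d = self.bn_b.backward(dz)
        d = self.conv_b.backward(d)
        d = self.relu_a.backward(d)
        d = self.bn_a.backward(d)
        d = self.conv_a.backward(d)
        return dz + d


class SmallResCNN:
    """A compact residual CNN for square single-channel patches.

    conv-BN-ReLU-pool, residual block, pool, conv-BN-ReLU-pool, residual
    block, pool, global average pooling, linear softmax head.  Four pooling
    stages, so the input side must be a multiple of 16 (64 by default,
    224 for full-resolution runs).
    """

    def __init__(self, n_classes: int, channels: tuple[int, int] = (8, 16), seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([0xC0FFEE, seed & 0x7FFFFFFF]))
        c1, c2 = channels
        self.n_classes = n_classes
        self.channels = tuple(channels)
        self.seed = seed
        self.conv1 = Conv2d(1, c1, 3, rng)
        self.bn1 = BatchNorm2d(c1)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2()
        self.block1 = ResBlock(c1, rng)
        self.pool2 = MaxPool2()
        self.conv2 = Conv2d(c1, c2, 3, rng)
        self.bn2 = BatchNorm2d(c2)
        self.relu2 = ReLU()
        self.pool3 = MaxPool2()
        self.block2 = ResBlock(c2, rng)
        self.pool4 = MaxPool2()
        self.gap = GlobalAvgPool()
        self.fc = Linear(c2, n_classes, rng)
        self._order: list[Layer] = [
            self.conv1, self.bn1, self.relu1, self.pool1,
            self.block1, self.pool2,
            self.conv2, self.bn2, self.relu2, self.pool3,
            self.block2, self.pool4,
            self.gap, self.fc,
        ]

    def leaf_layers(self) -> list[Layer]:
        leaves: list[Layer] = []
        for layer in self._order:
            if isinstance(layer, ResBlock):
                leaves.extend(layer.sublayers())
            else:
                leaves.append(layer)
        return leaves

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, 1, H, W) float32 in [0, 1]; returns logits (B, n_classes)."""
        out = x.astype(DTYPE)
        for layer in self._order:
            out = layer.forward(out, train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self._order):
            d = layer.backward(d)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.leaf_layers()):
            for k, v in layer.state().items():
                state[f"layer{i}.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.leaf_layers()):
            sub = {k.split(".", 1)[1]: v for k, v in state.items() if k.startswith(f"layer{i}.")}
            layer.load_state(sub)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient wrt logits."""
    b = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(probs[np.arange(b), y], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    return loss, (dlogits / b).astype(DTYPE)


class Adam:
    """Adam with no weight decay and no schedule (constant learning rate)."""

    def __init__(self, layers: list[Layer], lr: float, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (i, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(p, dtype=np.float64)
                    self.v[key] = np.zeros_like(p, dtype=np.float64)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
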