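"""Layers with explicit forward/backward passes.

Shapes follow the channels-first convention: images are (N, C, H, W),
dense inputs are (N, features). Each layer caches what its backward pass
needs; ``backward`` consumes the gradient of the loss w.r.t. the layer
output and returns the gradient w.r.t. the input, accumulating parameter
gradients into ``Param.grad`` along the way.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "LayerNorm",
    "BatchNorm",
    "Flatten",
    "Reshape",
    "Sequential",
]


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


def _xavier_std(fan_in: int, fan_out: int) -> float:
    return float(np.sqrt(2.0 / (fan_in + fan_out)))


def _lecun_std(fan_in: int) -> float:
    return float(np.sqrt(1.0 / fan_in))


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        init: str = "he",
        name: str = "dense",
    ) -> None:
        if init == "he":
            std = _he_std(n_in)
        elif init == "lecun":
            std = _lecun_std(n_in)
        else:
            std = _xavier_std(n_in, n_out)
        self.W = Param(rng.normal(0.0, std, (n_in, n_out)), f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data.T


def _gather_cols(
    x: np.ndarray, k: int, stride: int, pad: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """im2col: (N,C,H,W) -> (N, Ho*Wo, C*k*k) plus the output spatial size."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo)


def _scatter_cols(
    cols: np.ndarray,
    out_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    grid: tuple[int, int],
) -> np.ndarray:
    """col2im: adjoint of :func:`_gather_cols`; overlapping windows add."""
    n, c, h, w = out_shape
    ho, wo = grid
    acc = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    win = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            acc[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += win[
                :, :, :, :, i, j
            ]
    return acc[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """Strided 2D convolution. Output size: floor((H + 2p - k) / s) + 1."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
        name: str = "conv",
    ) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s, self.p = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        self.W = Param(rng.normal(0.0, _he_std(fan_in), (c_out, fan_in)), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, int, int, int] | None = None
        self._grid: tuple[int, int] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_size(self, size: int) -> int:
        return (size + 2 * self.p - self.k) // self.s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = _gather_cols(x, self.k, self.s, self.p)
        self._cols, self._x_shape, self._grid = cols, x.shape, (ho, wo)
        y = cols @ self.W.data.T + self.b.data  # (N, L, c_out)
        return y.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        gy = grad.reshape(n, self.c_out, -1).transpose(0, 2, 1)  # (N, L, c_out)
        self.W.grad += gy.reshape(-1, self.c_out).T @ self._cols.reshape(
            -1, self.c_in * self.k * self.k
        )
        self.b.grad += gy.sum(axis=(0, 1))
        gcols = gy @ self.W.data
        return _scatter_cols(gcols, self._x_shape, self.k, self.s, self.p, self._grid)


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution (the adjoint of :class:`Conv2d`).

    Output size: (H - 1) * s - 2p + k + output_padding; ``output_padding``
    disambiguates which input size a strided convolution came from.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
        output_padding: int = 1,
        name: str = "deconv",
    ) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s, self.p, self.op = kernel, stride, pad, output_padding
        fan_in = c_in * kernel * kernel
        self.W = Param(
            rng.normal(0.0, _he_std(fan_in), (c_in, c_out * kernel * kernel)),
            f"{name}.W",
        )
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._x: np.ndarray | None = None
        self._out_hw: tuple[int, int] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_size(self, size: int) -> int:
        return (size - 1) * self.s - 2 * self.p + self.k + self.op

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, hi, wi = x.shape
        ho, wo = self.out_size(hi), self.out_size(wi)
        self._x, self._out_hw = x, (ho, wo)
        xf = x.reshape(n, self.c_in, hi * wi).transpose(0, 2, 1)  # (N, L, c_in)
        cols = xf @ self.W.data  # (N, L, c_out*k*k)
        out = _scatter_cols(
            cols, (n, self.c_out, ho, wo), self.k, self.s, self.p, (hi, wi)
        )
        return out + self.b.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, hi, wi = self._x.shape
        cols, _ = _gather_cols(grad, self.k, self.s, self.p)  # (N, L, c_out*k*k)
        xf = self._x.reshape(n, self.c_in, hi * wi).transpose(0, 2, 1)
        self.W.grad += xf.reshape(-1, self.c_in).T @ cols.reshape(
            -1, self.c_out * self.k * self.k
        )
        self.b.grad += grad.sum(axis=(0, 2, 3))
        gx = cols @ self.W.data.T  # (N, L, c_in)
        return gx.transpose(0, 2, 1).reshape(self._x.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01) -> None:
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class LayerNorm(Layer):
    """Parameter-free per-sample standardization over the feature axis.

    Keeps downstream saturating activations (the sigmoid bottleneck) in
    their responsive range whatever scale the upstream stack drifts to.
    """

    def __init__(self, eps: float = 1e-5) -> None:
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._sd = np.sqrt(var + self.eps)
        self._y = (x - mu) / self._sd
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gm = grad.mean(axis=1, keepdims=True)
        gy = (grad * self._y).mean(axis=1, keepdims=True)
        return (grad - gm - self._y * gy) / self._sd


class BatchNorm(Layer):
    """Parameter-free feature-wise batch standardization for (N, D) inputs.

    During training each feature is standardized by the batch mean and
    variance, which forces the features to vary across the batch — placed
    on a sigmoid bottleneck's pre-activation this prevents the latent code
    from collapsing to a constant. Inference uses exponential running
    statistics accumulated during training.
    """

    def __init__(self, eps: float = 1e-5, momentum: float = 0.9) -> None:
        self.eps = eps
        self.momentum = momentum
        self.training = True
        self.running_mean: np.ndarray | None = None
        self.running_var: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            if self.running_mean is None:
                self.running_mean = mu.copy()
                self.running_var = var.copy()
            else:
                self.running_mean *= self.momentum
                self.running_mean += (1 - self.momentum) * mu
                self.running_var *= self.momentum
                self.running_var += (1 - self.momentum) * var
        elif self.running_mean is not None:
            mu, var = self.running_mean, self.running_var
        else:  # eval before any training: plain pass-through statistics
            mu, var = np.zeros(x.shape[1]), np.ones(x.shape[1])
        self._sd = np.sqrt(var + self.eps)
        self._batch_stats = self.training and x.shape[0] > 1
        self._y = (x - mu) / self._sd
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if not self._batch_stats:
            return grad / self._sd
        n = grad.shape[0]
        gm = grad.mean(axis=0)
        gy = (grad * self._y).mean(axis=0)
        return (grad - gm - self._y * gy) / self._sd


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(grad.shape[0], -1)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    def train(self, mode: bool = True) -> "Sequential":
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = mode
        return self

    def eval(self) -> "Sequential":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"{i}:{p.name}": p.data.copy() for i, p in enumerate(self.params())}
        for j, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm) and layer.running_mean is not None:
                out[f"buf{j}:running_mean"] = layer.running_mean.copy()
                out[f"buf{j}:running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        n_param_entries = sum(1 for k in state if not k.startswith("buf"))
        if n_param_entries != len(params):
            raise ValueError(
                f"state has {n_param_entries} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = state[f"{i}:{p.name}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data[...] = arr
        for j, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm) and f"buf{j}:running_mean" in state:
                layer.running_mean = state[f"buf{j}:running_mean"].copy()
                layer.running_var = state[f"buf{j}:running_var"].copy()
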