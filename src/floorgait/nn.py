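"""Minimal 1D neural-network engine used by the step-proposal network and
the activity classifier.

The networks here are tiny (four conv blocks and three dense layers at
most), so layers are implemented directly on numpy arrays with hand-written
backward passes.  Data layout is ``(batch, channels, time)`` for
convolutional layers and ``(batch, features)`` after flattening.

Conventions shared by both networks:

* weights are initialized i.i.d. Gaussian with standard deviation 0.2,
  biases at zero, batch-norm gains at one;
* optimization is plain SGD with Nesterov momentum and a learning rate
  decaying geometrically (x0.9) every 10 epochs;
* dropout is inverted (activations scaled by ``1/(1-p)`` at train time);
* frozen layers keep their parameters and, for batch norm, their running
  statistics bitwise fixed, and always normalize with running statistics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "Dense",
    "Tanh",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "MaxPool1d",
    "Flatten",
    "Sequential",
    "SGD",
    "lr_at_epoch",
    "INIT_STD",
]

INIT_STD = 0.2


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "frozen")

    def __init__(self, value: np.ndarray, frozen: bool = False):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.frozen = frozen

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (running statistics)."""
        return {}

    def set_rng(self, rng: np.random.Generator) -> None:
        pass

    @property
    def frozen(self) -> bool:
        ps = self.params()
        return bool(ps) and all(p.frozen for p in ps)

    def freeze(self) -> None:
        for p in self.params():
            p.frozen = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """1D convolution (cross-correlation), valid padding, arbitrary stride."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, init_std: float = INIT_STD):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, init_std, size=(out_channels, in_channels * kernel)))
        self.b = Param(np.zeros(out_channels))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    @staticmethod
    def out_len(t: int, kernel: int, stride: int) -> int:
        if t < kernel:
            raise ValueError(f"input length {t} shorter than kernel {kernel}")
        return (t - kernel) // stride + 1

    def _windows(self, x: np.ndarray) -> np.ndarray:
        # (N, C, T) -> (N, T_out, C * k)
        view = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        view = view[:, :, :: self.stride]  # (N, C, T_out, k)
        return view.transpose(0, 2, 1, 3).reshape(x.shape[0], -1, self.in_channels * self.kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        self._x_shape = x.shape
        self._win = self._windows(np.ascontiguousarray(x))
        y = self._win @ self.w.value.T + self.b.value  # (N, T_out, out)
        return y.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.transpose(0, 2, 1)  # (N, T_out, out)
        n, t_out, _ = g.shape
        flat_g = g.reshape(-1, self.out_channels)
        self.w.grad += flat_g.T @ self._win.reshape(-1, self.in_channels * self.kernel)
        self.b.grad += flat_g.sum(axis=0)
        dwin = (flat_g @ self.w.value).reshape(n, t_out, self.in_channels, self.kernel)
        dx = np.zeros(self._x_shape)
        for j in range(self.kernel):
            dx[:, :, j : j + t_out * self.stride : self.stride] += dwin[:, :, :, j].transpose(0, 2, 1)
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time).

    Running statistics are tracked with momentum 0.1.  A frozen layer
    normalizes with running statistics even in train mode and never
    updates them.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray) -> np.ndarray:
        use_batch = self.train_mode and not self.frozen
        if use_batch:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean
            var = self.running_var
        self._use_batch = use_batch
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._inv_std[None, :, None]
        return self.gamma.value[None, :, None] * self._xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        if not self._use_batch:
            return g * self._inv_std[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        sum_g = g.sum(axis=(0, 2), keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (self._inv_std[None, :, None] / m) * (m * g - sum_g - self._xhat * sum_gx)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, init_std: float = INIT_STD):
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, init_std, size=(out_features, in_features)))
        self.b = Param(np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._y**2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; active only in train mode."""

    def __init__(self, p: float = 0.5):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng()

    def set_rng(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train_mode or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, t = x.shape
        t_out = t // self.size
        blocks = x[:, :, : t_out * self.size].reshape(n, c, t_out, self.size)
        self._argmax = blocks.argmax(axis=3)
        self._in_shape = x.shape
        return blocks.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, t_out = grad.shape
        dx = np.zeros(self._in_shape)
        blocks = dx[:, :, : t_out * self.size].reshape(n, c, t_out, self.size)
        ni, ci, ti = np.ogrid[:n, :c, :t_out]
        blocks[ni, ci, ti, self._argmax] = grad
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.set_rng(rng)

    def set_train(self, mode: bool) -> None:
        for layer in self.layers:
            layer.train_mode = mode
        self.train_mode = mode

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
            p.zero_grad()

    # --- serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                state[f"layer{i}.param{j}"] = p.value.copy()
            for name, buf in layer.buffers().items():
                state[f"layer{i}.{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p.value = state[f"layer{i}.param{j}"].copy()
                p.grad = np.zeros_like(p.value)
            for name in list(layer.buffers()):
                setattr(layer, name, state[f"layer{i}.{name}"].copy())


def lr_at_epoch(lr0: float, epoch: int, decay: float = 0.9, every: int = 10) -> float:
    """Geometric learning-rate schedule: ``lr0 * decay ** (epoch // every)``."""
    return lr0 * decay ** (epoch // every)


class SGD:
    """SGD with Nesterov momentum; frozen parameters are never touched."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = [p for p in params if not p.frozen]
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        mu = self.momentum
        for p, v in zip(self.params, self.velocity):
            v *= mu
            v += p.grad
            p.value -= self.lr * (p.grad + mu * v)
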