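"""A small numpy training backend for the pipeline's networks.

Implements exactly the layers the feature extractors and the stack head
need -- 1D convolution, (bidirectional) LSTM, max-pooling over time, batch
normalization, dropout, dense layers -- together with Adam and a
softmax/cross-entropy loss.  Everything is plain numpy with explicit
backpropagation (including backpropagation through time for the recurrent
layers), so training is bit-reproducible under a seed on any platform.

Array convention: batch-first.  Sequence tensors are ``(N, T, F)``; dense
inputs are ``(N, F)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Conv1D", "LSTM", "Bidirectional", "MaxPool1D", "BatchNorm",
    "Flatten", "Dropout", "ReLU", "Sequential", "Adam",
    "softmax", "softmax_cross_entropy", "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.sum(onehot * np.log(p + eps), axis=1))
    grad = (p - onehot) / logits.shape[0]
    return float(loss), grad


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameters and their gradients live in parallel lists."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def init(self, rng: np.random.Generator, in_shape: tuple) -> tuple:
        """Allocate parameters for ``in_shape`` (sans batch); return out shape."""
        return in_shape

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, units: int, activation: str | None = None) -> None:
        super().__init__()
        self.units = units
        self.activation = activation

    def init(self, rng, in_shape):
        (d,) = in_shape
        self.W = _glorot(rng, d, self.units, (d, self.units))
        self.b = np.zeros(self.units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (self.units,)

    def forward(self, x, train):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv1D(Layer):
    """Valid 1D convolution along time: (N, T, C_in) -> (N, T-k+1, filters)."""

    def __init__(self, filters: int, kernel: int = 2, activation: str | None = "relu") -> None:
        super().__init__()
        self.filters = filters
        self.kernel = kernel
        self.activation = activation

    def init(self, rng, in_shape):
        t, c = in_shape
        if t - self.kernel + 1 < 1:
            raise ValueError(f"sequence length {t} shorter than kernel {self.kernel}")
        self.W = _glorot(rng, self.kernel * c, self.filters,
                         (self.kernel, c, self.filters))
        self.b = np.zeros(self.filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (t - self.kernel + 1, self.filters)

    def forward(self, x, train):
        self._x = x
        n, t, c = x.shape
        t_out = t - self.kernel + 1
        z = np.zeros((n, t_out, self.filters))
        for i in range(self.kernel):
            z += x[:, i:i + t_out, :] @ self.W[i]
        z += self.b
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        x = self._x
        n, t, c = x.shape
        t_out = grad.shape[1]
        gx = np.zeros_like(x)
        for i in range(self.kernel):
            self.grads[0][i] = np.einsum("ntc,ntf->cf", x[:, i:i + t_out, :], grad)
            gx[:, i:i + t_out, :] += grad @ self.W[i].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        return gx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; truncates a ragged tail."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def init(self, rng, in_shape):
        t, c = in_shape
        if t < self.pool:
            raise ValueError(f"sequence length {t} shorter than pool size {self.pool}")
        return (t // self.pool, c)

    def forward(self, x, train):
        n, t, c = x.shape
        t_out = t // self.pool
        xr = x[:, :t_out * self.pool, :].reshape(n, t_out, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        n, t_out, c = grad.shape
        gx = np.zeros(self._in_shape)
        gxr = gx[:, :t_out * self.pool, :].reshape(n, t_out, self.pool, c)
        ni, ti, ci = np.ogrid[:n, :t_out, :c]
        gxr[ni, ti, self._argmax, ci] = grad
        return gx


class BatchNorm(Layer):
    """Normalizes the last axis over all other axes; running stats at inference."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def init(self, rng, in_shape):
        c = in_shape[-1]
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        return in_shape

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        if not self._train:
            return grad * self.gamma / self._std
        m = self._m
        gxhat = grad * self.gamma
        return (gxhat - gxhat.mean(axis=axes)
                - self._xhat * (gxhat * self._xhat).mean(axis=axes)) / self._std


class Flatten(Layer):
    def init(self, rng, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float = 0.2) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def init(self, rng, in_shape):
        self.rng = np.random.default_rng(rng.integers(2 ** 31))
        return in_shape

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class LSTM(Layer):
    """Single LSTM layer returning the full hidden sequence.

    Standard gate order i, f, g, o with sigmoid/tanh nonlinearities, zero
    initial state and forget-gate bias 1.  Backward is full BPTT.
    """

    def __init__(self, units: int) -> None:
        super().__init__()
        self.units = units

    def init(self, rng, in_shape):
        t, d = in_shape
        h = self.units
        self.Wx = _glorot(rng, d, 4 * h, (d, 4 * h))
        self.Wh = _glorot(rng, h, 4 * h, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # forget gate
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        return (t, h)

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def forward(self, x, train):
        n, t, d = x.shape
        h = self.units
        self._x = x
        self._cache = []
        hs = np.zeros((n, t, h))
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        for step in range(t):
            z = x[:, step, :] @ self.Wx + h_t @ self.Wh + self.b
            i = self._sigmoid(z[:, :h])
            f = self._sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = self._sigmoid(z[:, 3 * h:])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tanh_c = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tanh_c
            hs[:, step, :] = h_t
            self._cache.append((i, f, g, o, c_prev, tanh_c, h_prev))
        return hs

    def backward(self, grad):
        x = self._x
        n, t, d = x.shape
        h = self.units
        for g_ in self.grads:
            g_[...] = 0.0
        gx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = self._cache[step]
            dh = grad[:, step, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.grads[0] += x[:, step, :].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            gx[:, step, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return gx


class _Reverse(Layer):
    def forward(self, x, train):
        return x[:, ::-1, :]

    def backward(self, grad):
        return grad[:, ::-1, :]


class Bidirectional(Layer):
    """Runs an LSTM forward and a twin backward; concatenates hidden states."""

    def __init__(self, units: int) -> None:
        super().__init__()
        self.units = units
        self.fwd = LSTM(units)
        self.bwd = LSTM(units)

    def init(self, rng, in_shape):
        t, _ = in_shape
        self.fwd.init(rng, in_shape)
        self.bwd.init(rng, in_shape)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads
        return (t, 2 * self.units)

    def forward(self, x, train):
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1, :], train)[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, grad):
        h = self.units
        gf = self.fwd.backward(grad[:, :, :h])
        gb = self.bwd.backward(grad[:, ::-1, h:])[:, ::-1, :]
        return gf + gb


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential:
    """A feed-forward stack of layers with a Keras-flavored training loop."""

    def __init__(self, layers: list[Layer], n_classes: int = 2,
                 output_activation: str = "linear") -> None:
        if output_activation not in ("linear", "relu"):
            raise ValueError("output_activation must be 'linear' or 'relu'")
        self.layers = layers
        self.n_classes = n_classes
        self.output_activation = output_activation
        self.built = False

    def build(self, input_shape: tuple, seed: int = 0) -> "Sequential":
        rng = np.random.default_rng(seed)
        shape = input_shape
        for layer in self.layers:
            shape = layer.init(rng, shape)
        self._shuffle_rng = np.random.default_rng(rng.integers(2 ** 31))
        self.input_shape = input_shape
        self.built = True
        return self

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool = False,
                upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train)
        if upto is None and self.output_activation == "relu":
            x = np.maximum(x, 0.0)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def _loss_grad(self, x: np.ndarray, onehot: np.ndarray) -> float:
        logits = self.forward(x, train=True)
        if self.output_activation == "relu":
            relu_out = np.maximum(logits, 0.0)
            loss, grad = softmax_cross_entropy(relu_out, onehot)
            grad = grad * (logits > 0)
        else:
            loss, grad = softmax_cross_entropy(logits, onehot)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        logits = self.forward(x, train=False)
        onehot = np.eye(self.n_classes)[y]
        loss, _ = softmax_cross_entropy(logits, onehot)
        acc = float(np.mean(logits.argmax(axis=1) == y))
        return loss, acc

    def fit(self, x: np.ndarray, y: np.ndarray,
            validation: tuple[np.ndarray, np.ndarray] | None = None,
            lr: float = 1e-4, batch_size: int = 32, max_epochs: int = 100,
            patience: int | None = 10) -> dict[str, list[float]]:
        """Adam + cross-entropy minimization with optional early stopping.

        Returns a history dict with one entry per completed epoch for train
        loss/accuracy and, when a validation split is given, val loss/accuracy.
        """
        if not self.built:
            raise RuntimeError("call build() before fit()")
        onehot = np.eye(self.n_classes)[y]
        opt = Adam(self.params, lr=lr)
        history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        if validation is not None:
            history["val_loss"] = []
            history["val_accuracy"] = []
        best_val = np.inf
        best_params = None
        stall = 0
        n = x.shape[0]
        for _epoch in range(max_epochs):
            order = self._shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss = self._loss_grad(x[idx], onehot[idx])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite training loss at epoch {_epoch}; "
                        "lower the learning rate or check the inputs"
                    )
                opt.step(self.grads)
                epoch_loss += loss * len(idx)
            tr_loss, tr_acc = self.evaluate(x, y)
            history["loss"].append(tr_loss)
            history["accuracy"].append(tr_acc)
            if validation is not None:
                va_loss, va_acc = self.evaluate(*validation)
                history["val_loss"].append(va_loss)
                history["val_accuracy"].append(va_acc)
                if patience is not None:
                    if va_loss < best_val - 1e-6:
                        best_val = va_loss
                        best_params = [p.copy() for p in self.params]
                        stall = 0
                    else:
                        stall += 1
                        if stall > patience:
                            break
        if best_params is not None:
            for p, bp in zip(self.params, best_params):
                p[...] = bp
        return history
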