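"""Minimal NumPy neural-network core with explicit backward passes.

Provides exactly the layers the hybrid model needs: dense, batch
normalization, dropout, per-subset graph convolution, strided temporal
convolution, multi-layer LSTM, softmax cross-entropy and the Adam optimizer.
Every layer caches its forward activations and implements an analytic
backward pass; the test suite verifies the gradients against finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "Parameter",
    "Dense",
    "BatchNorm",
    "Dropout",
    "ReLU",
    "GraphConv",
    "TemporalConv",
    "LSTM",
    "GlobalAvgPool",
    "softmax",
    "cross_entropy_loss",
    "Adam",
]

PROB_CLAMP = 1e-12


@dataclass
class Parameter:
    """A named trainable array with its gradient accumulator.

    ``regularized`` marks weight matrices that enter the explicit L2 term of
    the loss; biases and normalization parameters are excluded.
    """

    name: str
    value: np.ndarray
    regularized: bool = True
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; subclasses populate ``self.params``."""

    def __init__(self) -> None:
        self.params: list[Parameter] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    """Affine map ``y = x W + b`` on the trailing feature dimension."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        super().__init__()
        self.W = Parameter(f"{name}.W", _glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = Parameter(f"{name}.b", np.zeros(n_out), regularized=False)
        self.params = [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        self.b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm(Layer):
    """Batch normalization over arbitrary reduction axes.

    ``feature_shape`` is the broadcast shape of gamma/beta (e.g. ``(C, 1, 1)``
    for ``(B, C, T, N)`` inputs with ``axes=(0, 2, 3)``).  Running statistics
    with momentum 0.1 are used at inference time.
    """

    def __init__(self, feature_shape: tuple[int, ...], axes: tuple[int, ...],
                 name: str = "bn", momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.axes = axes
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(feature_shape),
                               regularized=False)
        self.beta = Parameter(f"{name}.beta", np.zeros(feature_shape),
                              regularized=False)
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(feature_shape)
        self.running_var = np.ones(feature_shape)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=self.axes, keepdims=True)
            var = x.var(axis=self.axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.reshape(
                self.running_mean.shape)
            self.running_var = (1 - m) * self.running_var + m * var.reshape(
                self.running_var.shape)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x - mean) if train else None
        self._train = train
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if not self._train:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            return dout * self.gamma.value * inv_std
        xhat, inv_std, xc = self._cache
        m = np.prod([dout.shape[a] for a in self.axes])
        self.gamma.grad += (dout * xhat).sum(axis=self.axes, keepdims=True).reshape(
            self.gamma.value.shape)
        self.beta.grad += dout.sum(axis=self.axes, keepdims=True).reshape(
            self.beta.value.shape)
        dxhat = dout * self.gamma.value
        dvar = (dxhat * xc).sum(axis=self.axes, keepdims=True) * -0.5 * inv_std**3
        dmean = (-dxhat * inv_std).sum(axis=self.axes, keepdims=True) + \
            dvar * (-2.0 * xc).mean(axis=self.axes, keepdims=True)
        return dxhat * inv_std + dvar * 2.0 * xc / m + dmean / m


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValidationError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class GraphConv(Layer):
    """Per-subset graph convolution on channel-last ``(B, T, N, C)`` tensors.

    Equivalent to the dense form ``sum_k A_k X W_k`` applied per frame, with
    ``A`` the stacked ``K x N x N`` subset adjacency.
    """

    def __init__(self, n_in: int, n_out: int, adjacency: np.ndarray,
                 rng: np.random.Generator, name: str = "gcn",
                 learnable_mask: bool = False):
        super().__init__()
        self.A = np.asarray(adjacency, dtype=np.float64)
        K = self.A.shape[0]
        self.n_in = n_in
        self.W = Parameter(f"{name}.W",
                           _glorot(rng, n_in * K, n_out, (K * n_in, n_out)))
        self.b = Parameter(f"{name}.b", np.zeros(n_out), regularized=False)
        self.params = [self.W, self.b]
        self.mask: Parameter | None = None
        if learnable_mask:
            self.mask = Parameter(f"{name}.edge_mask", np.ones_like(self.A),
                                  regularized=False)
            self.params.append(self.mask)

    def _effective_adjacency(self) -> np.ndarray:
        if self.mask is None:
            return self.A
        return self.A * self.mask.value

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        A = self._effective_adjacency()
        B, T, N, C = x.shape
        # xa[..., i, k * C + c] = sum_j A[k, i, j] x[..., j, c]
        xa2 = np.concatenate([Ak @ x for Ak in A], axis=-1)
        self._cache = (x, xa2, A)
        return xa2 @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, xa2, A = self._cache
        B, T, N, C = x.shape
        K = A.shape[0]
        self.W.grad += xa2.reshape(-1, K * C).T @ dout.reshape(-1, dout.shape[-1])
        self.b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        dxa = dout @ self.W.value.T  # (..., K * C)
        dx = np.zeros_like(x)
        for k in range(K):
            dxa_k = dxa[..., k * C:(k + 1) * C]
            dx += np.swapaxes(A[k], 0, 1) @ dxa_k
            if self.mask is not None:
                self.mask.grad[k] += np.einsum(
                    "btic,btjc->ij", dxa_k, x, optimize=True) * self.A[k]
        return dx


class TemporalConv(Layer):
    """Convolution over the time axis of ``(B, T, N, C)``, same padding."""

    def __init__(self, channels: int, kernel: int, stride: int,
                 rng: np.random.Generator, name: str = "tcn"):
        super().__init__()
        if kernel % 2 != 1:
            raise ValidationError("temporal kernel must be odd")
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2
        # packed layout: W[k * C + c, d]
        self.W = Parameter(f"{name}.W",
                           _glorot(rng, channels * kernel, channels,
                                   (kernel * channels, channels)))
        self.b = Parameter(f"{name}.b", np.zeros(channels), regularized=False)
        self.params = [self.W, self.b]

    def out_frames(self, t: int) -> int:
        return (t + 2 * self.pad - self.kernel) // self.stride + 1

    def _taps(self, t_out: int):
        for k in range(self.kernel):
            yield k, slice(k, k + self.stride * (t_out - 1) + 1, self.stride)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, N, C = x.shape
        t_out = self.out_frames(T)
        if t_out < 1:
            raise ValidationError(
                f"sequence too short for temporal convolution: T={T}"
            )
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0), (0, 0)))
        y = np.broadcast_to(self.b.value, (B, t_out, N, self.b.value.shape[0])
                            ).copy()
        W = self.W.value.reshape(self.kernel, C, -1)
        for k, sl in self._taps(t_out):
            y += xp[:, sl] @ W[k]
        self._cache = (xp, (B, T, N, C), t_out)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape, t_out = self._cache
        B, T, N, C = x_shape
        D = dout.shape[-1]
        W = self.W.value.reshape(self.kernel, C, D)
        dW = self.W.grad.reshape(self.kernel, C, D)
        dout2 = dout.reshape(-1, D)
        dxp = np.zeros_like(xp)
        for k, sl in self._taps(t_out):
            xk = np.ascontiguousarray(xp[:, sl]).reshape(-1, C)
            dW[k] += xk.T @ dout2
            dxp[:, sl] += dout @ W[k].T
        self.b.grad += dout2.sum(axis=0)
        return dxp[:, self.pad:self.pad + T]


class SubsampleTime(Layer):
    """Stride-s temporal subsampling used on residual shortcut paths."""

    def __init__(self, stride: int):
        super().__init__()
        self.stride = stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, ::self.stride]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, ::self.stride] = dout
        return dx


class GlobalAvgPool(Layer):
    """Mean over the time and joint axes of ``(B, T, N, C)`` -> ``(B, C)``."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, N, C = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (T * N), self._shape).copy()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class LSTMLayer(Layer):
    """Single LSTM layer over ``(B, T, F)`` returning the full hidden sequence.

    Gate order in the packed weight matrices is (input, forget, cell, output).
    Initial hidden and cell states are zero.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 name: str = "lstm"):
        super().__init__()
        self.hidden = hidden
        H = hidden
        self.Wx = Parameter(f"{name}.Wx", _glorot(rng, n_in, 4 * H, (n_in, 4 * H)))
        self.Wh = Parameter(f"{name}.Wh", _glorot(rng, H, 4 * H, (H, 4 * H)))
        self.b = Parameter(f"{name}.b", np.zeros(4 * H), regularized=False)
        self.params = [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        caches = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((x[:, t, :], h, c, i, f, g, o, c_new, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._caches = caches
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        B, T, H = dhs.shape
        dx = np.zeros((B, T, self.Wx.value.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tanh_c = self._caches[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ], axis=1)
            self.Wx.grad += x_t.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class LSTM(Layer):
    """Stacked LSTM; returns the last hidden state of the final layer."""

    def __init__(self, n_in: int, hidden: int, n_layers: int,
                 rng: np.random.Generator, name: str = "lstm"):
        super().__init__()
        self.layers = [
            LSTMLayer(n_in if i == 0 else hidden, hidden, rng, f"{name}{i}")
            for i in range(n_layers)
        ]
        self.params = [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        self._t = x.shape[1]
        return x[:, -1, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dhs = np.zeros((dout.shape[0], self._t, dout.shape[1]))
        dhs[:, -1, :] = dout
        dx = dhs
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(
    y_true: np.ndarray,
    y_hat: np.ndarray,
    lam: float = 0.0,
    weights: list[np.ndarray] | None = None,
) -> float:
    """Cross entropy plus ``lam / 2`` times the squared norm of the weights.

    ``y_true`` is one-hot (vector or batch), ``y_hat`` holds probabilities,
    clamped at 1e-12 before the log.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y_true.shape != y_hat.shape:
        raise ValidationError(
            f"class-count mismatch: {y_true.shape} vs {y_hat.shape}"
        )
    ce = -np.sum(y_true * np.log(np.clip(y_hat, PROB_CLAMP, None)), axis=-1)
    loss = float(np.mean(ce))
    if lam > 0.0 and weights:
        loss += 0.5 * lam * float(sum(np.sum(w**2) for w in weights))
    return loss


class Adam:
    """Adam optimizer over a list of :class:`Parameter` objects."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
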