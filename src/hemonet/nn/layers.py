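"""Neural-network layers built on the autodiff engine.

Weights are ``Param`` tensors; kernels (not biases or batch-norm scales)
carry ``decay=True`` and receive the L2 penalty during training.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Param", "Layer", "Dense", "Conv1d", "MaxPool1d", "BatchNorm",
    "Activation", "GlobalAvgPool1d", "Flatten", "Sequential",
    "LSTMCellWeights", "lstm_step", "LSTM", "Bidirectional",
]


class Param(Tensor):
    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = False):
        super().__init__(data, requires_grad=True)
        self.decay = decay


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: stateless call + parameter enumeration."""

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        raise NotImplementedError

    def params(self) -> list[Param]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out), decay=True)
        self.b = Param(np.zeros(n_out))

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return ag.add(ag.matmul(x, self.W), self.b)


class Conv1d(Layer):
    """Stride-1 "same"-padded 1-D convolution: (B, C, L) -> (B, O, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = Param(_glorot(rng, (c_out, c_in, kernel), fan_in, fan_out), decay=True)
        self.b = Param(np.zeros(c_out)) if bias else None
        self.kernel = kernel

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return ag.conv1d_same(x, self.W, self.b)


class MaxPool1d(Layer):
    def __init__(self, k: int = 3):
        self.k = k

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return ag.maxpool1d_same(x, self.k)


class BatchNorm(Layer):
    """Batch normalisation over the batch (and time, for 3-D input) axis.

    Training uses batch statistics (gradients flow through them); inference
    uses exponentially tracked running statistics.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        conv = len(x.shape) == 3  # (B, C, L): normalise per channel
        axes = (0, 2) if conv else (0,)
        if train:
            mu = ag.mean(x, axis=axes, keepdims=True)
            var = ag.mean(ag.power(ag.sub(x, mu), 2.0), axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
            inv = ag.power(ag.add(var, self.eps), -0.5)
            xhat = ag.mul(ag.sub(x, mu), inv)
        else:
            shape = (1, -1, 1) if conv else (1, -1)
            mu = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ag.mul(ag.sub(x, mu), inv.reshape(shape))
        shape = (1, -1, 1) if conv else (1, -1)
        return ag.add(
            ag.mul(xhat, ag.reshape(self.gamma, shape)),
            ag.reshape(self.beta, shape),
        )


class Activation(Layer):
    def __init__(self, kind: str, alpha: float = 0.01):
        self.kind = kind
        self.alpha = alpha

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if self.kind == "relu":
            return ag.relu(x)
        if self.kind == "leaky_relu":
            return ag.leaky_relu(x, self.alpha)
        if self.kind == "sigmoid":
            return ag.sigmoid(x)
        if self.kind == "tanh":
            return ag.tanh(x)
        raise ValueError(f"unknown activation {self.kind!r}")


class GlobalAvgPool1d(Layer):
    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return ag.mean(x, axis=2)


class Flatten(Layer):
    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return ag.reshape(x, (x.shape[0], -1))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer(x, train=train)
        return x


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

class LSTMCellWeights:
    """Weights of one LSTM cell.

    Gate blocks are ordered (update, forget, output, candidate); the input
    kernel is (D, 4H), the recurrent kernel (H, 4H), the bias (4H,) with the
    forget block initialised to 1 (standard practice, keeps early gradients
    alive).
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = Param(_glorot(rng, (n_in, 4 * units), n_in, 4 * units), decay=True)
        self.Wa = Param(_glorot(rng, (units, 4 * units), units, 4 * units), decay=True)
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0
        self.b = Param(b)

    def params(self) -> list[Param]:
        return [self.Wx, self.Wa, self.b]


def lstm_step(
    x_t: Tensor,
    a_prev: Tensor,
    c_prev: Tensor,
    weights: LSTMCellWeights,
    literal: bool = False,
) -> tuple[Tensor, Tensor]:
    """One LSTM time step: returns (activation a_t, cell state c_t).

    The canonical form (default) updates the cell state as
    c_t = u * g + f * c_prev and emits a_t = o * tanh(c_t).  With
    ``literal=True`` both the cell update and the output are additionally
    wrapped in a sigmoid (c_t = sigma(u*g + f*c_prev), a_t = sigma(o*c_t)),
    reproducing a non-standard printed variant of the update equations.
    """
    H = weights.units
    z = ag.add(ag.add(ag.matmul(x_t, weights.Wx), ag.matmul(a_prev, weights.Wa)), weights.b)
    u = ag.sigmoid(_slice_gate(z, 0, H))
    f = ag.sigmoid(_slice_gate(z, 1, H))
    o = ag.sigmoid(_slice_gate(z, 2, H))
    g = ag.tanh(_slice_gate(z, 3, H))
    pre_c = ag.add(ag.mul(u, g), ag.mul(f, c_prev))
    if literal:
        c_t = ag.sigmoid(pre_c)
        a_t = ag.sigmoid(ag.mul(o, c_t))
    else:
        c_t = pre_c
        a_t = ag.mul(o, ag.tanh(c_t))
    return a_t, c_t


def _slice_gate(z: Tensor, i: int, H: int) -> Tensor:
    lo, hi = i * H, (i + 1) * H

    def bw(g):
        full = np.zeros_like(z.data)
        full[:, lo:hi] = g
        ag._accum(z, full)

    return ag._make(z.data[:, lo:hi], (z,), bw)


class LSTM(Layer):
    """LSTM over (B, C, L) input, scanning the time (last) axis.

    ``return_sequences`` emits the activation at every step as (B, H, L);
    otherwise only the final activation (B, H).
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False, literal: bool = False):
        self.cell = LSTMCellWeights(n_in, units, rng)
        self.units = units
        self.return_sequences = return_sequences
        self.literal = literal

    def params(self) -> list[Param]:
        return self.cell.params()

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        B, C, L = x.shape
        a = Tensor(np.zeros((B, self.units)))
        c = Tensor(np.zeros((B, self.units)))
        outs = []
        for t in range(L):
            x_t = _slice_time(x, t)
            a, c = lstm_step(x_t, a, c, self.cell, literal=self.literal)
            if self.return_sequences:
                outs.append(ag.reshape(a, (B, self.units, 1)))
        if self.return_sequences:
            return ag.concat(outs, axis=2)
        return a


def _slice_time(x: Tensor, t: int) -> Tensor:
    def bw(g):
        full = np.zeros_like(x.data)
        full[:, :, t] = g
        ag._accum(x, full)

    return ag._make(x.data[:, :, t], (x,), bw)


class Bidirectional(Layer):
    """Runs a forward and a time-reversed LSTM and concatenates features."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.fwd = LSTM(n_in, units, rng, return_sequences=return_sequences)
        self.bwd = LSTM(n_in, units, rng, return_sequences=return_sequences)
        self.return_sequences = return_sequences
        self.units = units

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        yf = self.fwd(x, train=train)
        yb = self.bwd(ag.flip_time(x), train=train)
        if self.return_sequences:
            return ag.concat([yf, ag.flip_time(yb)], axis=1)
        return ag.concat([yf, yb], axis=1)
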