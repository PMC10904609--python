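"""The five deep classifier architectures.

All networks emit unnormalised logits of width ``n_classes``; the softmax
lives in the loss (training) or in ``predict_proba`` (inference).  Dense
networks consume flat (B, T) feature vectors, the sequence networks consume
(B, 1, T) single-channel time series.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (
    Activation,
    BatchNorm,
    Bidirectional,
    Conv1d,
    Dense,
    Flatten,
    GlobalAvgPool1d,
    Layer,
    LSTM,
    MaxPool1d,
    Sequential,
)

__all__ = [
    "build_baseline_dnn",
    "build_lstm",
    "build_bilstm",
    "build_hybrid",
    "InceptionBlock",
    "build_hemo_net",
    "HemoNet",
]


def _check_len(input_len: int, minimum: int = 1) -> None:
    if input_len < minimum:
        raise ValueError(f"input length must be >= {minimum}, got {input_len}")


class Net(Sequential):
    """Sequential network tagged with its expected input layout."""

    input_kind = "flat"

    def __init__(self, *layers: Layer, input_kind: str = "flat"):
        super().__init__(*layers)
        self.input_kind = input_kind


def build_baseline_dnn(input_len: int = 77, n_classes: int = 5,
                       rng: np.random.Generator | None = None) -> Net:
    """Fully connected baseline: dense 1024/512/128/64 each followed by
    batch normalisation and ReLU, then a ``n_classes``-wide output layer."""
    _check_len(input_len)
    rng = np.random.default_rng() if rng is None else rng
    widths = [1024, 512, 128, 64]
    layers: list[Layer] = []
    n_in = input_len
    for w in widths:
        layers += [Dense(n_in, w, rng), BatchNorm(w), Activation("relu")]
        n_in = w
    layers.append(Dense(n_in, n_classes, rng))
    return Net(*layers, input_kind="flat")


def build_lstm(input_len: int = 77, n_classes: int = 5,
               rng: np.random.Generator | None = None,
               literal_cell: bool = False) -> Net:
    """Two stacked LSTM layers of 50 units, then dense 50 and 20 (ReLU),
    batch-normalised throughout, with a ``n_classes`` output layer."""
    _check_len(input_len)
    rng = np.random.default_rng() if rng is None else rng
    return Net(
        LSTM(1, 50, rng, return_sequences=True, literal=literal_cell),
        BatchNorm(50),
        LSTM(50, 50, rng, return_sequences=False, literal=literal_cell),
        BatchNorm(50),
        Dense(50, 50, rng), BatchNorm(50), Activation("relu"),
        Dense(50, 20, rng), BatchNorm(20), Activation("relu"),
        Dense(20, n_classes, rng),
        input_kind="sequence",
    )


def build_bilstm(input_len: int = 77, n_classes: int = 5,
                 rng: np.random.Generator | None = None) -> Net:
    """Three bidirectional LSTM layers (50, 50, 20 units) with batch
    normalisation, a dense layer of 20 (ReLU), and the output layer."""
    _check_len(input_len)
    rng = np.random.default_rng() if rng is None else rng
    return Net(
        Bidirectional(1, 50, rng, return_sequences=True),
        BatchNorm(100),
        Bidirectional(100, 50, rng, return_sequences=True),
        BatchNorm(100),
        Bidirectional(100, 20, rng, return_sequences=False),
        BatchNorm(40),
        Dense(40, 20, rng), Activation("relu"),
        Dense(20, n_classes, rng),
        input_kind="sequence",
    )


class _HybridNet(Layer):
    """Parallel CNN and LSTM heads, concatenated into a dense block."""

    input_kind = "sequence"

    def __init__(self, input_len: int, n_classes: int, rng: np.random.Generator):
        self.cnn = Sequential(
            Conv1d(1, 64, 3, rng), BatchNorm(64), Activation("leaky_relu"),
            Conv1d(64, 64, 5, rng), BatchNorm(64), Activation("leaky_relu"),
            Conv1d(64, 32, 3, rng), BatchNorm(32), Activation("leaky_relu"),
            Flatten(),
            Dense(32 * input_len, 32, rng), BatchNorm(32), Activation("leaky_relu"),
        )
        self.lstm = Sequential(
            LSTM(1, 64, rng, return_sequences=True), BatchNorm(64),
            LSTM(64, 64, rng, return_sequences=True), BatchNorm(64),
            LSTM(64, 32, rng, return_sequences=False), BatchNorm(32),
            Dense(32, 32, rng), BatchNorm(32), Activation("leaky_relu"),
        )
        self.head = Sequential(
            Dense(64, 32, rng), BatchNorm(32), Activation("leaky_relu"),
            Dense(32, 32, rng), BatchNorm(32), Activation("leaky_relu"),
            Dense(32, n_classes, rng),
        )

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        a = self.cnn(x, train=train)
        b = self.lstm(x, train=train)
        return self.head(ag.concat([a, b], axis=1), train=train)


def build_hybrid(input_len: int = 77, n_classes: int = 5,
                 rng: np.random.Generator | None = None) -> _HybridNet:
    """CNN head (1-D convs 64/64/32, kernels 3/5/3, leaky ReLU) in parallel
    with an LSTM head (64/64/32), concatenated into two dense-32 layers."""
    _check_len(input_len)
    rng = np.random.default_rng() if rng is None else rng
    return _HybridNet(input_len, n_classes, rng)


# ---------------------------------------------------------------------------
# Hemo-Net (inception-style)
# ---------------------------------------------------------------------------

class InceptionBlock(Layer):
    """Multi-scale inception block for 1-D time series.

    A 1x1 bottleneck feeds three parallel bias-free convolutions with
    kernel lengths 10/20/40; a stride-1 max-pool path with its own 1x1
    bottleneck runs from the block input.  The four branches (each
    ``n_filters`` wide) are concatenated, batch-normalised and passed
    through ReLU, so the output has 4 * n_filters channels and the input's
    temporal length ("same" padding everywhere).
    """

    def __init__(self, c_in: int, n_filters: int, rng: np.random.Generator,
                 kernel_lengths: tuple[int, ...] = (10, 20, 40),
                 bottleneck: int = 32):
        self.bottleneck = Conv1d(c_in, bottleneck, 1, rng, bias=False)
        self.convs = [
            Conv1d(bottleneck, n_filters, k, rng, bias=False) for k in kernel_lengths
        ]
        self.pool = MaxPool1d(3)
        self.pool_conv = Conv1d(c_in, n_filters, 1, rng, bias=False)
        self.bn = BatchNorm(n_filters * (len(kernel_lengths) + 1))
        self.kernel_lengths = tuple(kernel_lengths)
        self.n_out = n_filters * (len(kernel_lengths) + 1)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        z = self.bottleneck(x)
        branches = [conv(z) for conv in self.convs]
        branches.append(self.pool_conv(self.pool(x)))
        out = ag.concat(branches, axis=1)
        return ag.relu(self.bn(out, train=train))


class HemoNet(Layer):
    """Inception-time style classifier: three inception blocks, a residual
    connection from the input across the block stack (linear 1x1 projection
    plus batch norm), global average pooling over time, and a dense softmax
    classifier."""

    input_kind = "sequence"

    def __init__(self, input_len: int = 77, n_classes: int = 5,
                 n_filters: int = 32, bottleneck: int = 32,
                 kernel_lengths: tuple[int, ...] = (10, 20, 40),
                 residual: bool = True,
                 rng: np.random.Generator | None = None):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        _check_len(input_len)
        rng = np.random.default_rng() if rng is None else rng
        self.blocks = []
        c_in = 1
        for _ in range(3):
            blk = InceptionBlock(c_in, n_filters, rng,
                                 kernel_lengths=kernel_lengths,
                                 bottleneck=bottleneck)
            self.blocks.append(blk)
            c_in = blk.n_out
        self.residual = residual
        self.shortcut = Conv1d(1, c_in, 1, rng, bias=False)
        self.shortcut_bn = BatchNorm(c_in)
        self.gap = GlobalAvgPool1d()
        self.out = Dense(c_in, n_classes, rng)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        h = x
        for blk in self.blocks:
            h = blk(h, train=train)
        if self.residual:
            sc = self.shortcut_bn(self.shortcut(x), train=train)
            h = ag.relu(ag.add(h, sc))
        return self.out(self.gap(h))


def build_hemo_net(input_len: int = 77, n_classes: int = 5,
                   n_filters: int = 32, bottleneck: int = 32,
                   residual: bool = True,
                   rng: np.random.Generator | None = None) -> HemoNet:
    return HemoNet(input_len=input_len, n_classes=n_classes,
                   n_filters=n_filters, bottleneck=bottleneck,
                   residual=residual, rng=rng)
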