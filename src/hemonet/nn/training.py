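"""Deep-network training: Adam, cyclic learning rate, early stopping.

The training plan mirrors the study protocol: batch size 32, L2 weight
penalty, and either a triangular cyclic learning rate in [1e-5, 1e-2]
(baseline DNN and Hemo-Net) or a fixed 1e-4 rate (recurrent and hybrid
models).  Optimiser identity and cycle period are not part of that
protocol; Adam and an 8-epoch triangle are this package's choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import BatchNorm, Layer, Param


def _bn_layers(layer: Layer) -> list[BatchNorm]:
    found: list[BatchNorm] = []
    if isinstance(layer, BatchNorm):
        found.append(layer)
    for v in vars(layer).values():
        if isinstance(v, Layer):
            found.extend(_bn_layers(v))
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Layer):
                    found.extend(_bn_layers(item))
    return found

__all__ = ["TrainingPlan", "train_deep", "predict_proba_net", "TrainingHistory"]


@dataclass(frozen=True)
class TrainingPlan:
    """Hyperparameters of one training run."""

    batch_size: int = 32
    lr_schedule: str = "cyclic"        # "cyclic" | "fixed"
    lr_min: float = 1e-5               # cyclic lower bound
    lr_max: float = 1e-2               # cyclic upper bound
    lr_fixed: float = 1e-4
    cycle_epochs: int = 8              # full triangle period, in epochs
    l2: float = 1e-4                   # weight penalty on kernels
    max_epochs: int = 500
    patience: int = 20                 # early stopping on validation loss
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_min < self.lr_max):
            raise ValueError("need 0 < lr_min < lr_max")
        if self.lr_schedule not in ("cyclic", "fixed"):
            raise ValueError("lr_schedule must be 'cyclic' or 'fixed'")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


class _Adam:
    def __init__(self, params: list[Param], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float, l2: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if getattr(p, "decay", False) and l2 > 0:
                g = g + 2.0 * l2 * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def _lr_at(plan: TrainingPlan, step: int, steps_per_epoch: int) -> float:
    if plan.lr_schedule == "fixed":
        return plan.lr_fixed
    half = max(plan.cycle_epochs * steps_per_epoch // 2, 1)
    cycle_pos = (step % (2 * half)) / half       # 0..2
    tri = 1.0 - abs(cycle_pos - 1.0)             # 0 -> 1 -> 0
    return plan.lr_min + (plan.lr_max - plan.lr_min) * tri


def _prepare_input(net: Layer, X: np.ndarray) -> np.ndarray:
    if getattr(net, "input_kind", "flat") == "sequence":
        return X[:, None, :]
    return X


def _forward_loss(net: Layer, Xb: np.ndarray, yb: np.ndarray, train: bool):
    logits = net(Tensor(Xb), train=train)
    loss = ag.softmax_cross_entropy(logits, yb)
    return logits, loss


def predict_proba_net(net: Layer, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class probabilities in inference mode (running batch-norm statistics)."""
    X = _prepare_input(net, np.asarray(X, float))
    out = []
    for i in range(0, X.shape[0], batch_size):
        logits = net(Tensor(X[i:i + batch_size]), train=False)
        out.append(ag._softmax_np(logits.data))
    return np.concatenate(out, axis=0)


def train_deep(
    net: Layer,
    X: np.ndarray,
    y: np.ndarray,
    plan: TrainingPlan = TrainingPlan(),
) -> TrainingHistory:
    """Train ``net`` in place by minimising multi-class cross-entropy.

    ``y`` holds integer class ids.  A stratification-free random validation
    split of ``plan.val_fraction`` monitors early stopping; the best
    validation-loss weights are restored on exit.  Divergence (non-finite
    loss) raises with the offending epoch.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    rng = np.random.default_rng(plan.seed)
    n = X.shape[0]

    idx = rng.permutation(n)
    n_val = int(round(plan.val_fraction * n)) if plan.patience > 0 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    Xtr_in = _prepare_input(net, Xtr)
    params = net.params()
    bns = _bn_layers(net)
    opt = _Adam(params)
    hist = TrainingHistory()
    steps_per_epoch = max(int(np.ceil(len(tr_idx) / plan.batch_size)), 1)
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None
    best_bn: list[tuple[np.ndarray, np.ndarray]] = []
    bad_epochs = 0
    step = 0

    for epoch in range(plan.max_epochs):
        order = rng.permutation(len(tr_idx))
        losses, correct = [], 0
        for i in range(0, len(order), plan.batch_size):
            sel = order[i:i + plan.batch_size]
            logits, loss = _forward_loss(net, Xtr_in[sel], ytr[sel], train=True)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            loss.backward()
            opt.step(_lr_at(plan, step, steps_per_epoch), plan.l2)
            step += 1
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == ytr[sel]).sum())
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(correct / len(tr_idx))

        if n_val > 0:
            proba = predict_proba_net(net, Xval)
            vloss = float(-np.mean(np.log(proba[np.arange(n_val), yval] + 1e-300)))
            hist.val_loss.append(vloss)
            hist.val_acc.append(float((proba.argmax(axis=1) == yval).mean()))
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_weights = [p.data.copy() for p in params]
                best_bn = [(b.running_mean.copy(), b.running_var.copy()) for b in bns]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= plan.patience:
                    break
        hist.stopped_epoch = epoch + 1

    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p.data = w
        for b, (m, v) in zip(bns, best_bn):
            b.running_mean, b.running_var = m, v
    return hist
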