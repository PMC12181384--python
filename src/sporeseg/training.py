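"""Training loop for the spore-UNet.

Adam optimization (default learning rate 0.002 with the customary
momentum parameters beta1 = 0.9, beta2 = 0.999, which the original
setup leaves unstated), binary cross-entropy on the sigmoid output
(optionally compounded with a soft-Dice term), a fixed epoch budget
(50 by default) and no early stopping.  Runs are bit-reproducible on a
single device given the config seed, which controls both weight
initialization (via the network seed) and batch shuffling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autograd as ag
from .autograd import Tensor
from .io_annotation import BinaryMask
from .metrics import ConfusionCounts, MetricReport, compute_metrics
from .model import SporeUNet
from .preprocessing import Patch

__all__ = ["TrainConfig", "TrainingHistory", "Adam", "train", "evaluate_on_split"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 50
    batch_size: int = 16
    loss_name: str = "bce"  # "bce" or "bce_dice"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("momentum parameters must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss_name not in ("bce", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss_name!r}")


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy curves from one training run."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss if self.val_loss else np.nan,
                "val_accuracy": self.val_accuracy if self.val_accuracy else np.nan,
            }
        )

    def summary(self) -> str:
        df = self.to_dataframe()
        return df.to_string(index=False, float_format=lambda v: f"{v:.4f}")


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 0.002,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_arrays(patches) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, Y) ndarrays or a list of Patch objects."""
    if isinstance(patches, tuple):
        x, y = patches
        return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.float32)
    xs = [p.image.pixels for p in patches]
    ys = [p.mask.pixels for p in patches]
    return (np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32))


def _loss(logits: Tensor, target: np.ndarray, name: str) -> Tensor:
    bce = ag.bce_with_logits(logits, target)
    if name == "bce_dice":
        return ag.add(bce, ag.soft_dice_loss(logits, target))
    return bce


def train(net: SporeUNet, train_patches, val_patches=None,
          config: TrainConfig | None = None) -> tuple[SporeUNet, TrainingHistory]:
    """Train a network on (image, mask) patches.

    ``train_patches``/``val_patches`` are either ``(X, Y)`` float arrays
    of shape (n, H, W) - inputs already preprocessed - or lists of
    :class:`~sporeseg.preprocessing.Patch`.  Returns the trained network
    and the full per-epoch history.
    """
    config = config or TrainConfig()
    x, y = _as_arrays(train_patches)
    if len(x) == 0:
        raise ValueError("empty training set")
    has_val = val_patches is not None and len(
        val_patches[0] if isinstance(val_patches, tuple) else val_patches
    ) > 0
    if has_val:
        xv, yv = _as_arrays(val_patches)

    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    history = TrainingHistory()

    for epoch in range(config.epochs):
        net.train()
        perm = rng.permutation(len(x))
        losses, correct, seen = [], 0, 0
        for start in range(0, len(x), config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = x[idx][:, None]  # (B, 1, H, W)
            yb = y[idx][:, None]
            net.zero_grad()
            logits = net(Tensor(xb))
            loss = _loss(logits, yb, config.loss_name)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data} at epoch {epoch + 1}; "
                    "check input scaling and learning rate"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int(((logits.data > 0) == (yb > 0.5)).sum())
            seen += yb.size
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(correct / seen)

        if has_val:
            vl, va = _eval_loss_acc(net, xv, yv, config)
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
            logger.info(
                "epoch %d/%d  train loss %.4f acc %.4f  val loss %.4f acc %.4f",
                epoch + 1, config.epochs, history.train_loss[-1],
                history.train_accuracy[-1], vl, va,
            )
        else:
            logger.info(
                "epoch %d/%d  train loss %.4f acc %.4f",
                epoch + 1, config.epochs,
                history.train_loss[-1], history.train_accuracy[-1],
            )
    return net, history


def _eval_loss_acc(net: SporeUNet, x: np.ndarray, y: np.ndarray,
                   config: TrainConfig) -> tuple[float, float]:
    net.eval()
    losses, correct, seen = [], 0, 0
    for start in range(0, len(x), config.batch_size):
        xb = x[start : start + config.batch_size][:, None]
        yb = y[start : start + config.batch_size][:, None]
        logits = net(Tensor(xb))
        losses.append(float(_loss(logits, yb, config.loss_name).data) * len(xb))
        correct += int(((logits.data > 0) == (yb > 0.5)).sum())
        seen += yb.size
    return float(np.sum(losses) / len(x)), correct / seen


def evaluate_on_split(net: SporeUNet, patches, threshold: float = 0.5,
                      batch_size: int = 16) -> MetricReport:
    """Pool pixel confusion counts over a patch split and compute the
    six evaluation metrics (micro-averaged)."""
    x, y = _as_arrays(patches)
    if len(x) == 0:
        raise ValueError("empty evaluation split")
    net.eval()
    counts = ConfusionCounts()
    for start in range(0, len(x), batch_size):
        xb = x[start : start + batch_size][:, None]
        yb = y[start : start + batch_size][:, None]
        logits = net(Tensor(xb))
        prob = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        pred = prob > threshold
        truth = yb > 0.5
        counts = counts + ConfusionCounts(
            tp=int(np.count_nonzero(pred & truth)),
            tn=int(np.count_nonzero(~pred & ~truth)),
            fp=int(np.count_nonzero(pred & ~truth)),
            fn=int(np.count_nonzero(~pred & truth)),
        )
    return compute_metrics(counts)
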