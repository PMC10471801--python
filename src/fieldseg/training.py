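"""Dice loss, cosine-annealed learning rate, and the training loop.

The network is optimized with Adam (beta1 = 0.9) on the multi-class Dice
loss -- the mean over classes of 1 - 2*sum(p*g) / (sum(p^2) + sum(g^2)) --
which is insensitive to the foreground/background imbalance of field
scenes.  The learning rate follows cosine annealing from 5e-4 down to
5e-6 over the training run, updated per epoch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .metrics import confusion_matrix, iou
from .network import AttMobileDeeplab, _normalize_image
from .nn import Adam, BatchNorm2d, Tensor, softmax_channels

__all__ = ["TrainConfig", "TrainHistory", "EpochRecord", "dice_loss",
           "dice_loss_tensor", "cosine_lr", "train_epochs", "one_hot",
           "recalibrate_batchnorm"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    lr_initial: float = 5e-4
    lr_min: float = 5e-6
    momentum_beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 1
    seed: int = 0
    freeze_backbone: bool = False
    bn_recalibrate: bool = True

    def __post_init__(self):
        if self.lr_min >= self.lr_initial:
            raise ValueError("lr_min must be below lr_initial")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    lr: float
    val_miou: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    @property
    def train_losses(self) -> list[float]:
        return [r.train_loss for r in self.records]

    @property
    def learning_rates(self) -> list[float]:
        return [r.lr for r in self.records]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss", "lr",
                             "val_miou"])
            for r in self.records:
                writer.writerow([r.epoch, r.train_loss, r.val_loss, r.lr,
                                 r.val_miou])


def dice_loss(probs, targets) -> float:
    """Multi-class Dice loss of plain arrays; value in [0, 1].

    1-D inputs are a single class; otherwise axis 0 indexes classes and
    the result is the mean of the per-class binary Dice losses.  A class
    empty in both prediction and truth is a perfect (zero-loss) match and
    is excluded from the mean.
    """
    p = np.asarray(probs, dtype=np.float64)
    g = np.asarray(targets, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("probs and targets must have the same shape")
    if p.ndim == 1:
        p = p[None]
        g = g[None]
    c = p.shape[0]
    p = p.reshape(c, -1)
    g = g.reshape(c, -1)
    inter = (p * g).sum(axis=1)
    denom = (p * p).sum(axis=1) + (g * g).sum(axis=1)
    defined = denom > 0
    if not defined.any():
        return 0.0
    losses = 1.0 - 2.0 * inter[defined] / denom[defined]
    return float(losses.mean())


def dice_loss_tensor(scores: Tensor, onehot: np.ndarray,
                     eps: float = 1e-5) -> Tensor:
    """Differentiable Dice loss of raw class scores vs a one-hot target.

    ``scores`` is N x C x H x W; softmax over channels gives the per-pixel
    class probabilities of the loss.  ``eps`` guards the denominator
    (softmax probabilities keep it positive anyway).
    """
    p = softmax_channels(scores)
    g = Tensor(onehot.astype(np.float32))
    axes = (0, 2, 3)
    inter = (p * g).sum(axis=axes)
    denom = (p * p).sum(axis=axes) + (g * g).sum(axis=axes) + np.float32(eps)
    per_class = 1.0 - (inter * np.float32(2.0)) / denom
    return per_class.mean()


def cosine_lr(t: int | float, total: int, lr_initial: float = 5e-4,
              lr_min: float = 5e-6) -> float:
    """lr(t) = lr_min + (lr_initial - lr_min) (1 + cos(pi t / T)) / 2."""
    if total < 1:
        raise ValueError("total epochs must be >= 1")
    if not 0 <= t <= total:
        raise ValueError(f"epoch {t} outside [0, {total}]")
    return float(lr_min + 0.5 * (lr_initial - lr_min)
                 * (1.0 + np.cos(np.pi * t / total)))


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """(H, W) labels -> (num_classes, H, W) one-hot float32."""
    return (np.arange(num_classes)[:, None, None] ==
            np.asarray(mask)[None]).astype(np.float32)


def _as_pairs(dataset):
    pairs = []
    for item in dataset:
        if hasattr(item, "image") and hasattr(item, "mask"):
            pairs.append((item.image, item.mask))
        else:
            pairs.append((item[0], item[1]))
    return pairs


def recalibrate_batchnorm(network: AttMobileDeeplab, dataset,
                          batch_size: int = 8) -> None:
    """Replace the batch-norm running statistics with cumulative averages
    from one forward sweep over ``dataset``.

    Short training runs leave the exponential running estimates far from
    the activation statistics the trained weights produce; recomputing
    them (the usual "precise BN" / stochastic-weight-averaging update)
    makes eval-mode behavior match train-mode behavior.
    """
    pairs = _as_pairs(dataset)
    bns = [m for m in network.modules() if isinstance(m, BatchNorm2d)]
    if not bns or not pairs:
        return
    saved = [(bn.momentum, bn.running_mean.copy(), bn.running_var.copy())
             for bn in bns]
    for bn in bns:
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 0.0
    network.train()
    try:
        n_batches = 0
        for lo in range(0, len(pairs), batch_size):
            batch = pairs[lo:lo + batch_size]
            for bn in bns:
                bn.momentum = 1.0 / (n_batches + 1)    # cumulative average
            x = np.concatenate([_normalize_image(img) for img, _ in batch])
            network(Tensor(x))
            n_batches += 1
    except Exception:
        for bn, (mom, mean, var) in zip(bns, saved):
            bn.momentum, bn.running_mean, bn.running_var = mom, mean, var
        raise
    for bn, (mom, _, _) in zip(bns, saved):
        bn.momentum = mom
    network.eval()


def _evaluate(network: AttMobileDeeplab, pairs, num_classes: int
              ) -> tuple[float, float]:
    network.eval()
    losses = []
    cm = None
    for image, mask in pairs:
        scores = network(Tensor(_normalize_image(image)))
        g = one_hot(mask, num_classes)[None]
        losses.append(float(dice_loss_tensor(scores, g).data))
        pred = scores.data[0].argmax(axis=0)
        m = confusion_matrix(pred, mask, num_classes - 1)
        cm = m if cm is None else cm + m
    _, miou = iou(cm)
    return float(np.mean(losses)), miou


def train_epochs(network: AttMobileDeeplab, dataset, config: TrainConfig,
                 val_dataset=None) -> TrainHistory:
    """Mini-batch Adam training of the segmentation network.

    Shuffling and any weight initialization randomness derive from
    ``config.seed``; with a fixed seed and single-threaded execution the
    run is bitwise reproducible.  ``epochs == 0`` returns an empty history
    and leaves the weights untouched.
    """
    pairs = _as_pairs(dataset)
    if not pairs:
        raise ValueError("dataset is empty")
    val_pairs = _as_pairs(val_dataset) if val_dataset else []
    num_classes = network.config.num_classes
    history = TrainHistory()
    if config.epochs == 0:
        return history
    if config.freeze_backbone:
        frozen = {id(p) for p in network.backbone.parameters()}
        params = [p for p in network.parameters() if id(p) not in frozen]
    else:
        params = network.parameters()
    optimizer = Adam(params, lr=config.lr_initial,
                     beta1=config.momentum_beta1, beta2=config.beta2)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr_initial, config.lr_min)
        optimizer.lr = lr
        network.train()
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            batch = [pairs[i] for i in order[lo:lo + config.batch_size]]
            x = np.concatenate([_normalize_image(img) for img, _ in batch])
            g = np.stack([one_hot(msk, num_classes) for _, msk in batch])
            optimizer.zero_grad()
            loss = dice_loss_tensor(network(Tensor(x)), g)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss {value} at epoch {epoch}, "
                    f"batch starting {lo}; lr={lr:.2e}")
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        if val_pairs:
            if config.bn_recalibrate:
                recalibrate_batchnorm(network, pairs, config.batch_size)
            val_loss, val_miou = _evaluate(network, val_pairs, num_classes)
        else:
            val_loss, val_miou = float("nan"), float("nan")
        history.records.append(EpochRecord(
            epoch=epoch, train_loss=float(np.mean(epoch_losses)),
            val_loss=val_loss, lr=lr, val_miou=val_miou))
    if config.bn_recalibrate and not val_pairs:
        recalibrate_batchnorm(network, pairs, config.batch_size)
    network.eval()
    return history
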