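"""From-scratch training with generalized Dice loss and Adam.

Hyperparameters follow the published recipe: initial learning rate 0.001,
squared-gradient (second-moment) decay 0.95, L2 regularization 0.0005,
35 epochs by default.  The generalized Dice loss weights each class by the
squared reciprocal of its pixel volume, recomputed per batch, which keeps
the dominant blastocoel/background pixels from swamping the small inner-
cell-mass class.  Validation is split by *source* image so augmented
variants never leak across the split; the best-validation-loss weights
are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import SegmentationNet
from .phantom import SegmentationSample
from .stem import StemConfig

__all__ = [
    "TrainConfig",
    "LossConfig",
    "TrainingHistory",
    "generalized_dice_loss",
    "one_hot",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    squared_gradient_decay: float = 0.95
    l2_regularization: float = 0.0005
    epochs: int = 35
    batch_size: int = 1
    val_fraction: float = 0.1
    flip_augment: bool = True
    bn_recalibrate: bool = False
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if min(self.learning_rate, self.squared_gradient_decay, self.l2_regularization) < 0:
            raise ValueError("hyperparameters must be nonnegative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")
        return self


@dataclass(frozen=True)
class LossConfig:
    """Generalized Dice loss settings; class weights are the squared
    reciprocal per-batch class volumes (absent classes excluded)."""

    epsilon: float = 1e-5


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def one_hot(masks: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """(N, H, W) integer masks -> (N, C, H, W) one-hot float32."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    out = np.zeros((masks.shape[0], n_classes) + masks.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c][masks == c] = 1.0
    return out


def generalized_dice_loss(
    probabilities: np.ndarray, one_hot_targets: np.ndarray, config: LossConfig = LossConfig()
) -> float:
    """Scalar generalized Dice loss of plain arrays (evaluation-side API)."""
    t = nn.generalized_dice_loss(
        nn.Tensor(np.asarray(probabilities, dtype=np.float32)),
        np.asarray(one_hot_targets, dtype=np.float32),
        eps=config.epsilon,
    )
    return float(t.data)


def _flip2d(arr: np.ndarray, flip_h: bool, flip_v: bool) -> np.ndarray:
    out = arr
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def _split_by_group(n: int, groups, val_fraction: float, rng: np.random.Generator):
    groups = np.asarray(groups if groups is not None else np.arange(n))
    uniq = np.unique(groups)
    n_val = int(round(len(uniq) * val_fraction))
    val_groups = set(rng.permutation(uniq)[:n_val].tolist())
    val_idx = np.array([i for i in range(n) if groups[i] in val_groups], dtype=int)
    train_idx = np.array([i for i in range(n) if groups[i] not in val_groups], dtype=int)
    return train_idx, val_idx


def train(
    net: SegmentationNet,
    dataset: list[SegmentationSample],
    train_config: TrainConfig = TrainConfig(),
    loss_config: LossConfig = LossConfig(),
    groups: list[int] | None = None,
    stem_config: StemConfig = StemConfig(),
    verbose: bool = False,
) -> tuple[SegmentationNet, TrainingHistory]:
    """Train ``net`` in place; returns it (best-validation weights) + history.

    ``groups[i]`` identifies the source image of sample ``i`` so that
    augmented variants of one image never straddle the train/validation
    split.  Deterministic given ``train_config.seed`` on a single-threaded
    run.
    """
    train_config.validate()
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(train_config.seed)
    n_classes = net.config.n_classes

    # the stem is fixed preprocessing: compute every modality stack once.
    # With on-the-fly flip augmentation the stacks of all four flip states
    # are precomputed too (LBP codes are not mirror-equivariant, so flipped
    # images need their stems recomputed, not their channels mirrored).
    masks = np.stack([s.mask for s in dataset])
    flip_states = (
        ((False, False), (True, False), (False, True), (True, True))
        if train_config.flip_augment
        else ((False, False),)
    )
    stacks_by_flip = []
    masks_by_flip = []
    for fh, fv in flip_states:
        imgs = [_flip2d(s.image, fh, fv) for s in dataset]
        stacks_by_flip.append(np.stack([net.prepare_input(im, stem_config) for im in imgs]))
        masks_by_flip.append(np.stack([_flip2d(s.mask, fh, fv) for s in dataset]))
    stacks = stacks_by_flip[0]
    targets_by_flip = [one_hot(m, n_classes) for m in masks_by_flip]
    targets = targets_by_flip[0]

    train_idx, val_idx = _split_by_group(len(dataset), groups, train_config.val_fraction, rng)
    if len(train_idx) == 0:
        raise ValueError("validation split left no training samples")

    opt = nn.Adam(
        net.parameters(),
        lr=train_config.learning_rate,
        beta2=train_config.squared_gradient_decay,
        l2=train_config.l2_regularization,
    )
    history = TrainingHistory()
    best_val = np.inf
    best_state = None
    bs = train_config.batch_size

    for epoch in range(train_config.epochs):
        order = rng.permutation(train_idx)
        losses, correct, total = [], 0, 0
        for lo in range(0, len(order), bs):
            idx = order[lo : lo + bs]
            opt.zero_grad()
            if len(flip_states) > 1:
                states = rng.integers(0, len(flip_states), len(idx))
                batch_x = np.stack([stacks_by_flip[s][i] for s, i in zip(states, idx)])
                batch_t = np.stack([targets_by_flip[s][i] for s, i in zip(states, idx)])
                batch_m = np.stack([masks_by_flip[s][i] for s, i in zip(states, idx)])
            else:
                batch_x, batch_t, batch_m = stacks[idx], targets[idx], masks[idx]
            probs = net.forward(batch_x, training=True)
            loss = nn.generalized_dice_loss(probs, batch_t, eps=loss_config.epsilon)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // bs}: {float(loss.data)}"
                )
            nn.backward(loss)
            opt.step()
            losses.append(float(loss.data))
            pred = probs.data.argmax(axis=1)
            correct += int((pred == batch_m).sum())
            total += pred.size
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(correct / max(total, 1))

        if len(val_idx):
            vl, va = evaluate_loss_acc(net, stacks[val_idx], masks[val_idx], targets[val_idx], bs, loss_config)
            history.val_loss.append(vl)
            history.val_acc.append(va)
            if vl < best_val:
                best_val, best_state, history.best_epoch = vl, net.state_dict(), epoch
        if verbose:
            msg = f"epoch {epoch + 1}/{train_config.epochs} loss {history.train_loss[-1]:.4f} acc {history.train_acc[-1]:.4f}"
            if len(val_idx):
                msg += f" val_loss {history.val_loss[-1]:.4f} val_acc {history.val_acc[-1]:.4f}"
            print(msg)

    if best_state is not None:
        net.load_state_dict({k: v.copy() for k, v in best_state.items()})
    else:
        history.best_epoch = train_config.epochs - 1
    if train_config.bn_recalibrate:
        recalibrate_batch_norm(net, stacks, bs)
    return net, history


def recalibrate_batch_norm(net, stacks: np.ndarray, batch_size: int = 4) -> None:
    """Recompute batch-norm running statistics as exact means over a dataset.

    After few-epoch training the exponentially averaged statistics can lag
    the trained weights; one calibration pass over the training stacks
    replaces them with plain averages of the per-batch moments.
    """

    def _bns(module):
        out = [module] if isinstance(module, nn.BatchNorm2d) else []
        for _, m in module.submodules():
            out.extend(_bns(m))
        return out

    bns = _bns(net)
    saved = [b.momentum for b in bns]
    for b in bns:
        b.running_mean[...] = 0.0
        b.running_var[...] = 0.0
    try:
        for k, lo in enumerate(range(0, len(stacks), batch_size), start=1):
            for b in bns:
                b.momentum = 1.0 / k  # cumulative arithmetic mean
            net.forward(stacks[lo : lo + batch_size], training=True)
    finally:
        for b, m in zip(bns, saved):
            b.momentum = m


def evaluate_loss_acc(net, stacks, masks, targets, batch_size, loss_config=LossConfig()):
    """Mean loss and global pixel accuracy in inference mode."""
    losses, correct, total = [], 0, 0
    for lo in range(0, len(stacks), batch_size):
        sl = slice(lo, lo + batch_size)
        probs = net.forward(stacks[sl], training=False)
        loss = nn.generalized_dice_loss(probs, targets[sl], eps=loss_config.epsilon)
        losses.append(float(loss.data) * (min(lo + batch_size, len(stacks)) - lo))
        pred = probs.data.argmax(axis=1)
        correct += int((pred == masks[sl]).sum())
        total += pred.size
    return float(np.sum(losses) / len(stacks)), correct / max(total, 1)
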