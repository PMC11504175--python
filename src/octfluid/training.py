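"""Training protocol: combined BCE+Dice loss, Adam, plateau LR decay,
early stopping, L2 regularization, augmentation and the 80-20 split.

The loss is ``w_bce * BCE + w_dice * DiceLoss`` over the per-class sigmoid
maps against one-hot targets of the three fluid classes; background enters
only through the negative BCE terms.  The learning rate drops by exactly
``plateau_factor`` whenever validation loss fails to improve by more than
1e-4 for ``plateau_patience`` epochs; training stops after
``early_stop_patience`` unimproved epochs and the best-validation weights
are restored.  One master seed fans out to the split (+1), batch
shuffling (+2) and augmentation (+3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._autodiff import Tensor
from ._nn import Adam
from .errors import ConfigError, DivergenceError, ShapeError
from .network import SegmentationNetwork, predict_mask

EPS = 1e-6
IMPROVE_TOL = 1e-4  # an "improvement" must beat the best loss by this much


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 10
    l2_coeff: float = 0.0001
    loss_weights: tuple = (1.0, 1.0)
    val_fraction: float = 0.2
    seed: int = 0
    augment: bool = False
    max_steps: int | None = None  # optional hard cap on optimizer steps
    validate_on_train: bool = False  # overfit diagnostic: no held-out split

    def __post_init__(self):
        if not (0 < self.plateau_factor < 1):
            raise ConfigError("plateau_factor must be in (0, 1)")
        if not (0 < self.val_fraction < 1):
            raise ConfigError("val_fraction must be in (0, 1)")
        for name in ("plateau_patience", "batch_size", "max_epochs",
                     "early_stop_patience"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        w_bce, w_dice = self.loss_weights
        if w_bce < 0 or w_dice < 0 or (w_bce == 0 and w_dice == 0):
            raise ConfigError("loss_weights must be >= 0 and not both zero")


@dataclass
class TrainHistory:
    """Per-epoch records; the lr column is non-increasing by construction."""

    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)   # per-class tuple per epoch
    lr: list = field(default_factory=list)

    def n_epochs(self) -> int:
        return len(self.epoch)


# ------------------------------------------------------------------ losses

def _check_pair(probs, target):
    pshape = probs.shape if isinstance(probs, Tensor) else np.shape(probs)
    if tuple(pshape) != tuple(np.shape(target)):
        raise ShapeError(f"probs {tuple(pshape)} vs target "
                         f"{tuple(np.shape(target))}")


def dice_loss(probs, target) -> Tensor:
    """1 - mean over classes of (2 sum(p t) + eps) / (sum p + sum t + eps)."""
    _check_pair(probs, target)
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    t = np.asarray(target, dtype=p.data.dtype)
    axes = (0, 2, 3) if p.data.ndim == 4 else tuple(
        i for i in range(p.data.ndim) if i != 0)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (inter * 2.0 + EPS) / (denom + EPS)
    return 1.0 - dice.mean()


def bce_loss(probs, target) -> Tensor:
    """Mean binary cross-entropy over all pixels and classes."""
    _check_pair(probs, target)
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    t = np.asarray(target, dtype=p.data.dtype)
    pc = p.clip(EPS, 1.0 - EPS)
    ll = pc.log() * t + (1.0 - pc).log() * (1.0 - t)
    return -ll.mean()


def combined_loss(probs, target, weights=(1.0, 1.0)) -> Tensor:
    w_bce, w_dice = weights
    if w_bce < 0 or w_dice < 0 or (w_bce == 0 and w_dice == 0):
        raise ConfigError("loss weights must be >= 0 and not both zero")
    total = None
    if w_bce:
        total = bce_loss(probs, target) * w_bce
    if w_dice:
        d = dice_loss(probs, target) * w_dice
        total = d if total is None else total + d
    return total


# ----------------------------------------------------- input preparation

def normalize_inputs(image: np.ndarray) -> np.ndarray:
    """Standardize to zero mean and unit variance."""
    image = np.asarray(image, dtype=float)
    std = image.std()
    if std == 0:
        raise ConfigError("cannot normalize a constant image (zero variance)")
    return (image - image.mean()) / std


def one_hot(mask: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """(H,W) labels -> (C,H,W) one-hot over the fluid classes 1..n."""
    mask = np.asarray(mask)
    return np.stack([(mask == c + 1).astype(np.float32)
                     for c in range(n_classes)])


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator) -> tuple:
    """Random horizontal flip, +-10 degree rotation and multiplicative
    intensity jitter in [0.9, 1.1], each applied with probability 0.5;
    geometric transforms hit image and mask identically (mask by
    nearest-neighbour, so no new labels appear)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if rng.random() < 0.5:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if rng.random() < 0.5:
        angle = rng.uniform(-10.0, 10.0)
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="nearest")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="nearest")
    if rng.random() < 0.5:
        image = np.clip(image * rng.uniform(0.9, 1.1), 0.0, 1.0)
    return image, mask


def split_dataset(items: list, val_fraction: float = 0.2,
                  seed: int = 0) -> tuple:
    """Seeded disjoint, exhaustive train/validation split."""
    n = len(items)
    if n < 2:
        raise ConfigError("need at least 2 items to split")
    if not (0 < val_fraction < 1):
        raise ConfigError("val_fraction must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_val = min(max(int(round(val_fraction * n)), 1), n - 1)
    val_idx = set(order[:n_val].tolist())
    train = [items[i] for i in range(n) if i not in val_idx]
    val = [items[i] for i in range(n) if i in val_idx]
    return train, val


# ------------------------------------------------------------ training loop

@dataclass
class Sample:
    """One training example: enhanced image, edge map and label mask."""

    image: np.ndarray  # (H, W) in [0, 1]
    edge: np.ndarray   # (H, W) in [0, 1]
    mask: np.ndarray   # (H, W) labels {0..3}


def _batch_arrays(samples, n_classes, augment, rng):
    imgs, edges, targets = [], [], []
    for s in samples:
        img, mask = s.image, s.mask
        if augment:
            img, mask = augment_pair(img, mask, rng)
        imgs.append(normalize_inputs(img))
        edges.append(s.edge)
        targets.append(one_hot(mask, n_classes))
    x = np.stack(imgs)[:, None].astype(np.float32)
    e = np.stack(edges)[:, None].astype(np.float32)
    t = np.stack(targets).astype(np.float32)
    return x, e, t


def _evaluate_split(model, samples, n_classes, weights):
    """Validation loss and per-class Dice at threshold 0.5."""
    inters = np.zeros(n_classes)
    sums = np.zeros(n_classes)
    x, e, t = _batch_arrays(samples, n_classes, False, None)
    probs = model.forward_tensor(Tensor(x), Tensor(e))
    loss = float(combined_loss(probs, t, weights).data)
    for i, s in enumerate(samples):
        pred = predict_mask(probs.data[i])
        for c in range(n_classes):
            pm = pred == c + 1
            tm = s.mask == c + 1
            inters[c] += np.logical_and(pm, tm).sum()
            sums[c] += pm.sum() + tm.sum()
    dice = tuple((2 * inters[c] / sums[c]) if sums[c] else 1.0
                 for c in range(n_classes))
    return loss, dice


def train(model: SegmentationNetwork, dataset: list,
          config: TrainConfig) -> tuple:
    """Mini-batch Adam training; returns (model, TrainHistory).

    `dataset` is a list of Sample.  The model is left holding the weights
    that achieved the best validation loss.
    """
    if not dataset:
        raise ConfigError("empty dataset")
    n_classes = model.spec.n_classes
    if config.validate_on_train or len(dataset) < 2:
        train_set, val_set = list(dataset), list(dataset)
    else:
        train_set, val_set = split_dataset(
            dataset, config.val_fraction, seed=config.seed + 1)

    shuffle_rng = np.random.default_rng(config.seed + 2)
    aug_rng = np.random.default_rng(config.seed + 3)

    params = model.parameters()
    opt = Adam(params, lr=config.lr, l2_coeff=config.l2_coeff)
    history = TrainHistory()

    lr = config.lr
    best_val = np.inf
    best_state = model.state_dict()
    plateau_count = 0
    stall_count = 0
    steps = 0

    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            if config.max_steps is not None and steps >= config.max_steps:
                break
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            x, e, t = _batch_arrays(batch, n_classes, config.augment, aug_rng)
            opt.zero_grad()
            probs = model.forward_tensor(Tensor(x), Tensor(e))
            loss = combined_loss(probs, t, config.loss_weights)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.lr = lr
            opt.step()
            steps += 1
            epoch_losses.append(lv)

        val_loss, val_dice = _evaluate_split(
            model, val_set, n_classes, config.loss_weights)
        history.epoch.append(epoch)
        history.train_loss.append(
            float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        history.lr.append(lr)

        if val_loss < best_val - IMPROVE_TOL:
            best_val = val_loss
            best_state = model.state_dict()
            plateau_count = 0
            stall_count = 0
        else:
            plateau_count += 1
            stall_count += 1
            if plateau_count >= config.plateau_patience:
                lr *= config.plateau_factor
                plateau_count = 0
        if stall_count >= config.early_stop_patience:
            break
        if config.max_steps is not None and steps >= config.max_steps:
            break

    model.load_state_dict(best_state)
    return model, history
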