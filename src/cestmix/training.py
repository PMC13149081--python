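"""Losses, learning-rate schedule, early stopping and patient-level splits.

Defaults mirror the training protocol the networks are trained with at full
scale: SGD (lr 1e-4, momentum 0.9, weight decay 1e-4), batch sizes 8
(segmentation) / 128 (genotype), up to 500 epochs with patience 30, linear
warmup over 10 epochs (factor 0.001) followed by cosine annealing (scale
0.001), class weights 9:1 for segmentation and inverse class frequencies for
genotype, all splits stratified with seed 42.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 500
    patience: int = 30
    warmup_epochs: int = 10
    warmup_factor: float = 1e-3
    cosine_scale: float = 1e-3
    class_weights: tuple[float, float] = (1.0, 9.0)  # (background, tumor)
    alpha_bce: float = 1.0
    beta_dice: float = 1.0
    clip_norm: float = 1.0  # global gradient-norm ceiling
    augment: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("learning_rate", "momentum", "weight_decay", "batch_size",
                     "patience", "warmup_factor", "cosine_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.max_epochs and self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def combined_loss(
    probs: np.ndarray,
    target: np.ndarray,
    class_weights: tuple[float, float] = (1.0, 1.0),
    pixel_mask: np.ndarray | None = None,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy plus soft Dice on the foreground class.

    ``probs`` is (..., 2) softmax output; ``target`` binary with matching
    leading shape.  The BCE term is the weight-normalized mean of per-pixel
    cross-entropy on the foreground probability (equivalent to 2-class
    cross-entropy with a softmax head); the Dice term is one global soft Dice
    over all included pixels.  ``pixel_mask`` excludes pixels from both terms.
    Returns ``(loss, dL/dprobs)`` with the gradient on the foreground column.
    """
    probs = np.asarray(probs)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    t = np.asarray(target).astype(np.float64)
    p = np.clip(probs[..., 1].astype(np.float64), _EPS, 1.0 - _EPS)
    w = np.where(t > 0.5, class_weights[1], class_weights[0])
    if pixel_mask is not None:
        w = w * np.asarray(pixel_mask, dtype=np.float64)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("no pixels included in the loss")

    # class-weighted BCE
    bce = -(w * (t * np.log(p) + (1.0 - t) * np.log(1.0 - p))).sum() / wsum
    dbce = -(w * (t / p - (1.0 - t) / (1.0 - p))) / wsum

    # global soft Dice on included pixels
    m = (w > 0).astype(np.float64)
    inter = (m * p * t).sum()
    denom = (m * p).sum() + (m * t).sum() + _EPS
    dice_loss = 1.0 - (2.0 * inter + _EPS) / denom
    ddice = -m * (2.0 * t * denom - (2.0 * inter + _EPS)) / denom**2

    loss = alpha * bce + beta * dice_loss
    grad = np.zeros_like(probs, dtype=np.float64)
    grad[..., 1] = alpha * dbce + beta * ddice
    return float(loss), grad


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Linear warmup to the base rate, then cosine annealing down to
    ``base * cosine_scale`` at the final epoch."""
    if epoch < 0 or epoch >= config.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.max_epochs})")
    base = config.learning_rate
    wu = config.warmup_epochs
    if epoch < wu:
        frac = epoch / wu
        return base * (config.warmup_factor + (1.0 - config.warmup_factor) * frac)
    span = config.max_epochs - 1 - wu
    t = (epoch - wu) / span if span > 0 else 1.0
    s = config.cosine_scale
    return base * (s + (1.0 - s) * 0.5 * (1.0 + np.cos(np.pi * t)))


class EarlyStopper:
    """Stop after ``patience`` epochs without improvement of >= ``min_delta``.

    ``mode`` is ``"min"`` (loss) or ``"max"`` (accuracy/Dice).
    """

    def __init__(self, patience: int, mode: str = "min", min_delta: float = 1e-5):
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.patience = patience
        self.mode = mode
        self.min_delta = min_delta
        self.best: float | None = None
        self.best_epoch = -1
        self._bad = 0
        self._epoch = -1

    def update(self, value: float) -> bool:
        """Record one epoch's monitored value; returns True to stop."""
        self._epoch += 1
        improved = self.best is None or (
            value < self.best - self.min_delta
            if self.mode == "min"
            else value > self.best + self.min_delta
        )
        if improved:
            self.best = value
            self.best_epoch = self._epoch
            self._bad = 0
        else:
            self._bad += 1
        return self._bad >= self.patience


@dataclass
class SplitPlan:
    """Patient-level assignment to the holdout set or one of k dev folds."""

    holdout: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    seed: int
    stratify_labels: dict[str, int] = field(default_factory=dict)

    def assignment(self) -> dict[str, str | int]:
        out: dict[str, str | int] = {pid: "holdout" for pid in self.holdout}
        for j, fold in enumerate(self.folds):
            for pid in fold:
                out[pid] = j
        return out

    def dev_ids(self) -> tuple[str, ...]:
        return tuple(pid for fold in self.folds for pid in fold)


def make_splits(
    labels: dict[str, int],
    holdout_fraction: float = 0.15,
    k: int = 5,
    seed: int = 42,
) -> SplitPlan:
    """Stratified patient-level split: holdout + k cross-validation folds.

    Per class, patients are shuffled (seeded), a rounded share goes to the
    holdout set, and the rest are dealt round-robin into folds, so fold sizes
    differ by at most one and per-fold class counts are within one patient of
    proportionality.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(labels)
    classes = sorted(set(labels.values()))

    # global holdout count, apportioned to classes by largest remainder
    n_hold_total = int(round(holdout_fraction * len(ids)))
    sizes = {c: sum(1 for pid in ids if labels[pid] == c) for c in classes}
    quota = {c: holdout_fraction * sizes[c] for c in classes}
    n_hold = {c: int(np.floor(quota[c])) for c in classes}
    leftover = n_hold_total - sum(n_hold.values())
    for c in sorted(classes, key=lambda c: quota[c] - np.floor(quota[c]), reverse=True):
        if leftover <= 0:
            break
        n_hold[c] += 1
        leftover -= 1

    holdout: list[str] = []
    per_class_dev: dict[int, list[str]] = {}
    for c in classes:
        members = [pid for pid in ids if labels[pid] == c]
        members = list(np.array(members)[rng.permutation(len(members))])
        holdout += members[: n_hold[c]]
        dev = members[n_hold[c] :]
        if len(dev) < k:
            raise ValueError(
                f"class {c}: only {len(dev)} dev patients for {k} folds"
            )
        per_class_dev[c] = dev

    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for c in classes:
        for i, pid in enumerate(per_class_dev[c]):
            folds[(i + offset) % k].append(pid)
        offset += len(per_class_dev[c])  # continue dealing where the last class stopped

    return SplitPlan(
        holdout=tuple(sorted(holdout)),
        folds=tuple(tuple(sorted(f)) for f in folds),
        seed=seed,
        stratify_labels=dict(labels),
    )


def inverse_frequency_weights(labels: np.ndarray) -> tuple[float, float]:
    """Per-class weights proportional to inverse empirical frequency,
    normalized to mean 1."""
    labels = np.asarray(labels)
    n = labels.size
    n1 = int((labels == 1).sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    w0, w1 = n / (2.0 * n0), n / (2.0 * n1)
    return (float(w0), float(w1))


def augment_batch(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Random 90-degree rotations and flips, applied identically to image,
    label and mask (spatial axes 1, 2)."""
    x, y = x.copy(), y.copy()
    mask = mask.copy() if mask is not None else None
    for i in range(x.shape[0]):
        k = int(rng.integers(4))
        flip = bool(rng.integers(2))
        x[i] = np.rot90(x[i], k, axes=(0, 1))
        y[i] = np.rot90(y[i], k, axes=(0, 1))
        if mask is not None:
            mask[i] = np.rot90(mask[i], k, axes=(0, 1))
        if flip:
            x[i] = x[i][:, ::-1]
            y[i] = y[i][:, ::-1]
            if mask is not None:
                mask[i] = mask[i][:, ::-1]
    return x, y, mask


def train_task(model, records, task: str, config: TrainConfig | None = None, **kwargs):
    """Train ``model`` (an estimator from :mod:`cestmix.models`) on phantom
    records for ``task`` in {"segmentation", "genotype"}; returns the fitted
    model (its ``history_`` holds per-epoch losses/metrics).  Optimization
    fields of ``config`` override the estimator's settings."""
    from . import models as _models

    if config is not None:
        overrides = {
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "weight_decay": config.weight_decay,
            "batch_size": config.batch_size,
            "max_epochs": config.max_epochs,
            "patience": config.patience,
            "augment": config.augment,
            "seed": config.seed,
        }
        model.set_params(**{k: v for k, v in overrides.items()
                            if k in model.get_params()})
    if task == "segmentation":
        X, y = _models.records_to_seg_arrays(records)
        return model.fit(X, y, **kwargs)
    if task == "genotype":
        X, y, m = _models.records_to_patch_arrays(records, **kwargs)
        return model.fit(X, y, pixel_mask=m)
    raise ValueError(f"unknown task {task!r}")
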