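"""Estimator-style models wrapping the numpy network library.

`MixBranchNetSegmenter` and `MixBranchNetGenotypeClassifier` follow the
sklearn estimator protocol (``fit`` / ``predict`` / ``predict_proba``,
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) so they compose with sklearn tooling; the module-level pipeline
functions stay thin wrappers over them.  `SpectralMLPClassifier` is the
spectrum-only fully connected baseline (no spatial context by construction).
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier

from .nn.core import SGD
from .nn.net import MixBranchNet, NetworkConfig, build_network
from .phantom import PatientRecord
from .training import (
    TrainConfig,
    augment_batch,
    combined_loss,
    EarlyStopper,
    inverse_frequency_weights,
    lr_at_epoch,
)


# --------------------------------------------------------------------------- #
# record -> array helpers
# --------------------------------------------------------------------------- #


def records_to_seg_arrays(
    records: Sequence[PatientRecord], input_mode: str = "full"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack whole-image inputs and binary tumor masks.

    ``input_mode`` selects the input ablation: ``"full"`` uses the complete
    multi-offset Z-stack, ``"m0"`` the single reference image, and
    ``"m0_duplicated"`` the reference image replicated to the Z-stack's
    channel count (controls for channel-number effects).
    """
    y = np.stack([r.tumor_mask for r in records]).astype(np.int64)
    if input_mode == "full":
        X = np.stack([r.volume.data for r in records])
    elif input_mode == "m0":
        X = np.stack([r.volume.m0[..., None] for r in records])
    elif input_mode == "m0_duplicated":
        c = records[0].volume.offsets.size
        X = np.stack([np.repeat(r.volume.m0[..., None], c, axis=-1) for r in records])
    else:
        raise ValueError(f"unknown input mode {input_mode!r}")
    return X.astype(np.float32), y


def records_to_patch_arrays(
    records: Sequence[PatientRecord],
    task: str = "idh",
    patch_size: int = 48,
    stride: int = 12,
    use_predicted_masks: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract genotype training patches with pixel-wise labels.

    Every tumor pixel in a patch carries the patient's binary label; pixels
    outside the tumor mask are excluded from the loss via the returned
    pixel mask.
    """
    from .patching import build_grid, extract_patches

    xs, ys, ms = [], [], []
    for rec in records:
        mask = (
            use_predicted_masks[rec.patient_id]
            if use_predicted_masks is not None
            else rec.tumor_mask
        )
        if not mask.any():
            continue
        label = int(getattr(rec, task))
        grid = build_grid(mask, rec.volume.shape, patch_size, stride)
        ps = extract_patches(rec.volume, grid, roi_mask=mask, patient_id=rec.patient_id)
        keep = ps.masks.any(axis=(1, 2))  # drop patches with no ROI pixels
        xs.append(ps.patches[keep])
        ms.append(ps.masks[keep])
        ys.append(np.full(ps.masks[keep].shape, label, dtype=np.int64) * ps.masks[keep])
    if not xs:
        raise ValueError("no non-empty tumor masks in records")
    return (
        np.concatenate(xs).astype(np.float32),
        np.concatenate(ys),
        np.concatenate(ms),
    )


# --------------------------------------------------------------------------- #
# shared training loop
# --------------------------------------------------------------------------- #


def _fit_network(
    net: MixBranchNet,
    X: np.ndarray,
    y: np.ndarray,
    pixel_mask: np.ndarray | None,
    train_config: TrainConfig,
    class_weights: tuple[float, float],
    monitor: str,
    val_frac: float,
) -> tuple[MixBranchNet, list[dict]]:
    """Mini-batch SGD with warmup+cosine schedule and early stopping.

    Monitors ``monitor`` in {"dice", "accuracy"} on a held-back validation
    slice; restores the best-epoch weights before returning.
    """
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    n_val = max(1, int(round(val_frac * n))) if n > 2 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("empty training set")

    opt = SGD(net.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    mode = "max"  # both dice and accuracy improve upward
    stopper = EarlyStopper(cfg.patience, mode=mode)
    history: list[dict] = []
    best_state = net.state_dict()

    def eval_metric(idx: np.ndarray) -> tuple[float, float]:
        losses, metric_num, metric_den = [], 0.0, 0.0
        inter = psum = tsum = 0.0
        for s in range(0, idx.size, cfg.batch_size):
            b = idx[s : s + cfg.batch_size]
            probs = net.forward(X[b], train=False)
            m = pixel_mask[b] if pixel_mask is not None else None
            loss, _ = combined_loss(
                probs, y[b], class_weights, pixel_mask=m,
                alpha=cfg.alpha_bce, beta=cfg.beta_dice,
            )
            losses.append(loss * b.size)
            pred = (probs[..., 1] >= 0.5).astype(np.float64)
            t = y[b].astype(np.float64)
            if monitor == "dice":
                inter += (pred * t).sum()
                psum += pred.sum()
                tsum += t.sum()
            else:
                sel = m > 0 if m is not None else np.ones_like(t, bool)
                metric_num += (pred[sel] == t[sel]).sum()
                metric_den += sel.sum()
        if monitor == "dice":
            metric = (2.0 * inter + 1e-7) / (psum + tsum + 1e-7)
        else:
            metric = metric_num / max(metric_den, 1.0)
        return float(np.sum(losses) / idx.size), float(metric)

    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        for s in range(0, order.size, cfg.batch_size):
            b = order[s : s + cfg.batch_size]
            xb, yb = X[b], y[b]
            mb = pixel_mask[b] if pixel_mask is not None else None
            if cfg.augment:
                xb, yb, mb = augment_batch(xb, yb, rng, mb)
            net.zero_grad()
            probs = net.forward(xb, train=True)
            loss, dprobs = combined_loss(
                probs, yb, class_weights, pixel_mask=mb,
                alpha=cfg.alpha_bce, beta=cfg.beta_dice,
            )
            net.backward(dprobs.astype(np.float32))
            if cfg.clip_norm > 0:
                gn = np.sqrt(sum(float((p_.grad**2).sum()) for p_ in net.parameters()))
                if gn > cfg.clip_norm:
                    scale = cfg.clip_norm / gn
                    for p_ in net.parameters():
                        p_.grad *= scale
            opt.step()
            ep_loss += loss * b.size
        ep_loss /= order.size

        if val_idx.size:
            val_loss, val_metric = eval_metric(val_idx)
        else:
            val_loss, val_metric = eval_metric(tr_idx)
        history.append(
            {"epoch": epoch, "lr": lr, "train_loss": ep_loss,
             "val_loss": val_loss, f"val_{monitor}": val_metric}
        )
        improved_before = stopper.best_epoch
        stop = stopper.update(val_metric)
        if stopper.best_epoch != improved_before or epoch == 0:
            best_state = net.state_dict()
        if stop:
            break

    net.load_state_dict(best_state)
    return net, history


class _NetEstimator(BaseEstimator):
    """Shared config plumbing for the two network estimators."""

    def __init__(self, base_width=32, depths=(2, 2, 4, 2), window=4, heads=None,
                 ffn_ratio=4, conv_branch=True, attn_branch=True,
                 interactions=True, placement="encoder_only",
                 learning_rate=1e-4, momentum=0.9, weight_decay=1e-4,
                 batch_size=8, max_epochs=500, patience=30, augment=True,
                 val_frac=0.2, seed=42):
        self.base_width = base_width
        self.depths = depths
        self.window = window
        self.heads = heads
        self.ffn_ratio = ffn_ratio
        self.conv_branch = conv_branch
        self.attn_branch = attn_branch
        self.interactions = interactions
        self.placement = placement
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.augment = augment
        self.val_frac = val_frac
        self.seed = seed

    def _network_config(self, in_channels: int) -> NetworkConfig:
        return NetworkConfig(
            in_channels=in_channels,
            base_width=self.base_width,
            depths=tuple(self.depths),
            window=self.window,
            heads=self.heads,
            ffn_ratio=self.ffn_ratio,
            conv_branch=self.conv_branch,
            attn_branch=self.attn_branch,
            interactions=self.interactions,
            placement=self.placement,
            seed=self.seed,
        )

    def _train_config(self, class_weights, beta_dice) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            class_weights=class_weights,
            beta_dice=beta_dice,
            augment=self.augment,
            seed=self.seed,
        )

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        # per-offset-channel z-scoring, fitted on the training stack
        return (X - self.input_mean_) / self.input_std_

    def predict_proba_images(self, X: np.ndarray) -> np.ndarray:
        """(n, H, W, C) -> (n, H, W, 2) per-pixel class probabilities."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "net_")
        X = self._standardize(np.asarray(X, dtype=np.float32)).astype(np.float32)
        out = []
        for s in range(0, X.shape[0], max(self.batch_size, 1)):
            out.append(self.net_.forward(X[s : s + self.batch_size], train=False))
        return np.concatenate(out)


class MixBranchNetSegmenter(_NetEstimator):
    """Whole-image tumor segmentation with the dual-branch network.

    ``fit(X, y)`` takes stacked CEST volumes (n, H, W, C) and binary masks
    (n, H, W); ``predict`` returns binary masks (argmax of the 2-class
    softmax, ties broken to background).
    """

    def __init__(self, base_width=32, depths=(2, 2, 4, 2), window=4, heads=None,
                 ffn_ratio=4, conv_branch=True, attn_branch=True,
                 interactions=True, placement="encoder_only",
                 learning_rate=1e-4, momentum=0.9, weight_decay=1e-4,
                 batch_size=8, max_epochs=500, patience=30, augment=True,
                 val_frac=0.2, seed=42,
                 class_weights=(1.0, 9.0)):
        super().__init__(base_width, depths, window, heads, ffn_ratio,
                         conv_branch, attn_branch, interactions, placement,
                         learning_rate, momentum, weight_decay, batch_size,
                         max_epochs, patience, augment, val_frac, seed)
        self.class_weights = class_weights

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MixBranchNetSegmenter":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or y.shape != X.shape[:3]:
            raise ValueError("X must be (n, H, W, C) and y (n, H, W)")
        self.input_mean_ = X.mean(axis=(0, 1, 2))
        self.input_std_ = np.where(X.std(axis=(0, 1, 2)) > 0, X.std(axis=(0, 1, 2)), 1.0)
        X = self._standardize(X).astype(np.float32)
        cfg = self._network_config(X.shape[-1])
        net = build_network(cfg)
        net, history = _fit_network(
            net, X, y, None,
            self._train_config(tuple(self.class_weights), beta_dice=1.0),
            tuple(self.class_weights), monitor="dice", val_frac=self.val_frac,
        )
        self.net_ = net
        self.network_config_ = cfg
        self.history_ = history
        self.n_features_in_ = X.shape[-1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba_images(X)[..., 1] > 0.5).astype(np.int64)


class MixBranchNetGenotypeClassifier(_NetEstimator):
    """Patch-wise genotype prediction (dense per-pixel head, same backbone).

    ``fit(X, y, pixel_mask)`` takes patches (n, s, s, C), pixel-wise binary
    labels (n, s, s) and an ROI mask excluding non-tumor pixels from the
    loss.  Class weights default to inverse class frequency.  Trained with
    cross-entropy only (the Dice term is a segmentation-overlap objective).
    """

    def __init__(self, base_width=32, depths=(2, 2, 4, 2), window=4, heads=None,
                 ffn_ratio=4, conv_branch=True, attn_branch=True,
                 interactions=True, placement="encoder_only",
                 learning_rate=1e-4, momentum=0.9, weight_decay=1e-4,
                 batch_size=128, max_epochs=500, patience=30, augment=True,
                 val_frac=0.2, seed=42):
        super().__init__(base_width, depths, window, heads, ffn_ratio,
                         conv_branch, attn_branch, interactions, placement,
                         learning_rate, momentum, weight_decay, batch_size,
                         max_epochs, patience, augment, val_frac, seed)

    def fit(self, X: np.ndarray, y: np.ndarray,
            pixel_mask: np.ndarray | None = None) -> "MixBranchNetGenotypeClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if pixel_mask is None:
            pixel_mask = np.ones(y.shape, dtype=np.float64)
        pixel_mask = np.asarray(pixel_mask, dtype=np.float64)
        self.input_mean_ = X.mean(axis=(0, 1, 2))
        self.input_std_ = np.where(X.std(axis=(0, 1, 2)) > 0, X.std(axis=(0, 1, 2)), 1.0)
        X = self._standardize(X).astype(np.float32)
        labels = y[pixel_mask > 0]
        cw = inverse_frequency_weights(labels)
        cfg = self._network_config(X.shape[-1])
        net = build_network(cfg)
        net, history = _fit_network(
            net, X, y, pixel_mask,
            self._train_config(cw, beta_dice=0.0),
            cw, monitor="accuracy", val_frac=self.val_frac,
        )
        self.net_ = net
        self.network_config_ = cfg
        self.history_ = history
        self.class_weights_ = cw
        self.n_features_in_ = X.shape[-1]
        return self

    def predict_proba_patches(self, patches: np.ndarray) -> np.ndarray:
        return self.predict_proba_images(patches)


class SpectralMLPClassifier(BaseEstimator, ClassifierMixin):
    """Pixel-wise fully connected classifier over the Z-spectrum offsets.

    Operates on single-pixel spectra only, so it has no spatial context by
    construction: permuting pixels permutes outputs identically.
    """

    def __init__(self, hidden_layer_sizes=(64, 32), max_iter=300, seed=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SpectralMLPClassifier":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (n_pixels, n_offsets)")
        self.n_features_in_ = X.shape[1]
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            max_iter=self.max_iter,
            random_state=self.seed,
        ).fit(X, y)
        self.classes_ = self.mlp_.classes_
        return self

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"expected spectra of length {self.n_features_in_}, got {X.shape[-1]}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.mlp_.predict_proba(self._check(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.mlp_.predict(self._check(X))

    def predict_proba_image(self, image: np.ndarray) -> np.ndarray:
        """(H, W, C) -> (H, W, 2), each pixel classified independently."""
        H, W, C = image.shape
        return self.predict_proba(image.reshape(-1, C)).reshape(H, W, -1)


def spectral_mlp_baseline(zspec: np.ndarray, model: SpectralMLPClassifier) -> np.ndarray:
    """Per-pixel class probabilities from the spectrum-only baseline."""
    zspec = np.asarray(zspec)
    if zspec.ndim == 1:
        return model.predict_proba(zspec[None])[0]
    if zspec.ndim == 3:
        return model.predict_proba_image(zspec)
    return model.predict_proba(zspec)


def clone_with_ablation(estimator: _NetEstimator, **overrides) -> _NetEstimator:
    """Copy an estimator's settings with branch/interaction switches changed."""
    est = copy.deepcopy(estimator)
    est.set_params(**overrides)
    for attr in list(vars(est)):
        if attr.endswith("_") and not attr.endswith("__"):
            delattr(est, attr)
    return est
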