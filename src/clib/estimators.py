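"""Scikit-learn style estimators.

``ContrastiveEncoder`` is the self-supervised pretrainer: ``fit(X)`` runs
the view-building -> encode -> contrastive-loss -> SGD loop for one of the
three variants (``clib``, ``simclr``, ``clib_ablation``) and keeps the
epoch with the lowest mean training loss; ``transform(X)`` returns frozen
backbone features.  ``LinearProbe`` is the supervised read-out: a single
linear layer trained with softmax cross-entropy on frozen features, keeping
the weights with the best validation accuracy.

Both follow sklearn conventions (get_params/set_params, trailing-underscore
fitted attributes) and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .loss import VARIANTS, loss_and_grad
from .model import (EncoderSpec, ProjectionHead, ProjectionSpec,
                    SmallConvEncoder, nchw)
from .views import (AugmentationPolicy, CropGeometry, ImageBatch,
                    build_three_view_batch, build_two_view_batch,
                    resize_bilinear)

__all__ = ["ContrastiveEncoder", "LinearProbe", "cosine_lr"]


def cosine_lr(epoch: float, epochs: int, initial_lr: float, final_lr: float) -> float:
    """Cosine interpolation from initial_lr (epoch 0) to final_lr (last epoch)."""
    if epochs == 1:
        return initial_lr
    phase = epoch / (epochs - 1)
    return final_lr + (initial_lr - final_lr) * 0.5 * (1 + np.cos(np.pi * phase))


def _validate_images(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 4:
        raise ValueError("X must be a (N, H, W, C) image stack")
    if not np.isfinite(X).all() or X.min() < 0 or X.max() > 1:
        raise ValueError("image intensities must be finite and in [0, 1]")
    return X


class ContrastiveEncoder(BaseEstimator, TransformerMixin):
    """Self-supervised contrastive pretraining of a small conv backbone.

    Parameters
    ----------
    variant : {"clib", "simclr", "clib_ablation"}
        Which view construction / loss to train with.  ``clib`` uses the
        three views (original, subject crop, four-corner background mosaic)
        with the background as extra negatives; ``simclr`` is the standard
        two-augmentation baseline; ``clib_ablation`` is SimCLR plus the
        background view as extra negatives only.
    alpha, gamma : float
        Subject and per-corner crop ratios (beta = alpha, delta = gamma).
    temperature : float
        Softmax temperature of the contrastive loss.
    epochs, batch_size, learning_rate, final_lr, momentum
        SGD schedule; the learning rate decays along a cosine from
        ``learning_rate`` to ``final_lr``.  Incomplete trailing batches are
        dropped so the positive/negative accounting is exact.
    widths, proj_dim
        Backbone block widths and projection output dimension.
    augment : AugmentationPolicy or None
        View augmentation; defaults to the SimCLR recipe.

    Attributes
    ----------
    encoder_, projector_ : trained modules at the lowest-loss epoch
    loss_curve_ : per-epoch mean contrastive loss
    lr_trace_ : per-epoch learning rate
    best_epoch_ : epoch index of the restored checkpoint
    """

    def __init__(self, variant: str = "clib", image_size: int = 32,
                 alpha: float = 0.5, gamma: float = 0.25,
                 temperature: float = 0.07, epochs: int = 30,
                 batch_size: int = 32, learning_rate: float = 0.01,
                 final_lr: float = 0.0001, momentum: float = 0.9,
                 widths: tuple[int, ...] = (16, 32, 64), proj_dim: int = 16,
                 augment: AugmentationPolicy | None = None,
                 random_state: int | None = None):
        self.variant = variant
        self.image_size = image_size
        self.alpha = alpha
        self.gamma = gamma
        self.temperature = temperature
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.final_lr = final_lr
        self.momentum = momentum
        self.widths = widths
        self.proj_dim = proj_dim
        self.augment = augment
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _geometry(self) -> CropGeometry:
        return CropGeometry(alpha=self.alpha, beta=self.alpha,
                            gamma=self.gamma, delta=self.gamma,
                            output_size=(self.image_size, self.image_size))

    def _build_batch(self, images: ImageBatch, geometry, policy, rng):
        if self.variant == "clib":
            return build_three_view_batch(images, geometry, policy, seed=rng)
        with_bg = self.variant == "clib_ablation"
        return build_two_view_batch(images, policy, seed=rng,
                                    with_background=with_bg, geometry=geometry)

    def fit(self, X, y=None):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.learning_rate >= self.final_lr > 0:
            raise ValueError("require initial_lr >= final_lr > 0")
        X = _validate_images(X)
        if len(X) == 0:
            raise ValueError("empty dataset")
        n_channels = X.shape[3]
        # separate init and data streams so the view stream can be replayed
        # deterministically without re-consuming the weight-init draws
        ss_init, self._data_entropy_ = np.random.SeedSequence(
            self.random_state).spawn(2)
        rng = np.random.default_rng(self._data_entropy_)
        geometry = self._geometry()
        policy = self.augment if self.augment is not None else AugmentationPolicy()

        spec = EncoderSpec(input_size=self.image_size, in_channels=n_channels,
                           widths=tuple(self.widths))
        init_rng = np.random.default_rng(ss_init)
        encoder = SmallConvEncoder(spec, rng=init_rng)
        projector = ProjectionHead(spec.feature_dim,
                                   ProjectionSpec(spec.feature_dim, self.proj_dim),
                                   rng=init_rng)
        opt = _nn.SGD([encoder.net, projector.net], momentum=self.momentum)

        layout = {"clib": "three_view", "simclr": "two_view",
                  "clib_ablation": "two_view_bg"}[self.variant]
        n = len(X)
        batch = min(self.batch_size, n)
        self.train_loss_curve_ = []
        self.loss_curve_ = []
        self.lr_trace_ = []
        best = (np.inf, None, None, -1)
        for epoch in range(self.epochs):
            lr = cosine_lr(epoch, self.epochs, self.learning_rate, self.final_lr)
            perm = rng.permutation(n)
            losses = []
            epoch_views = []
            for start in range(0, n - batch + 1, batch):
                idx = perm[start : start + batch]
                images = ImageBatch(pixels=X[idx], ids=list(idx))
                vb = self._build_batch(images, geometry, policy, rng)
                epoch_views.append(vb)
                feats = encoder.forward(nchw(vb.samples), train=True)
                z = projector.forward(feats, train=True)
                total, _, dz = loss_and_grad(z, layout, vb.n_sources,
                                             self.temperature)
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"non-finite contrastive loss at epoch {epoch}")
                encoder.backward(projector.backward(dz))
                opt.step(lr)
                losses.append(total)
            # end-of-epoch selection pass: score this epoch's views with the
            # now-fixed weights, so the preserved minimum is reproducible
            # from the checkpoint alone
            sel = self._score_views(encoder, projector, epoch_views, layout)
            self.train_loss_curve_.append(float(np.mean(losses)))
            self.loss_curve_.append(sel)
            self.lr_trace_.append(lr)
            if sel < best[0]:
                best = (sel, encoder.state_dict(), projector.state_dict(),
                        epoch)
        encoder.load_state_dict(best[1])
        projector.load_state_dict(best[2])
        self.encoder_, self.projector_ = encoder, projector
        self.best_epoch_ = best[3]
        self.best_loss_ = best[0]
        self.train_loss_curve_ = np.array(self.train_loss_curve_)
        self.loss_curve_ = np.array(self.loss_curve_)
        self.lr_trace_ = np.array(self.lr_trace_)
        self.n_features_out_ = spec.feature_dim
        return self

    def _score_views(self, encoder, projector, view_batches, layout) -> float:
        losses = []
        for vb in view_batches:
            feats = encoder.forward(nchw(vb.samples), train=False)
            z = projector.forward(feats, train=False)
            total, _, _ = loss_and_grad(z, layout, vb.n_sources,
                                        self.temperature)
            losses.append(total)
        return float(np.mean(losses))

    def selection_loss(self, X, epoch: int) -> float:
        """Replay the deterministic view stream up to ``epoch`` and score the
        fitted model on that epoch's views in evaluation mode.

        Because view construction consumes the seeded rng independently of
        the weights, ``selection_loss(X, best_epoch_)`` on the restored
        best checkpoint reproduces ``best_loss_`` exactly.
        """
        check_is_fitted(self, "encoder_")
        X = _validate_images(X)
        rng = np.random.default_rng(self._data_entropy_)
        geometry = self._geometry()
        policy = self.augment if self.augment is not None else AugmentationPolicy()
        layout = {"clib": "three_view", "simclr": "two_view",
                  "clib_ablation": "two_view_bg"}[self.variant]
        n = len(X)
        batch = min(self.batch_size, n)
        # mirror the fit loop's rng consumption exactly: one permutation per
        # epoch, then the view draws batch by batch
        for e in range(epoch + 1):
            perm = rng.permutation(n)
            views = []
            for start in range(0, n - batch + 1, batch):
                idx = perm[start : start + batch]
                images = ImageBatch(pixels=X[idx], ids=list(idx))
                views.append(self._build_batch(images, geometry, policy, rng))
            if e == epoch:
                return self._score_views(self.encoder_, self.projector_,
                                         views, layout)
        raise ValueError("epoch out of range")

    def transform(self, X) -> np.ndarray:
        """Frozen backbone features of center-resized full images."""
        check_is_fitted(self, "encoder_")
        X = _validate_images(X)
        if X.shape[1] != self.image_size or X.shape[2] != self.image_size:
            X = np.stack([resize_bilinear(img, self.image_size, self.image_size)
                          for img in X])
        feats = []
        for start in range(0, len(X), 256):
            feats.append(self.encoder_.forward(nchw(X[start : start + 256]),
                                               train=False))
        return np.concatenate(feats)


class LinearProbe(BaseEstimator, ClassifierMixin):
    """Linear softmax classifier on frozen features, SGD-trained.

    Keeps the epoch with the highest validation accuracy (earliest epoch on
    ties); validation data comes either from ``fit(..., X_val=, y_val=)`` or
    from an internal stratified ``validation_fraction`` split, else training
    accuracy is used for selection.
    """

    def __init__(self, epochs: int = 20, learning_rate: float = 0.01,
                 final_lr: float = 0.0001, momentum: float = 0.9,
                 batch_size: int = 32, validation_fraction: float = 0.0,
                 random_state: int | None = None):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.final_lr = final_lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)
        if X_val is None and self.validation_fraction > 0:
            X, X_val, y, y_val = train_test_split(
                X, y, test_size=self.validation_fraction, stratify=y,
                random_state=int(rng.integers(2**31)))
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        d = X.shape[1]
        w = np.zeros((d, k))
        b = np.zeros(k)
        vw, vb = np.zeros_like(w), np.zeros_like(b)
        n = len(X)
        batch = min(self.batch_size, n)
        if X_val is not None:
            y_val = np.asarray(y_val)
            pos = np.searchsorted(self.classes_, y_val).clip(0, k - 1)
            # classes unseen in training can never be predicted correctly
            y_val_enc = np.where(self.classes_[pos] == y_val, pos, -1)
        best = (-np.inf, None, None, -1)
        self.val_accuracy_curve_ = []
        for epoch in range(self.epochs):
            lr = cosine_lr(epoch, self.epochs, self.learning_rate, self.final_lr)
            perm = rng.permutation(n)
            for start in range(0, n, batch):
                idx = perm[start : start + batch]
                logits = X[idx] @ w + b
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                p[np.arange(len(idx)), y_enc[idx]] -= 1.0
                p /= len(idx)
                gw, gb = X[idx].T @ p, p.sum(axis=0)
                vw = self.momentum * vw - lr * gw
                vb = self.momentum * vb - lr * gb
                w += vw
                b += vb
            if X_val is not None:
                pred = np.argmax(X_val @ w + b, axis=1)
                acc = float(np.mean(pred == y_val_enc))
            else:
                pred = np.argmax(X @ w + b, axis=1)
                acc = float(np.mean(pred == y_enc))
            self.val_accuracy_curve_.append(acc)
            if acc > best[0]:
                best = (acc, w.copy(), b.copy(), epoch)
        self.best_val_accuracy_, self.coef_, self.intercept_, self.best_epoch_ = best
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        logits = self.decision_function(X)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
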