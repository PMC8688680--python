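"""Scikit-learn-style estimators wrapping the segmentation networks.

``ResUNetSegmenter`` (residual encoder, the proposed model) and
``UNetSegmenter`` (plain Convblock encoder, the ablation baseline) are
``BaseEstimator`` subclasses: hyperparameters are constructor arguments,
``fit(X, y)`` trains on a stack of images, fitted state lives in
trailing-underscore attributes, and ``predict`` / ``predict_proba``
return label maps / per-pixel class probabilities. They compose with
sklearn model selection as long as a pixel-level scorer is supplied.

X is (n_images, H, W) float in [0, 1]; y is (n_images, H, W) integer
labels in {0, 1, 2}.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .network import NetworkSpec, SegNet, segment_image
from .training import TrainConfig, train


class _SegmenterBase(BaseEstimator):
    _residual_encoder: bool

    def __init__(self, base_channels: int = 32, epochs: int = 500, batch_size: int = 16,
                 lr0: float = 0.001, lr_decay: float = 0.98, decay_every: int = 5,
                 augment: bool = True, random_state: int = 0):
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.augment = augment
        self.random_state = random_state

    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_images, H, W), got shape {X.shape}")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        if y is not None:
            y = np.asarray(y)
            if y.shape != X.shape:
                raise ValueError(f"y shape {y.shape} != X shape {X.shape}")
            if not np.isin(y, [0, 1, 2]).all():
                raise ValueError("labels must be in {0, 1, 2}")
            y = y.astype(np.uint8)
        return X, y

    def fit(self, X, y, X_val=None, y_val=None):
        """Train the network; optional validation stack drives checkpoint selection."""
        X, y = self._validate_xy(X, y)
        if X_val is not None:
            X_val, y_val = self._validate_xy(X_val, y_val)
        spec = NetworkSpec(base_channels=self.base_channels)
        model = SegNet(spec, residual_encoder=self._residual_encoder, seed=self.random_state)
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size, lr0=self.lr0,
                          lr_decay=self.lr_decay, decay_every=self.decay_every,
                          seed=self.random_state, augment=self.augment)
        self.model_, self.history_ = train(model, X, y, X_val, y_val, cfg)
        self.classes_ = np.array([0, 1, 2])
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X):
        """Per-pixel class labels, shape (n_images, H, W), values {0, 1, 2}."""
        check_is_fitted(self, "model_")
        X, _ = self._validate_xy(X)
        return np.stack([segment_image(self.model_, img) for img in X])

    def predict_proba(self, X):
        """Per-pixel class probabilities, shape (n_images, 3, H, W)."""
        check_is_fitted(self, "model_")
        X, _ = self._validate_xy(X)
        return np.stack([segment_image(self.model_, img, return_probs=True)[1] for img in X])

    def score(self, X, y):
        """Mean over images of the average ulna/radius Dice."""
        from .metrics import dice_class

        preds = self.predict(X)
        _, y = self._validate_xy(X, y)
        return float(np.mean([0.5 * (dice_class(p, t, 1) + dice_class(p, t, 2))
                              for p, t in zip(preds, y)]))


class ResUNetSegmenter(_SegmenterBase):
    """The proposed model: five-Resblock encoder U-Net with GDL training."""

    _residual_encoder = True


class UNetSegmenter(_SegmenterBase):
    """Ablation baseline: plain Convblock encoder, otherwise identical."""

    _residual_encoder = False
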