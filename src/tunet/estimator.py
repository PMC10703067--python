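"""Scikit-learn style estimator facade for the segmentation network.

``TUNetSegmenter`` wraps model construction, the SGD training loop and
inference behind the familiar ``fit`` / ``predict`` / ``score`` surface, so
it composes with sklearn pipelines, cloning and parameter search.  Inputs
are arrays of grayscale images ``X`` with shape (n, H, W) (values in [0,1],
H and W divisible by 16) and binary masks ``y`` of the same shape.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .losses import LossConfig
from .metrics import binarize, evaluate_pair, records_to_frame
from .network import ModelConfig
from .synthetic import Sample
from .experiment import TrainConfig, evaluate_model, train, predict_proba

__all__ = ["TUNetSegmenter"]


class TUNetSegmenter(BaseEstimator):
    """Hybrid transformer/U-Net binary segmenter.

    Parameters mirror the architecture and optimization configuration; see
    :class:`~tunet.network.ModelConfig` and
    :class:`~tunet.experiment.TrainConfig` for semantics.  ``score`` returns
    the mean per-image Dice coefficient of the binarized predictions.

    Examples
    --------
    >>> seg = TUNetSegmenter(base_channels=(8, 16, 32, 64, 128), embed_dim=64,
    ...                      num_layers=2, num_heads=4, mlp_dim=128,
    ...                      pool_fields=(1, 2, 2, 4), image_size=64,
    ...                      epochs=5, random_state=0)
    """

    def __init__(self, base_channels=(64, 128, 256, 512, 1024), patch_size=16,
                 embed_dim=768, num_layers=12, num_heads=12, mlp_dim=3072,
                 atrous_rates=(1, 3, 5, 7), pool_fields=(2, 4, 8, 16),
                 ablation="full", atrous_mode="cascade", fusion="concat",
                 image_size=320, loss_components=("dice", "topk"),
                 k_percent=10.0, focal_gamma=2.0, lr=0.01, momentum=0.9,
                 weight_decay=1e-4, batch_size=10, epochs=1,
                 lr_step_epochs=100, lr_decay_factor=0.1, max_iters=None,
                 threshold=0.5, random_state=0):
        self.base_channels = base_channels
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.num_layers = num_layers
        self.num_heads = num_heads
        self.mlp_dim = mlp_dim
        self.atrous_rates = atrous_rates
        self.pool_fields = pool_fields
        self.ablation = ablation
        self.atrous_mode = atrous_mode
        self.fusion = fusion
        self.image_size = image_size
        self.loss_components = loss_components
        self.k_percent = k_percent
        self.focal_gamma = focal_gamma
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_step_epochs = lr_step_epochs
        self.lr_decay_factor = lr_decay_factor
        self.max_iters = max_iters
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------ config
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            base_channels=tuple(self.base_channels), patch_size=self.patch_size,
            embed_dim=self.embed_dim, num_layers=self.num_layers,
            num_heads=self.num_heads, mlp_dim=self.mlp_dim,
            atrous_rates=tuple(self.atrous_rates),
            pool_fields=tuple(self.pool_fields), ablation=self.ablation,
            atrous_mode=self.atrous_mode, fusion=self.fusion,
            image_size=self.image_size)

    def _train_config(self) -> TrainConfig:
        loss = LossConfig(components=tuple(self.loss_components),
                          k_percent=self.k_percent,
                          focal_gamma=self.focal_gamma)
        return TrainConfig(
            lr=self.lr, momentum=self.momentum, weight_decay=self.weight_decay,
            batch_size=self.batch_size, epochs=self.epochs,
            lr_step_epochs=self.lr_step_epochs,
            lr_decay_factor=self.lr_decay_factor, max_iters=self.max_iters,
            seed=self.random_state, loss=loss, model=self._model_config())

    @staticmethod
    def _to_samples(X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"X must have shape (n, H, W), got {X.shape}")
        if y is None:
            y = np.zeros_like(X, dtype=np.uint8)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} does not match X {X.shape}")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary {0,1}")
        return [Sample(image=xi, mask=yi.astype(np.uint8), id=f"img_{i:05d}")
                for i, (xi, yi) in enumerate(zip(X, y))]

    # --------------------------------------------------------------------- API
    def fit(self, X, y):
        """Train the network on images ``X`` and masks ``y``."""
        samples = self._to_samples(X, y)
        cfg = self._train_config()
        result = train(samples, None, cfg)
        self.model_ = result.model
        self.history_ = result.history
        self.config_ = cfg
        self.n_parameters_ = result.model.num_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        check_is_fitted(self, "model_")
        samples = self._to_samples(X)
        return predict_proba(self.model_, samples, batch_size=self.batch_size)

    def predict(self, X) -> np.ndarray:
        """Binary masks thresholded at ``threshold``."""
        return binarize(self.predict_proba(X), self.threshold)

    def score(self, X, y) -> float:
        """Mean per-image Dice coefficient on (X, y)."""
        probs = self.predict_proba(X)
        samples = self._to_samples(X, y)
        records = [evaluate_pair(p, s.mask, threshold=self.threshold,
                                 image_id=s.id)
                   for p, s in zip(probs, samples)]
        return float(records_to_frame(records)["dice"].mean())

    def evaluate(self, X, y, spacing: float = 1.0):
        """Per-image metric table and mean ± std summary (incl. HD/ASD in mm)."""
        check_is_fitted(self, "model_")
        samples = self._to_samples(X, y)
        for s in samples:
            s.spacing = spacing
        return evaluate_model(self.model_, samples, threshold=self.threshold)
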