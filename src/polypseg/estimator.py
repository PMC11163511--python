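"""Scikit-learn style estimator facade over the segmentation pipeline.

``PolypSegmenter`` is a fit/predict wrapper: ``X`` is an array of RGB
images ``(n, H, W, 3)`` (uint8 or floats in [0, 255]) with H and W
divisible by 16, ``y`` the aligned binary masks ``(n, H, W)``.  It
composes with sklearn model selection (get_params/set_params clone
correctly) and scores with mean Dice.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import MODEL_PRESETS
from .data.pairs import ImageMaskPair
from .losses import LossWeights
from .metrics import evaluate_dataset
from .model import ModelConfig
from .training import TrainConfig, model_from_checkpoint, train


class PolypSegmenter(BaseEstimator):
    """Binary polyp segmentation with a nested-UNet + transformer network.

    Parameters mirror the training recipe: momentum SGD (momentum 0.9,
    weight decay 1e-4), polynomial LR decay from ``base_lr`` and the
    0.5/0.5 BCE + Dice loss.  ``preset`` selects the architecture
    ("tiny" for CPU-scale work, "full" for the reference layout); the
    ablation switches drop the transformer bridge or the MSFF fusion
    stages entirely.
    """

    def __init__(self, preset: str = "tiny", epochs: int = 50,
                 batch_size: int = 8, base_lr: float = 5e-3,
                 momentum: float = 0.9, weight_decay: float = 1e-4,
                 poly_power: float = 0.9, lambda_bce: float = 0.5,
                 lambda_dice: float = 0.5, enable_transformer: bool = True,
                 enable_msff: bool = True, alpha: float = 1.0,
                 val_fraction: float = 0.0, max_iterations: int | None = None,
                 seed: int = 0):
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.poly_power = poly_power
        self.lambda_bce = lambda_bce
        self.lambda_dice = lambda_dice
        self.enable_transformer = enable_transformer
        self.enable_msff = enable_msff
        self.alpha = alpha
        self.val_fraction = val_fraction
        self.max_iterations = max_iterations
        self.seed = seed

    # -- internals -----------------------------------------------------------
    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3) RGB images, got {X.shape}")
        if X.shape[1] % 16 or X.shape[2] % 16:
            raise ValueError(
                f"image size {X.shape[1]}x{X.shape[2]} must be divisible by 16")
        return X

    def _pairs(self, X: np.ndarray, y: np.ndarray) -> list[ImageMaskPair]:
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ValueError(f"y shape {y.shape} must be {X.shape[:3]}")
        return [ImageMaskPair(image=X[i].astype(np.uint8),
                              mask=(y[i] > 0.5).astype(np.uint8),
                              id=f"sample_{i:05d}")
                for i in range(len(X))]

    def _model_config(self, input_size: tuple[int, int]) -> ModelConfig:
        if self.preset not in MODEL_PRESETS:
            raise ValueError(f"unknown preset '{self.preset}'")
        cfg = MODEL_PRESETS[self.preset](ref_input_size=input_size)
        import dataclasses
        return dataclasses.replace(
            cfg, enable_transformer=self.enable_transformer,
            enable_msff=self.enable_msff, alpha=self.alpha)

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        X = self._validate_images(X)
        pairs = self._pairs(X, y)
        model_cfg = self._model_config(X.shape[1:3])
        train_cfg = TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            base_lr=self.base_lr, momentum=self.momentum,
            weight_decay=self.weight_decay, poly_power=self.poly_power,
            seed=self.seed, val_fraction=self.val_fraction,
            max_iterations=self.max_iterations,
            loss_weights=LossWeights(self.lambda_bce, self.lambda_dice))
        ckpt, state = train(model_cfg, train_cfg, pairs)
        self.model_ = model_from_checkpoint(ckpt)
        self.model_config_ = model_cfg
        self.checkpoint_ = ckpt
        self.state_ = state
        self.history_ = state.history
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_images(X)
        from .training import predict_probabilities
        maps = predict_probabilities(self.model_, list(X.astype(np.uint8)))
        return np.stack(maps)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice at threshold 0.5."""
        proba = self.predict_proba(X)
        report = evaluate_dataset(list(proba), [m.astype(np.uint8) for m in np.asarray(y)])
        return report.mdice

    def evaluate(self, X, y):
        """Full metrics report (mDice, mIoU, precision, recall)."""
        proba = self.predict_proba(X)
        return evaluate_dataset(list(proba),
                                [m.astype(np.uint8) for m in np.asarray(y)])

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("PolypSegmenter is not fitted; call fit first")
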