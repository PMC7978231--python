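"""scikit-learn style estimators wrapping the alternating-phase trainer.

``JigsawSSLClassifier`` follows the sklearn semi-supervised convention:
``y == -1`` marks unlabelled samples, which only feed the jigsaw pretext
stream.  ``SupervisedImageClassifier`` is the purely supervised baseline
(no jigsaw head).  ``X`` is an array of uint8 RGB images with shape
(n_samples, 222, 222, 3); ``groups`` (video identifiers) control the
group-level validation split used for checkpoint selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import INPUT_SIDE, DualHeadModel
from .objectives import ood_scores_batch
from .trainer import TrainConfig, fit_core, predict_proba

__all__ = ["JigsawSSLClassifier", "SupervisedImageClassifier"]


def _check_images(X):
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[3] != 3:
        raise ValueError(
            f"X must have shape (n_samples, {INPUT_SIDE}, {INPUT_SIDE}, 3), got {X.shape}"
        )
    return X


class _ImageClassifierBase(BaseEstimator, ClassifierMixin):
    _mode = "ssl"

    def __init__(self, backbone="tiny-conv", P=30, s=0.6, lambda0=1.5,
                 lambda_growth=False, epochs=10, batch_size=32,
                 learning_rate=1e-4, weight_decay=0.005, grid_size=3,
                 augment=True, jitter=True, validation_fraction=0.2,
                 random_state=0):
        self.backbone = backbone
        self.P = P
        self.s = s
        self.lambda0 = lambda0
        self.lambda_growth = lambda_growth
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.grid_size = grid_size
        self.augment = augment
        self.jitter = jitter
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _config(self):
        return TrainConfig(
            lr=self.learning_rate, weight_decay=self.weight_decay,
            lambda0=self.lambda0, lambda_growth=self.lambda_growth,
            P=self.P, s=self.s, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.random_state, mode=self._mode,
            backbone=self.backbone, grid_size=self.grid_size,
            augment=self.augment, jitter=self.jitter,
        )

    def _split_validation(self, labeled_idx, y, groups):
        """Group-level validation split over the labelled samples."""
        if self.validation_fraction <= 0:
            return labeled_idx, np.array([], dtype=int)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 977]))
        if groups is None:
            groups = np.arange(len(y))  # each sample its own group
        val_groups = []
        for cls in np.unique(y[labeled_idx]):
            gs = np.unique(np.asarray(groups)[labeled_idx][y[labeled_idx] == cls])
            gs = gs[rng.permutation(len(gs))]
            n_val = max(1, int(round(self.validation_fraction * len(gs)))) \
                if len(gs) > 1 else 0
            val_groups += list(gs[:n_val])
        in_val = np.isin(np.asarray(groups), val_groups)
        tr = np.array([i for i in labeled_idx if not in_val[i]], dtype=int)
        va = np.array([i for i in labeled_idx if in_val[i]], dtype=int)
        if len(tr) == 0 or len(np.unique(y[tr])) < 2:
            return labeled_idx, np.array([], dtype=int)
        return tr, va

    def fit(self, X, y, groups=None):
        X = _check_images(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        labeled_idx = np.flatnonzero(y != -1)
        if len(labeled_idx) == 0:
            raise ValueError("need at least one labelled sample")
        self.classes_ = np.unique(y[labeled_idx])
        if not np.array_equal(self.classes_, np.array([0, 1])):
            raise ValueError("labels must be binary {0, 1} (-1 for unlabelled)")

        tr_idx, val_idx = self._split_validation(labeled_idx, y, groups)
        sup_images = [X[i] for i in tr_idx]
        sup_labels = y[tr_idx]
        not_val = np.setdiff1d(np.arange(len(X)), val_idx)
        pool_images = [X[i] for i in not_val]
        val_images = [X[i] for i in val_idx] if len(val_idx) else None
        val_labels = y[val_idx] if len(val_idx) else None

        cfg = self._config()
        model = DualHeadModel(backbone=cfg.backbone, P=cfg.P, seed=cfg.seed,
                              include_jigsaw=(self._mode != "baseline"))
        res = fit_core(model, sup_images, sup_labels, pool_images, cfg,
                       val_images=val_images, val_labels=val_labels)
        self.model_ = res.model
        self.history_ = res.history
        self.class_weights_ = res.class_weights
        self.jigsaw_weights_ = res.jigsaw_weights
        self.permutations_ = res.perms
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = _check_images(X)
        return predict_proba(self.model_, list(X), head="supervised")

    def predict(self, X):
        p = self.predict_proba(X)
        return (p[:, 1] > p[:, 0]).astype(int)  # ties -> negative class


class JigsawSSLClassifier(_ImageClassifierBase):
    """Semi-supervised lesion classifier with a jigsaw pretext head."""

    _mode = "ssl"

    def ood_score(self, X, mode: str = "ssl"):
        """Per-sample kappa OOD scores (higher = more out-of-distribution)."""
        check_is_fitted(self, "model_")
        X = _check_images(X)
        cp = predict_proba(self.model_, list(X), head="supervised")
        jp = predict_proba(self.model_, list(X), head="jigsaw") \
            if mode == "ssl" else None
        kappa, _, _ = ood_scores_batch(cp, jp, self.jigsaw_weights_, mode)
        return kappa


class SupervisedImageClassifier(_ImageClassifierBase):
    """Purely supervised baseline: weighted cross-entropy only, no jigsaw head."""

    _mode = "baseline"

    def ood_score(self, X):
        check_is_fitted(self, "model_")
        X = _check_images(X)
        cp = predict_proba(self.model_, list(X), head="supervised")
        kappa, _, _ = ood_scores_batch(cp, None, None, "baseline")
        return kappa
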