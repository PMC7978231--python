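"""Alternating-phase semi-supervised training.

Each iteration runs a supervised step on a mini-batch of the selected
labelled subset D_K (weighted cross-entropy, updating the encoder and the
supervised head) followed — in SSL mode — by an unsupervised step on a
mini-batch drawn from the whole training pool (labelled + unlabelled,
validation excluded), passed through the jigsaw shuffler and scored by the
weighted jigsaw loss scaled by lambda (updating the encoder and the jigsaw
head).  Supervised batches are never scrambled, matching how images are
presented at test time.  The lambda schedule optionally multiplies lambda by
1.5 every 5 epochs to accelerate the unsupervised task in the low-data
regime.

Labelled-fraction selection is done at the video level: 20% of labelled
training videos are first held out for validation (fixed per fold and
identical for every k), then D_K takes the first k% of the remaining videos
in a seeded per-class order, so smaller fractions are nested inside larger
ones.

In domain-adaptation mode, supervised batches come only from labelled
source-domain (WLI) videos while unsupervised batches mix labelled source
and unlabelled target-domain (NBI) frames; held-out labelled target frames
are reserved for testing.  A routing counter records how many target-domain
frames ever enter a supervised batch (it must stay zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from ._nn import AdamW, softmax
from .manifest import label_codes
from .model import INPUT_SIDE, DualHeadModel
from .objectives import (ClassWeights, JigsawWeights, compute_class_weights,
                         jigsaw_loss, supervised_loss)
from .permutations import generate_permutation_set
from .shuffler import JigsawConfig, make_unsupervised_batch

logger = logging.getLogger("jigsawssl")

__all__ = ["TrainConfig", "FractionSelection", "select_labeled_fraction",
           "augment", "augment_geometric", "normalize_batch", "train",
           "train_domain_adaptation", "lambda_at_epoch", "TrainResult"]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

class DegenerateSelectionError(ValueError):
    """A class ended up with no videos in the labelled selection."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    k_fraction: float = 100.0
    fold: int = 1
    lr: float = 1e-4
    weight_decay: float = 0.005
    lambda0: float = 1.5
    lambda_growth: bool = False
    P: int = 30
    s: float = 0.6
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    mode: str = "ssl"  # ssl | baseline | domain_adaptation
    backbone: str = "tiny-conv"
    grid_size: int = 3
    augment: bool = True
    jitter: bool = True
    unsupervised_step: bool = True  # set False to skip the jigsaw phase entirely
    source_domain: str = "WLI"
    target_domain: str = "NBI"
    n_folds: int = 5

    def __post_init__(self):
        if self.mode not in ("ssl", "baseline", "domain_adaptation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 1 <= self.fold <= self.n_folds:
            raise ValueError(f"fold must be in 1..{self.n_folds}")
        if self.lambda0 < 0 or self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer/lambda settings")


def lambda_at_epoch(lambda0: float, epoch: int, growth: bool) -> float:
    """lambda0 * 1.5**floor(epoch / 5) when growth is on, else lambda0."""
    return lambda0 * (1.5 ** (epoch // 5)) if growth else lambda0


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def _resize_uint8(img: np.ndarray, side: int) -> np.ndarray:
    if img.shape[0] == side and img.shape[1] == side:
        return img
    return np.asarray(Image.fromarray(img).resize((side, side), Image.BILINEAR))


def augment_geometric(image: np.ndarray, rng: np.random.Generator,
                      side: int = INPUT_SIDE) -> np.ndarray:
    """Whole-image geometric augmentation, each transform applied with p=0.5:
    vertical flip, horizontal flip, rotation from {0, 90, 180, 270} degrees,
    and a random crop of relative size in [0.8, 1.0]; finally resized to
    ``side``.  No colour transforms — lesion colour is a class cue."""
    img = np.asarray(image)
    if rng.random() < 0.5:
        img = img[::-1]
    if rng.random() < 0.5:
        img = img[:, ::-1]
    if rng.random() < 0.5:
        img = np.rot90(img, k=int(rng.integers(0, 4)))
    if rng.random() < 0.5:
        scale = rng.uniform(0.8, 1.0)
        h, w = img.shape[:2]
        ch, cw = max(1, int(scale * h)), max(1, int(scale * w))
        r = int(rng.integers(0, h - ch + 1))
        c = int(rng.integers(0, w - cw + 1))
        img = img[r : r + ch, c : c + cw]
    img = np.ascontiguousarray(img)
    if img.dtype == np.uint8:
        return _resize_uint8(img, side)
    # float image in [0, 1]
    if img.shape[0] != side or img.shape[1] != side:
        img = _resize_uint8((np.clip(img, 0, 1) * 255).astype(np.uint8), side) / 255.0
    return img


_NORM_SCALE = (1.0 / (255.0 * IMAGENET_STD)).astype(np.float32)
_NORM_BIAS = (-IMAGENET_MEAN / IMAGENET_STD).astype(np.float32)


def normalize_batch(batch) -> np.ndarray:
    """uint8/float HWC images -> normalized float (B, 3, H, W)."""
    arr = np.stack([np.asarray(b) for b in batch])
    if arr.dtype == np.uint8:
        out = arr.astype(np.float32)
        out *= _NORM_SCALE
        out += _NORM_BIAS
    else:
        out = (arr.astype(np.float32) - IMAGENET_MEAN.astype(np.float32)) \
            / IMAGENET_STD.astype(np.float32)
    return out.transpose(0, 3, 1, 2)


def augment(image, rng: np.random.Generator, side: int = INPUT_SIDE,
            geometric: bool = True) -> np.ndarray:
    """Full input transform: geometric augmentation (optional), then channel
    normalization with the standard (0.485, 0.456, 0.406)/(0.229, 0.224,
    0.225) statistics at size ``side``; returns a (3, side, side) array."""
    img = augment_geometric(image, rng, side) if geometric else np.asarray(image)
    if not geometric and (img.shape[0] != side or img.shape[1] != side):
        if img.dtype != np.uint8:
            img = (np.clip(img, 0, 1) * 255).astype(np.uint8)
        img = _resize_uint8(img, side)
    return normalize_batch([img])[0]


# --------------------------------------------------------------------------
# labelled-fraction selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FractionSelection:
    """Video-level data routing for one (k, fold) configuration."""

    dk: pd.DataFrame          # labelled supervised subset D_K
    val: pd.DataFrame         # held-out labelled validation frames
    pool: pd.DataFrame        # unsupervised pool (train frames minus validation)
    dk_videos: tuple
    val_videos: tuple


def _video_folds(videos: list, n_folds: int, rng: np.random.Generator):
    videos = sorted(videos)
    order = list(np.array(videos)[rng.permutation(len(videos))])
    return [order[i::n_folds] for i in range(n_folds)], order


def select_labeled_fraction(manifest: pd.DataFrame, k_fraction: float, fold: int,
                            seed: int, n_folds: int = 5,
                            domain: str | None = None) -> FractionSelection:
    """Select D_K and the validation set at video level.

    The validation videos (one fold of a seeded 5-way partition, per class)
    are identical for every k; D_K takes the first ceil(k% * n) remaining
    videos per class in the seeded order, so selections are nested across k
    for a fixed (fold, seed).  ``domain`` restricts the labelled selection to
    one imaging domain (used by domain adaptation).
    """
    if not 0 < k_fraction <= 100:
        raise ValueError(f"k_fraction must be in (0, 100], got {k_fraction}")
    train = manifest[manifest["split"] == "train"]
    labeled = train[train["label"].isin(["0", "1"])]
    if domain is not None:
        labeled = labeled[labeled["domain"] == domain]

    val_videos, dk_videos = [], []
    rng_global = np.random.default_rng(np.random.SeedSequence([int(seed), 977]))
    for cls in ("0", "1"):
        vids = labeled[labeled["label"] == cls]["video_id"].unique().tolist()
        if len(vids) < n_folds:
            raise DegenerateSelectionError(
                f"need >= {n_folds} labelled training videos of class {cls}, "
                f"found {len(vids)}"
            )
        folds, order = _video_folds(vids, n_folds, rng_global)
        val_c = folds[fold - 1]
        remaining = [v for v in order if v not in val_c]
        n_take = math.ceil(k_fraction / 100.0 * len(remaining))
        if n_take == 0:
            raise DegenerateSelectionError(f"class {cls} empty at k={k_fraction}")
        val_videos += val_c
        dk_videos += remaining[:n_take]

    dk = labeled[labeled["video_id"].isin(dk_videos)]
    val = labeled[labeled["video_id"].isin(val_videos)]
    pool = train[~train["video_id"].isin(val_videos)]
    return FractionSelection(dk=dk, val=val, pool=pool,
                             dk_videos=tuple(sorted(dk_videos)),
                             val_videos=tuple(sorted(val_videos)))


# --------------------------------------------------------------------------
# core loop
# --------------------------------------------------------------------------

class _Cycler:
    """Cycles over indices with reshuffling whenever the pass is exhausted."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n, self.rng = n, rng
        self.order = rng.permutation(n)
        self.pos = 0

    def take(self, size: int) -> np.ndarray:
        out = []
        while len(out) < size:
            if self.pos >= self.n:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
            out.append(self.order[self.pos])
            self.pos += 1
        return np.asarray(out)


@dataclass
class TrainResult:
    model: DualHeadModel
    history: pd.DataFrame
    class_weights: ClassWeights
    jigsaw_weights: JigsawWeights | None
    perms: object
    selection: FractionSelection | None = None
    target_in_supervised: int = 0
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")


def _predict_probs(model, images, head="supervised", batch_size=64):
    x = normalize_batch([_resize_uint8(np.asarray(im), INPUT_SIDE) for im in images])
    return model.predict_proba(x, head=head, batch_size=batch_size)


def fit_core(model: DualHeadModel, sup_images: list, sup_labels: np.ndarray,
             pool_images: list, config: TrainConfig,
             val_images: list | None = None, val_labels: np.ndarray | None = None,
             perms=None, sup_is_target: np.ndarray | None = None) -> TrainResult:
    """Run the alternating training loop on in-memory uint8 images.

    ``pool_images`` feeds the unsupervised stream; it is ignored in baseline
    mode.  ``sup_is_target`` flags target-domain frames for the routing
    audit.  Deterministic for a fixed config (all randomness flows from
    named child streams of config.seed).
    """
    unsup_enabled = config.mode != "baseline" and config.unsupervised_step
    if unsup_enabled and len(pool_images) == 0:
        logger.warning("unlabelled pool empty; falling back to labelled frames only")
        pool_images = sup_images

    ss = np.random.SeedSequence([int(config.seed), 313])
    kids = ss.spawn(5)
    rng_sup_order = np.random.default_rng(kids[0])
    rng_sup_aug = np.random.default_rng(kids[1])
    rng_unsup_order = np.random.default_rng(kids[2])
    rng_unsup_aug = np.random.default_rng(kids[3])
    rng_jigsaw = np.random.default_rng(kids[4])

    class_w = compute_class_weights(sup_labels, n_classes=2)
    jig_w = JigsawWeights.from_ratio(config.s, config.P) if unsup_enabled else None
    if unsup_enabled and perms is None:
        perms = generate_permutation_set(config.grid_size**2, config.P,
                                         seed=int(config.seed))
    jig_cfg = JigsawConfig(grid_size=config.grid_size, output_side=INPUT_SIDE,
                           scrambled_ratio_s=config.s, P=config.P)

    opt = AdamW(lr=config.lr, weight_decay=config.weight_decay)
    sup_cycler = _Cycler(len(sup_images), rng_sup_order)
    B = config.batch_size
    n_iter = (math.ceil(len(pool_images) / B) if unsup_enabled
              else math.ceil(len(sup_images) / B))
    n_iter = max(n_iter, 1)

    w_sup = np.asarray(class_w.weights)
    target_count = 0
    history = []
    best_val, best_epoch, best_params = -np.inf, -1, None

    for epoch in range(config.epochs):
        lam = lambda_at_epoch(config.lambda0, epoch, config.lambda_growth)
        if unsup_enabled:
            unsup_order = rng_unsup_order.permutation(len(pool_images))
        ls_vals, lu_vals = [], []
        for it in range(n_iter):
            # ---- supervised phase: D_K batch, never scrambled -------------
            idx = sup_cycler.take(min(B, len(sup_images)))
            if sup_is_target is not None:
                target_count += int(sup_is_target[idx].sum())
            batch = [
                augment_geometric(sup_images[i], rng_sup_aug) if config.augment
                else _resize_uint8(np.asarray(sup_images[i]), INPUT_SIDE)
                for i in idx
            ]
            x = normalize_batch(batch)
            y = sup_labels[idx]
            logits, cache = model.forward(x, head="supervised")
            probs = softmax(logits)
            ls_vals.append(supervised_loss(probs, y, class_w))
            onehot = np.eye(2)[y]
            dlogits = (w_sup[y][:, None] * (probs - onehot)) / len(y)
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)

            # ---- unsupervised phase: jigsaw batch from the whole pool -----
            if unsup_enabled:
                lo = (it * B) % len(pool_images)
                take = unsup_order[lo : lo + B]
                if len(take) == 0:
                    take = unsup_order[:B]
                frames = [
                    augment_geometric(pool_images[i], rng_unsup_aug)
                    if config.augment
                    else _resize_uint8(np.asarray(pool_images[i]), INPUT_SIDE)
                    for i in take
                ]
                samples = make_unsupervised_batch(frames, jig_cfg, perms, rng_jigsaw,
                                                  jitter=config.jitter)
                xz = normalize_batch([smp.image_z for smp in samples])
                yz = np.array([smp.pseudo_label for smp in samples])
                logits_u, cache_u = model.forward(xz, head="jigsaw")
                probs_u = softmax(logits_u)
                lu_vals.append(jigsaw_loss(probs_u, yz, jig_w))
                onehot_u = np.eye(config.P + 1)[yz]
                wv = np.asarray(jig_w.weights)[yz][:, None]
                dlogits_u = lam * wv * (probs_u - onehot_u) / len(yz)
                grads_u = model.backward(dlogits_u, cache_u)
                opt.step(model.params, grads_u)

        rec = {"epoch": epoch, "lambda": lam,
               "L_S": float(np.mean(ls_vals)),
               "L_U": float(np.mean(lu_vals)) if lu_vals else 0.0}
        rec["L_total"] = rec["L_S"] + lam * rec["L_U"]
        if val_images is not None and len(val_images):
            vp = _predict_probs(model, val_images)
            pred = (vp[:, 1] > vp[:, 0]).astype(int)  # ties -> negative class
            acc = float((pred == val_labels).mean())
            rec["val_accuracy"] = acc
            if acc > best_val:
                best_val, best_epoch = acc, epoch
                best_params = {k: v.copy() for k, v in model.params.items()}
        history.append(rec)
        logger.info("epoch %d: %s", epoch,
                    " ".join(f"{k}={v:.4f}" for k, v in rec.items() if k != "epoch"))

    if best_params is not None:
        model.params = best_params

    return TrainResult(model=model, history=pd.DataFrame(history),
                       class_weights=class_w, jigsaw_weights=jig_w, perms=perms,
                       target_in_supervised=target_count, best_epoch=best_epoch,
                       best_val_accuracy=best_val if np.isfinite(best_val)
                       else float("nan"))


# --------------------------------------------------------------------------
# manifest-level entry points
# --------------------------------------------------------------------------

def _frames(df: pd.DataFrame, images: dict):
    return [images[p] for p in df["frame_path"]]


def train(manifest: pd.DataFrame, config: TrainConfig, images: dict,
          model: DualHeadModel | None = None, perms=None) -> TrainResult:
    """Train on a manifest (standard SSL or baseline mode).

    ``images`` maps frame_path to a uint8 array (see manifest.load_images).
    """
    if config.mode == "domain_adaptation":
        return train_domain_adaptation(manifest, config, images, model, perms)
    sel = select_labeled_fraction(manifest, config.k_fraction, config.fold,
                                  config.seed, n_folds=config.n_folds)
    if model is None:
        model = DualHeadModel(backbone=config.backbone, P=config.P,
                              seed=config.seed,
                              include_jigsaw=config.mode != "baseline")
    res = fit_core(
        model,
        _frames(sel.dk, images), label_codes(sel.dk),
        _frames(sel.pool, images), config,
        val_images=_frames(sel.val, images), val_labels=label_codes(sel.val),
        perms=perms,
    )
    res.selection = sel
    return res


def train_domain_adaptation(manifest: pd.DataFrame, config: TrainConfig,
                            images: dict, model: DualHeadModel | None = None,
                            perms=None) -> TrainResult:
    """Domain-adaptation routing: labelled source frames feed the supervised
    phase; the unsupervised phase sees labelled source plus unlabelled target
    frames.  Held-out labelled target frames are the test set."""
    src, tgt = config.source_domain, config.target_domain
    train_rows = manifest[manifest["split"] == "train"]
    if not (train_rows["domain"] == tgt).any():
        raise ValueError(f"no target-domain ({tgt}) frames in the training split")
    sel = select_labeled_fraction(manifest, config.k_fraction, config.fold,
                                  config.seed, n_folds=config.n_folds, domain=src)
    unl_target = train_rows[(train_rows["domain"] == tgt)
                            & (train_rows["label"] == "unlabeled")]
    pool = pd.concat([sel.dk, unl_target])
    if model is None:
        model = DualHeadModel(backbone=config.backbone, P=config.P,
                              seed=config.seed, include_jigsaw=True)
    res = fit_core(
        model,
        _frames(sel.dk, images), label_codes(sel.dk),
        _frames(pool, images), config,
        val_images=_frames(sel.val, images), val_labels=label_codes(sel.val),
        perms=perms,
        sup_is_target=(sel.dk["domain"] == tgt).to_numpy(),
    )
    res.selection = sel
    return res


def predict_proba(model: DualHeadModel, images, head: str = "supervised"):
    """Posterior probabilities for raw uint8 images (resized + normalized)."""
    return _predict_probs(model, images, head=head)
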