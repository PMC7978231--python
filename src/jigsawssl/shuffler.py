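"""Jigsaw image shuffling: tiling, tile jitter, recomposition, batch assembly.

An input image is cut into a ``grid_size x grid_size`` grid of tiles.  From
each tile a sub-patch of 0.75-0.9 times the tile side is cropped at a random
offset and rescaled back to the tile size, which destroys low-level cues
(edge continuity, local colour gradients) across tile borders.  The jittered
tiles are reordered by a permutation drawn from the permutation set and
concatenated back into an image of the original size, whose pseudo-label is
the permutation index.  Pseudo-label 0 means the image is left untouched.

Unsupervised mini-batches keep a scrambled : unscrambled ratio of
``s : (1 - s)``; the permutation index for scrambled images is uniform on
{1..P}, so pseudo-label frequencies are ``((1-s), s/P, ..., s/P)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .permutations import PermutationSet

__all__ = [
    "JigsawConfig",
    "ShuffledSample",
    "tile_image",
    "jitter_tile",
    "compose_jigsaw",
    "make_unsupervised_batch",
]


@dataclass(frozen=True)
class JigsawConfig:
    """Geometry and mixing parameters of the jigsaw shuffler."""

    grid_size: int = 3
    patch_scale_min: float = 0.75
    patch_scale_max: float = 0.9
    output_side: int = 222
    scrambled_ratio_s: float = 0.6
    P: int = 30

    def __post_init__(self):
        if self.output_side % self.grid_size != 0:
            raise ValueError(
                f"output_side {self.output_side} not divisible by grid {self.grid_size}"
            )
        if not 0 < self.patch_scale_min <= self.patch_scale_max <= 1:
            raise ValueError("require 0 < patch_scale_min <= patch_scale_max <= 1")
        if not 0 <= self.scrambled_ratio_s <= 1:
            raise ValueError("scrambled_ratio_s must be in [0, 1]")
        if self.P < 1:
            raise ValueError("P must be >= 1")

    @property
    def tile_side(self) -> int:
        return self.output_side // self.grid_size

    @property
    def n_tiles(self) -> int:
        return self.grid_size**2


@dataclass(frozen=True)
class ShuffledSample:
    image_z: np.ndarray  # (output_side, output_side, 3)
    pseudo_label: int  # 0..P; 0 = unscrambled original
    source_id: object = None


def tile_image(image: np.ndarray, config: JigsawConfig) -> list[np.ndarray]:
    """Split a square image into grid_size**2 tiles in row-major order."""
    img = np.asarray(image)
    side = config.output_side
    if img.shape[:2] != (side, side):
        raise ValueError(f"expected a {side}x{side} image, got shape {img.shape}")
    t = config.tile_side
    return [
        img[r * t : (r + 1) * t, c * t : (c + 1) * t].copy()
        for r in range(config.grid_size)
        for c in range(config.grid_size)
    ]


def _resize(arr: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize preserving dtype (uint8 round-trips through PIL)."""
    if arr.shape[0] == side and arr.shape[1] == side:
        return arr
    if arr.dtype == np.uint8:
        return np.asarray(Image.fromarray(arr).resize((side, side), Image.BILINEAR))
    as8 = np.clip(arr * 255.0, 0, 255).astype(np.uint8)
    out = np.asarray(Image.fromarray(as8).resize((side, side), Image.BILINEAR))
    return out.astype(arr.dtype) / 255.0


def jitter_tile(tile: np.ndarray, config: JigsawConfig, rng: np.random.Generator) -> np.ndarray:
    """Crop a random sub-patch of 0.75-0.9x the tile side and rescale back.

    The crop side is floor(scale * tile_side) with scale uniform on
    [patch_scale_min, patch_scale_max]; the offset is uniform over valid
    integer positions.  With both scales pinned to 1.0 this is the identity.
    """
    tile = np.asarray(tile)
    t = tile.shape[0]
    if tile.shape[1] != t:
        raise ValueError(f"tile must be square, got {tile.shape}")
    scale = rng.uniform(config.patch_scale_min, config.patch_scale_max)
    side = int(np.floor(scale * t))
    side = max(1, min(side, t))
    max_off = t - side
    r = int(rng.integers(0, max_off + 1))
    c = int(rng.integers(0, max_off + 1))
    patch = tile[r : r + side, c : c + side]
    return _resize(patch, t)


def compose_jigsaw(
    image: np.ndarray,
    pseudo_label: int,
    perms: PermutationSet,
    config: JigsawConfig,
    rng: np.random.Generator,
    jitter: bool = True,
) -> ShuffledSample:
    """Build a jigsaw sample: pseudo-label 0 passes the image through untouched;
    otherwise tiles are jittered, reordered by the permutation, and re-concatenated.

    Slot ``j`` of the output receives source tile ``perm[j]``, so applying the
    inverse permutation to the output's tiles recovers the original layout.
    """
    if not 0 <= pseudo_label <= perms.P:
        raise ValueError(f"pseudo_label {pseudo_label} outside 0..{perms.P}")
    img = np.asarray(image)
    if pseudo_label == 0:
        return ShuffledSample(image_z=img.copy(), pseudo_label=0)

    tiles = tile_image(img, config)
    if jitter:
        tiles = [jitter_tile(t, config, rng) for t in tiles]
    perm = perms.entries[pseudo_label]
    t = config.tile_side
    g = config.grid_size
    out = np.empty_like(img)
    for j, src in enumerate(perm):
        r, c = divmod(j, g)
        out[r * t : (r + 1) * t, c * t : (c + 1) * t] = tiles[src]
    return ShuffledSample(image_z=out, pseudo_label=int(pseudo_label))


def make_unsupervised_batch(
    frames,
    config: JigsawConfig,
    perms: PermutationSet,
    rng: np.random.Generator,
    jitter: bool = True,
    source_ids=None,
) -> list[ShuffledSample]:
    """Assemble an unsupervised mini-batch with scrambled ratio ``s``.

    Each frame is independently scrambled with probability ``s`` (permutation
    index uniform on {1..P}) and otherwise kept unscrambled with pseudo-label
    0, giving expected label frequencies ((1-s), s/P, ..., s/P).
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("empty batch")
    if source_ids is None:
        source_ids = [None] * len(frames)
    s = config.scrambled_ratio_s
    out = []
    for frame, sid in zip(frames, source_ids):
        if rng.random() < s:
            label = int(rng.integers(1, perms.P + 1))
        else:
            label = 0
        sample = compose_jigsaw(frame, label, perms, config, rng, jitter=jitter)
        out.append(ShuffledSample(sample.image_z, sample.pseudo_label, sid))
    return out
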