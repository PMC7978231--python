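"""Synthetic two-domain lesion videos for desk-scale experiments.

The real study data (colonoscopy videos of biopsied lesions) is private, so
this module renders small surrogate datasets with the statistical structure
the method relies on:

* two classes separated by *global* cues — class 1 ("neoplastic-like") has a
  lobulated blob boundary and coarse internal texture, class 0 a smooth
  boundary and fine texture.  Local edge continuity carries no class signal,
  which is the regime where a jigsaw pretext task can plausibly help;
* two imaging domains differing in colour statistics — domain A (WLI-like)
  uses a warm broad-band palette, domain B (NBI-like) a green–blue
  narrow-band palette;
* frames grouped into correlated "videos": each video renders one base
  lesion and frames are small affine jitters plus pixel noise of that
  render, so video-level splitting genuinely matters;
* class imbalance near 0.83 : 0.17 among labelled videos, and a fraction of
  videos left unlabelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = ["SyntheticConfig", "generate_lesion_video", "generate_dataset"]

# per-domain base palettes: background colour, lesion colour (RGB in [0,1])
_PALETTES = {
    "WLI": {"bg": np.array([0.82, 0.55, 0.45]), "lesion": np.array([0.75, 0.38, 0.30])},
    "NBI": {"bg": np.array([0.25, 0.52, 0.48]), "lesion": np.array([0.18, 0.40, 0.45])},
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_videos: int = 60
    frames_per_video: int = 15
    image_side: int = 222
    class_imbalance: float = 0.83   # fraction of labelled videos that are class 1
    unlabeled_fraction: float = 0.4
    domain_mix: float = 0.6         # fraction of domain-A (WLI-like) videos
    test_fraction: float = 0.2      # labelled videos held out as the test split
    noise_sd: float = 0.03          # pixel noise SD on the [0, 1] intensity scale
    seed: int = 0
    local_signal_only: bool = False  # negative control: class cue is a local colour patch

    def __post_init__(self):
        for name in ("class_imbalance", "unlabeled_fraction", "domain_mix",
                     "test_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_videos < 10:
            raise ValueError(f"n_videos must be >= 10, got {self.n_videos}")


def _smooth_noise(side: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _render_base_lesion(class_label: int, domain: str, config: SyntheticConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """One base lesion image in float RGB [0, 1].

    Appearance varies strongly from lesion to lesion (tone, size, contrast,
    illumination, highlights) so that a handful of training videos cannot
    represent a class; the class signal itself is global — margin lobulation
    and internal texture scale — with deliberately overlapping distributions.
    """
    side = config.image_side
    pal = _PALETTES[domain]
    # per-lesion appearance: tone jitter, contrast, illumination
    tone = rng.uniform(0.75, 1.2, size=3)
    bg_col = np.clip(pal["bg"] * tone * rng.uniform(0.85, 1.15), 0, 1)
    lesion_col = np.clip(pal["lesion"] * tone * rng.uniform(0.8, 1.2), 0, 1)
    # keep a minimum lesion/background contrast so the lesion is visible
    diff = lesion_col - bg_col
    norm = np.linalg.norm(diff)
    if norm < 0.15:
        direction = diff / norm if norm > 1e-6 else np.array([-1.0, -0.5, -0.5])
        lesion_col = np.clip(bg_col + 0.15 * direction / np.linalg.norm(direction), 0, 1)

    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    cy = side / 2 + rng.uniform(-0.10, 0.10) * side
    cx = side / 2 + rng.uniform(-0.10, 0.10) * side
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(yy - cy, xx - cx)

    r0 = side * rng.uniform(0.18, 0.34)
    aspect = rng.uniform(0.7, 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    ell = r0 * (aspect + (1 - aspect) * np.cos(theta - phase) ** 2)

    if config.local_signal_only:
        amp = rng.uniform(0.0, 0.05)
    elif class_label == 1:
        amp = rng.uniform(0.14, 0.26)   # lobulated margin
    else:
        amp = rng.uniform(0.0, 0.07)    # smooth margin (distributions overlap)
    lobes = int(rng.integers(3, 6))
    phase2 = rng.uniform(0, 2 * np.pi)
    boundary = ell * (1 + amp * np.cos(lobes * theta + phase2)
                      + 0.35 * amp * np.cos((lobes + 2) * theta - phase2))

    inside = 1.0 / (1.0 + np.exp((r - boundary) / 2.0))  # soft mask

    bg_tex = 0.06 * _smooth_noise(side, rng.uniform(3.0, 5.0), rng)
    if config.local_signal_only:
        tex_sigma, tex_amp = rng.uniform(1.5, 4.0), 0.06
    elif class_label == 1:
        tex_sigma, tex_amp = rng.uniform(4.5, 7.0), rng.uniform(0.08, 0.12)  # coarse
    else:
        tex_sigma, tex_amp = rng.uniform(1.0, 2.2), rng.uniform(0.04, 0.07)  # fine
    lesion_tex = tex_amp * _smooth_noise(side, tex_sigma, rng)

    shading = 0.10 * _smooth_noise(side, 25.0, rng)
    # radial vignetting of random strength, off-centre (endoscope illumination)
    vy = side / 2 + rng.uniform(-0.2, 0.2) * side
    vx = side / 2 + rng.uniform(-0.2, 0.2) * side
    vig = 1.0 - rng.uniform(0.1, 0.4) * (np.hypot(yy - vy, xx - vx) / side) ** 2

    lum_bg = (1.0 + bg_tex + shading) * vig
    lum_lesion = (1.0 + lesion_tex + shading) * vig

    img = (bg_col[None, None, :] * lum_bg[:, :, None] * (1 - inside[:, :, None])
           + lesion_col[None, None, :] * lum_lesion[:, :, None] * inside[:, :, None])

    # specular highlights: small saturated spots from the light source
    for _ in range(int(rng.integers(1, 4))):
        hy, hx = rng.uniform(0.1, 0.9, size=2) * side
        hs = rng.uniform(2.0, 5.0)
        spot = np.exp(-((yy - hy) ** 2 + (xx - hx) ** 2) / (2 * hs**2))
        img = img + 0.9 * spot[:, :, None]

    if config.local_signal_only and class_label == 1:
        # negative control: the only class cue is a small bright patch
        pr = int(rng.integers(10, side - 26))
        pc = int(rng.integers(10, side - 26))
        img[pr : pr + 16, pc : pc + 16] = np.array([0.95, 0.95, 0.2])

    return np.clip(img, 0.0, 1.0)


def _affine_jitter(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Small random rotation/scale/shift of the base render (per frame)."""
    angle = rng.uniform(-8, 8)
    scale = rng.uniform(0.95, 1.05)
    shift = rng.uniform(-6, 6, size=2)
    side = img.shape[0]
    c = np.array([side / 2, side / 2])
    a = np.deg2rad(angle)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) / scale
    offset = c - rot @ (c + shift)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            img[:, :, ch], rot, offset=offset, order=1, mode="reflect"
        )
    return out


def generate_lesion_video(class_label: int, domain: str, config: SyntheticConfig,
                          rng: np.random.Generator) -> list[np.ndarray]:
    """Render one lesion and return ``frames_per_video`` correlated frames (uint8)."""
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label}")
    if domain not in _PALETTES:
        raise ValueError(f"domain must be one of {sorted(_PALETTES)}, got {domain!r}")
    base = _render_base_lesion(class_label, domain, config, rng)
    frames = []
    for _ in range(config.frames_per_video):
        frame = _affine_jitter(base, rng)
        frame = frame + rng.normal(0.0, config.noise_sd, size=frame.shape)
        frames.append((np.clip(frame, 0, 1) * 255).round().astype(np.uint8))
    return frames


def generate_dataset(config: SyntheticConfig, out_dir=None):
    """Generate the full dataset.

    Returns ``(manifest, images)`` where ``manifest`` is a DataFrame with
    columns (frame_path, label, video_id, domain, split) and ``images`` maps
    frame_path -> uint8 HxWx3 array.  If ``out_dir`` is given, PNG frames and
    ``manifest.csv`` are also written there.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20201225]))

    n = config.n_videos
    n_unlabeled = int(round(config.unlabeled_fraction * n))
    n_labeled = n - n_unlabeled
    n_pos = int(round(config.class_imbalance * n_labeled))
    n_pos = min(max(n_pos, 1), n_labeled - 1)  # both classes present

    # video-level attributes
    labeled_flags = np.array([True] * n_labeled + [False] * n_unlabeled)
    rng.shuffle(labeled_flags)
    classes = np.empty(n, dtype=int)
    lab_idx = np.flatnonzero(labeled_flags)
    cls_lab = np.array([1] * n_pos + [0] * (n_labeled - n_pos))
    rng.shuffle(cls_lab)
    classes[lab_idx] = cls_lab
    unl_idx = np.flatnonzero(~labeled_flags)
    classes[unl_idx] = (rng.random(len(unl_idx)) < config.class_imbalance).astype(int)

    n_a = int(round(config.domain_mix * n))
    domains = np.array(["WLI"] * n_a + ["NBI"] * (n - n_a))
    rng.shuffle(domains)

    # labelled videos: test_fraction held out per (class, domain) where possible
    splits = np.array(["train"] * n, dtype=object)
    for c in (0, 1):
        for d in ("WLI", "NBI"):
            vids = np.flatnonzero(labeled_flags & (classes == c) & (domains == d))
            rng.shuffle(vids)
            n_test = int(round(config.test_fraction * len(vids)))
            splits[vids[:n_test]] = "test"

    rows = []
    images = {}
    for v in range(n):
        vid = f"vid{v:03d}"
        frames = generate_lesion_video(int(classes[v]), str(domains[v]), config, rng)
        label = str(classes[v]) if labeled_flags[v] else "unlabeled"
        for f, frame in enumerate(frames):
            path = f"{vid}/frame{f:03d}.png"
            rows.append({"frame_path": path, "label": label, "video_id": vid,
                         "domain": str(domains[v]), "split": str(splits[v])})
            images[path] = frame
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        for path, frame in images.items():
            p = out_dir / path
            p.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(frame).save(p)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, images
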