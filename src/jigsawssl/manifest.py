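"""Dataset manifest reading, validation and helpers.

A manifest is a CSV with columns (frame_path, label, video_id, domain,
split).  Labels are "0", "1" or "unlabeled"; the labelled rows form D_L and
the unlabelled rows D_U.  All frames of one video must share a single split,
label status and domain — the video-level consistency that prevents
near-duplicate frames of the same lesion leaking across partitions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["ManifestError", "read_manifest", "validate_manifest", "label_codes",
           "load_images"]

REQUIRED_COLUMNS = ("frame_path", "label", "video_id", "domain", "split")
VALID_LABELS = {"0", "1", "unlabeled"}
VALID_DOMAINS = {"WLI", "NBI"}
VALID_SPLITS = {"train", "val", "test"}


class ManifestError(ValueError):
    """Schema violation in a dataset manifest."""


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"missing required columns: {missing}")
    df = df.copy()
    df["label"] = df["label"].astype(str)
    for col, valid in (("label", VALID_LABELS), ("domain", VALID_DOMAINS),
                       ("split", VALID_SPLITS)):
        bad = ~df[col].isin(valid)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ManifestError(
                f"row {i} ({df['frame_path'].iloc[i]}): invalid {col} "
                f"{df[col].iloc[i]!r}, expected one of {sorted(valid)}"
            )
    dup = df["frame_path"].duplicated()
    if dup.any():
        raise ManifestError(
            f"duplicate frame_path {df['frame_path'][dup].iloc[0]!r}"
        )
    for col in ("split", "label", "domain"):
        per_video = df.groupby("video_id")[col].nunique()
        bad = per_video[per_video > 1]
        if len(bad):
            raise ManifestError(
                f"video {bad.index[0]!r} has frames with mixed {col} values"
            )
    return df


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest CSV."""
    df = pd.read_csv(path, dtype=str)
    return validate_manifest(df)


def label_codes(df: pd.DataFrame) -> np.ndarray:
    """Integer labels: 0, 1, or -1 for unlabelled rows."""
    return df["label"].map({"0": 0, "1": 1, "unlabeled": -1}).to_numpy(dtype=int)


def load_images(df: pd.DataFrame, root=None, images: dict | None = None) -> dict:
    """Resolve manifest rows to uint8 image arrays.

    ``images`` may supply in-memory arrays keyed by frame_path (as produced
    by the synthetic generator); otherwise frames are read from ``root``.
    """
    out = {}
    for path in df["frame_path"]:
        if images is not None and path in images:
            out[path] = images[path]
        else:
            full = Path(root) / path if root is not None else Path(path)
            out[path] = np.asarray(Image.open(full).convert("RGB"))
    return out
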