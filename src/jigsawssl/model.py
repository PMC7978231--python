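"""Shared-encoder, dual-head classifier.

A single feature encoder feeds two affine heads: a supervised head with 2
logits (non-neoplastic vs neoplastic) and a jigsaw head with P+1 logits (the
identity ordering plus the P scrambled permutations).  Training alternates
between the heads; each phase updates the encoder and its own head only, so
the other head's parameters stay bit-identical.  Discarding the jigsaw head
leaves supervised inference unchanged.

Two CPU-friendly backbones are provided: ``tiny-conv`` (two conv blocks on a
6x-downsampled input, 64-d features) and ``small-residual`` (a deeper
residual variant, 128-d features).  Feature maps are flattened rather than
globally pooled so the encoder keeps the spatial information the jigsaw task
needs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import AvgPool, Conv, Dense, Flatten, ReLU, Residual, softmax

__all__ = ["DualHeadModel", "forward_supervised", "forward_jigsaw", "INPUT_SIDE"]

INPUT_SIDE = 222


def _tiny_conv():
    layers = [
        AvgPool(6),                       # 3 x 37 x 37
        Conv("enc/c1", 3, 8, k=3),        # 8 x 35 x 35
        ReLU(),
        AvgPool(2),                       # 8 x 17 x 17
        Conv("enc/c2", 8, 16, k=3),       # 16 x 15 x 15
        ReLU(),
        AvgPool(3),                       # 16 x 5 x 5
        Flatten(),                        # 400
        Dense("enc/fc", 400, 64),
        ReLU(),
    ]
    return layers, 64


def _small_residual():
    layers = [
        AvgPool(3),                        # 3 x 74 x 74
        Conv("enc/c0", 3, 16, k=3),        # 16 x 72 x 72
        ReLU(),
        AvgPool(2),                        # 16 x 36 x 36
        Residual([
            Conv("enc/r1a", 16, 16, k=3, pad=1),
            ReLU(),
            Conv("enc/r1b", 16, 16, k=3, pad=1),
        ]),
        AvgPool(2),                        # 16 x 18 x 18
        Residual([
            Conv("enc/r2a", 16, 16, k=3, pad=1),
            ReLU(),
            Conv("enc/r2b", 16, 16, k=3, pad=1),
        ]),
        AvgPool(2),                        # 16 x 9 x 9
        Flatten(),                         # 1296
        Dense("enc/fc", 1296, 128),
        ReLU(),
    ]
    return layers, 128


_BACKBONES = {"tiny-conv": _tiny_conv, "small-residual": _small_residual}


class DualHeadModel:
    """Feature encoder theta_e with supervised head theta_s and jigsaw head theta_u."""

    def __init__(self, backbone: str = "tiny-conv", P: int = 30, seed: int = 0,
                 include_jigsaw: bool = True):
        if backbone not in _BACKBONES:
            raise ValueError(f"unknown backbone {backbone!r}; have {sorted(_BACKBONES)}")
        self.backbone_name = backbone
        self.P = int(P)
        self.seed = int(seed)
        self.include_jigsaw = bool(include_jigsaw)
        self.encoder_layers, self.feature_dim = _BACKBONES[backbone]()
        self.sup_head = Dense("sup/fc", self.feature_dim, 2)
        self.params = _nn.init_params(self.encoder_layers, seed)
        self.params.update(self.sup_head.init(seed))
        if include_jigsaw:
            self.jig_head = Dense("jig/fc", self.feature_dim, self.P + 1)
            self.params.update(self.jig_head.init(seed))
        else:
            self.jig_head = None

    # ---- parameter bookkeeping -------------------------------------------
    @property
    def encoder_param_names(self):
        return [n for n in self.params if n.startswith("enc/")]

    def phase_param_names(self, phase: str):
        """Parameters a training phase is allowed to update."""
        if phase == "supervised":
            heads = [n for n in self.params if n.startswith("sup/")]
        elif phase == "unsupervised":
            heads = [n for n in self.params if n.startswith("jig/")]
        else:
            raise ValueError(f"unknown phase {phase!r}")
        return self.encoder_param_names + heads

    # ---- forward / backward ----------------------------------------------
    def _check_input(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != INPUT_SIDE or x.shape[3] != INPUT_SIDE:
            raise ValueError(
                f"expected input of shape (B, 3, {INPUT_SIDE}, {INPUT_SIDE}), got {x.shape}"
            )
        return x

    def forward(self, x, head: str = "supervised"):
        """Return (logits, cache) for the requested head."""
        x = self._check_input(x)
        feats, enc_caches = _nn.forward_layers(x, self.encoder_layers, self.params)
        if head == "supervised":
            logits, hcache = self.sup_head.forward(feats, self.params)
            h = self.sup_head
        elif head == "jigsaw":
            if self.jig_head is None:
                raise ValueError("model was built without a jigsaw head")
            logits, hcache = self.jig_head.forward(feats, self.params)
            h = self.jig_head
        else:
            raise ValueError(f"unknown head {head!r}")
        return logits, (enc_caches, hcache, h)

    def backward(self, dlogits, cache):
        """Gradients for the encoder and the head used in the forward pass."""
        enc_caches, hcache, head = cache
        dfeats, grads = head.backward(dlogits, hcache, self.params)
        _, enc_grads = _nn.backward_layers(dfeats, self.encoder_layers, enc_caches,
                                           self.params, need_input_grad=False)
        grads.update(enc_grads)
        return grads

    def predict_proba(self, x, head: str = "supervised", batch_size: int = 64):
        """Softmax probabilities, computed in mini-batches."""
        x = self._check_input(x)
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size], head=head)
            out.append(softmax(logits))
        return np.vstack(out)

    # ---- persistence -------------------------------------------------------
    def save(self, path, perm_file=None) -> None:
        """Checkpoint to .npz plus a plain-text metadata sidecar."""
        path = Path(path)
        np.savez(path, **self.params)
        perm_hash = ""
        if perm_file is not None:
            perm_hash = hashlib.sha256(Path(perm_file).read_bytes()).hexdigest()
        sidecar = path.with_suffix(path.suffix + ".meta.txt")
        sidecar.write_text(
            f"backbone_name {self.backbone_name}\n"
            f"P {self.P}\n"
            f"feature_dim {self.feature_dim}\n"
            f"include_jigsaw {int(self.include_jigsaw)}\n"
            f"seed {self.seed}\n"
            f"permutation_file_sha256 {perm_hash}\n"
        )

    @classmethod
    def load(cls, path) -> "DualHeadModel":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".meta.txt")
        meta = {}
        for line in sidecar.read_text().strip().splitlines():
            parts = line.split(None, 1)
            meta[parts[0]] = parts[1].strip() if len(parts) > 1 else ""
        model = cls(
            backbone=meta["backbone_name"],
            P=int(meta["P"]),
            seed=int(meta["seed"]),
            include_jigsaw=bool(int(meta["include_jigsaw"])),
        )
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as data:
            for name in model.params:
                model.params[name] = data[name].copy()
        return model


def forward_supervised(model: DualHeadModel, batch) -> np.ndarray:
    """Per-sample posterior probabilities over {non-neoplastic, neoplastic}."""
    return model.predict_proba(batch, head="supervised")


def forward_jigsaw(model: DualHeadModel, batch) -> np.ndarray:
    """Per-sample probabilities over the P+1 jigsaw pseudo-labels."""
    return model.predict_proba(batch, head="jigsaw")
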