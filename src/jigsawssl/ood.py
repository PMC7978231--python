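"""Out-of-distribution detection experiments.

A classifier trained purely on in-distribution (WLI) lesion images is reused
as an OOD detector at inference: every test frame is presented unscrambled
and scored with kappa = KL[U || p(y|x)] (+ the weighted jigsaw cross-entropy
at pseudo-label 0 in ssl mode).  WLI test frames are the negative class
(label 0) and NBI frames the positive class (label 1); AUROC of kappa
against these labels measures detector quality.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluation import roc_auc
from .manifest import label_codes
from .objectives import JigsawWeights, ood_scores_batch
from .trainer import TrainConfig, fit_core, predict_proba, select_labeled_fraction
from .model import DualHeadModel

__all__ = ["score_frames", "run_ood_eval", "run_ood_experiment"]


def score_frames(model, frames, jigsaw_weights: JigsawWeights | None,
                 mode: str = "ssl", sample_ids=None, domain_labels=None) -> pd.DataFrame:
    """Per-frame OOD scores as a table (sample_id, kl_term, jigsaw_term,
    kappa, domain_label)."""
    class_probs = predict_proba(model, frames, head="supervised")
    jig_probs = None
    if mode == "ssl":
        jig_probs = predict_proba(model, frames, head="jigsaw")
    kappa, kl, jig = ood_scores_batch(class_probs, jig_probs, jigsaw_weights, mode)
    n = len(kappa)
    return pd.DataFrame({
        "sample_id": sample_ids if sample_ids is not None else np.arange(n),
        "kl_term": kl,
        "jigsaw_term": jig,
        "kappa": kappa,
        "domain_label": domain_labels if domain_labels is not None else [""] * n,
    })


def run_ood_eval(model, manifest: pd.DataFrame, images: dict,
                 jigsaw_weights: JigsawWeights | None,
                 in_domain: str = "WLI", out_domain: str = "NBI"):
    """Score every labelled test-domain frame of one trained model.

    In-distribution = ``in_domain`` test-split frames (OOD label 0);
    out-of-distribution = all labelled ``out_domain`` frames (OOD label 1).
    Returns a dict with per-mode AUROC and the score tables.
    """
    for d in (in_domain, out_domain):
        if not (manifest["domain"] == d).any():
            raise ValueError(f"manifest has no {d} frames")
    ind = manifest[(manifest["domain"] == in_domain) & (manifest["split"] == "test")
                   & manifest["label"].isin(["0", "1"])]
    ood = manifest[(manifest["domain"] == out_domain)
                   & manifest["label"].isin(["0", "1"])]
    if len(ind) == 0 or len(ood) == 0:
        raise ValueError("need labelled frames in both domains")
    frames = [images[p] for p in pd.concat([ind, ood])["frame_path"]]
    ids = pd.concat([ind, ood])["frame_path"].tolist()
    labels = np.array([0] * len(ind) + [1] * len(ood))
    out = {"labels": labels}
    modes = ["baseline"] + (["ssl"] if model.include_jigsaw else [])
    for mode in modes:
        tbl = score_frames(model, frames, jigsaw_weights, mode=mode,
                           sample_ids=ids, domain_labels=labels)
        auc, curve = roc_auc(tbl["kappa"].to_numpy(), labels)
        out[mode] = {"auroc": auc, "scores": tbl, "curve": curve}
    return out


def run_ood_experiment(manifest: pd.DataFrame, images: dict, config: TrainConfig,
                       in_domain: str = "WLI", out_domain: str = "NBI"):
    """Full OOD benchmark: train an SSL model and a baseline model on
    in-distribution data only, then compare their kappa AUROCs.

    The supervised phase uses labelled in-domain videos; the SSL unsupervised
    phase uses labelled *and* unlabelled in-domain frames (validation
    excluded).  No out-of-distribution frame is seen during training.
    """
    sel = select_labeled_fraction(manifest, config.k_fraction, config.fold,
                                  config.seed, n_folds=config.n_folds,
                                  domain=in_domain)
    train_rows = manifest[manifest["split"] == "train"]
    pool = train_rows[(train_rows["domain"] == in_domain)
                      & ~train_rows["video_id"].isin(sel.val_videos)]

    sup_frames = [images[p] for p in sel.dk["frame_path"]]
    sup_labels = label_codes(sel.dk)
    pool_frames = [images[p] for p in pool["frame_path"]]
    val_frames = [images[p] for p in sel.val["frame_path"]]
    val_labels = label_codes(sel.val)

    results = {}
    for mode in ("ssl", "baseline"):
        cfg = replace(config, mode=mode)
        model = DualHeadModel(backbone=cfg.backbone, P=cfg.P, seed=cfg.seed,
                              include_jigsaw=(mode == "ssl"))
        res = fit_core(model, sup_frames, sup_labels, pool_frames, cfg,
                       val_images=val_frames, val_labels=val_labels)
        ev = run_ood_eval(res.model, manifest, images, res.jigsaw_weights,
                          in_domain=in_domain, out_domain=out_domain)
        results[mode] = {"train": res, "eval": ev,
                         "auroc": ev[mode]["auroc"]}
    return results
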