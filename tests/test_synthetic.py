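"""Synthetic dataset generator: structure, correlation, domains, learnability."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from jigsawssl.synthetic import (SyntheticConfig, generate_dataset,
                                 generate_lesion_video)


def texture_shape_features(img):
    """Mean colour plus boundary-roughness and texture-scale features.

    The lesion is segmented by chromaticity distance from the border
    background (illumination-invariant); roughness is the energy of angular
    harmonics 3-8 of the contour radius (lobulation, independent of the
    ellipse component), and texture scale is the mid/fine band-energy ratio
    inside the mask.
    """
    from scipy import ndimage
    from skimage import filters, measure

    x = img.astype(float) / 255.0
    bright = x.max(axis=2)
    chrom = x / (x.sum(axis=2, keepdims=True) + 1e-6)
    border = np.concatenate([chrom[:10].reshape(-1, 3), chrom[-10:].reshape(-1, 3),
                             chrom[:, :10].reshape(-1, 3), chrom[:, -10:].reshape(-1, 3)])
    dist = np.sqrt(((chrom - np.median(border, axis=0)) ** 2).sum(axis=2))
    dist[bright > 0.97] = 0  # specular highlights
    dist = ndimage.gaussian_filter(dist, 5)
    mask = dist > filters.threshold_otsu(dist)
    lab = measure.label(mask)
    if lab.max() > 0:
        mask = lab == (np.bincount(lab.ravel())[1:].argmax() + 1)
    mask = ndimage.binary_fill_holes(mask)

    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    cont = max(measure.find_contours(mask.astype(float), 0.5), key=len)
    th = np.arctan2(cont[:, 0] - cy, cont[:, 1] - cx)
    rr = np.hypot(cont[:, 0] - cy, cont[:, 1] - cx)
    idx = np.clip(np.digitize(th, np.linspace(-np.pi, np.pi, 73)) - 1, 0, 71)
    prof = np.array([rr[idx == i].mean() if (idx == i).any() else np.nan
                     for i in range(72)])
    if np.isnan(prof).any():
        good = ~np.isnan(prof)
        prof = np.interp(np.arange(72), np.arange(72)[good], prof[good], period=72)
    F = np.abs(np.fft.rfft(prof - prof.mean())) / 72
    lobulation = np.sqrt((F[3:9] ** 2).sum()) / (prof.mean() + 1e-9)

    gray = x.mean(axis=2)
    g2 = ndimage.gaussian_filter(gray, 2.0)
    g8 = ndimage.gaussian_filter(gray, 8.0)
    fine = np.sqrt(((gray - g2)[mask] ** 2).mean())
    mid = np.sqrt(((g2 - g8)[mask] ** 2).mean())
    return list(x.mean(axis=(0, 1))) + [lobulation, mid / (fine + 1e-9)]


class TestVideoGeneration:
    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(n_videos=10, frames_per_video=3, seed=0)
        a = generate_lesion_video(1, "WLI", cfg, np.random.default_rng(5))
        b = generate_lesion_video(1, "WLI", cfg, np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_intra_video_correlation_exceeds_cross_video(self):
        cfg = SyntheticConfig(n_videos=10, frames_per_video=4, seed=0)
        rng = np.random.default_rng(2)
        videos = [generate_lesion_video(1, "WLI", cfg, rng) for _ in range(4)]

        def corr(a, b):
            fa = a.astype(float).ravel()
            fb = b.astype(float).ravel()
            return np.corrcoef(fa, fb)[0, 1]

        within = np.mean([corr(v[i], v[j]) for v in videos
                          for i in range(4) for j in range(i + 1, 4)])
        across = np.mean([corr(videos[i][0], videos[j][0])
                          for i in range(4) for j in range(i + 1, 4)])
        assert within > across

    def test_domains_differ_in_red_channel(self):
        cfg = SyntheticConfig(n_videos=10, frames_per_video=3, seed=0)
        rng = np.random.default_rng(3)
        wli = generate_lesion_video(0, "WLI", cfg, rng)
        nbi = generate_lesion_video(0, "NBI", cfg, rng)
        red_w = np.mean([f[:, :, 0].mean() for f in wli]) / 255.0
        red_n = np.mean([f[:, :, 0].mean() for f in nbi]) / 255.0
        assert red_w - red_n > 3 * cfg.noise_sd

    def test_invalid_inputs_rejected(self):
        cfg = SyntheticConfig(n_videos=10, frames_per_video=1, seed=0)
        with pytest.raises(ValueError):
            generate_lesion_video(2, "WLI", cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_lesion_video(0, "UV", cfg, np.random.default_rng(0))


class TestDatasetGeneration:
    def test_cardinality_and_schema(self, small_dataset):
        cfg, manifest, images = small_dataset
        assert len(manifest) == cfg.n_videos * cfg.frames_per_video
        assert len(images) == len(manifest)
        assert set(manifest.columns) == {"frame_path", "label", "video_id",
                                         "domain", "split"}

    def test_video_level_consistency(self, small_dataset):
        _, manifest, _ = small_dataset
        for col in ("label", "domain", "split"):
            assert (manifest.groupby("video_id")[col].nunique() == 1).all()

    def test_unlabeled_fraction_and_imbalance(self, default_dataset):
        cfg, manifest, _ = default_dataset
        vids = manifest.drop_duplicates("video_id")
        frac_unlab = (vids["label"] == "unlabeled").mean()
        assert frac_unlab == pytest.approx(cfg.unlabeled_fraction, abs=0.05)
        lab = vids[vids["label"] != "unlabeled"]
        assert (lab["label"] == "1").mean() == pytest.approx(
            cfg.class_imbalance, abs=0.05)

    def test_writes_pngs_and_csv(self, tmp_path):
        cfg = SyntheticConfig(n_videos=10, frames_per_video=2, seed=0)
        manifest, _ = generate_dataset(cfg, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / manifest["frame_path"].iloc[0]).exists()
        from jigsawssl.manifest import read_manifest
        assert len(read_manifest(tmp_path / "manifest.csv")) == 20

    def test_tiny_backbone_learns_full_data_quickly(self, default_dataset):
        """Supervised training on 100% of the labelled videos exceeds 75%
        held-out-video validation accuracy within 10 epochs on CPU."""
        from jigsawssl.trainer import TrainConfig, train
        _, manifest, images = default_dataset
        cfg = TrainConfig(k_fraction=100.0, fold=1, epochs=10, seed=0,
                          mode="baseline", lr=1e-3)
        res = train(manifest, cfg, images)
        assert res.best_val_accuracy > 0.75

    def test_domain_shift_is_real(self, default_dataset):
        """A model trained on the WLI domain only drops at least 10 accuracy
        points on NBI frames relative to its WLI validation accuracy."""
        from jigsawssl.evaluation import evaluate_model
        from jigsawssl.manifest import label_codes
        from jigsawssl.model import DualHeadModel
        from jigsawssl.trainer import (TrainConfig, fit_core,
                                       select_labeled_fraction)
        _, manifest, images = default_dataset
        cfg = TrainConfig(k_fraction=100.0, fold=1, epochs=10, seed=0,
                          mode="baseline", lr=1e-3, n_folds=3)
        sel = select_labeled_fraction(manifest, 100.0, 1, 0, n_folds=3,
                                      domain="WLI")
        model = DualHeadModel("tiny-conv", P=30, seed=0, include_jigsaw=False)
        res = fit_core(model, [images[p] for p in sel.dk["frame_path"]],
                       label_codes(sel.dk), [], cfg,
                       val_images=[images[p] for p in sel.val["frame_path"]],
                       val_labels=label_codes(sel.val))
        nbi = manifest[(manifest["domain"] == "NBI")
                       & manifest["label"].isin(["0", "1"])]
        rep = evaluate_model(res.model, [images[p] for p in nbi["frame_path"]],
                             label_codes(nbi))
        assert res.best_val_accuracy - rep.accuracy >= 0.10

    def test_linear_oracle_learns_domain_a(self, default_dataset):
        """Mean colour + texture-band features separate the classes on the
        WLI domain: the task is learnable from global cues."""
        _, manifest, images = default_dataset
        rows = manifest[(manifest["domain"] == "WLI")
                        & manifest["label"].isin(["0", "1"])]
        X = np.array([texture_shape_features(images[p])
                      for p in rows["frame_path"]])
        y = rows["label"].astype(int).to_numpy()
        clf = LogisticRegression(max_iter=5000, class_weight="balanced")
        clf.fit(X, y)
        assert clf.score(X, y) > 0.8
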