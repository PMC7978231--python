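"""Labelled-fraction selection, augmentation, and the alternating trainer."""

from dataclasses import replace

import numpy as np
import pytest

from jigsawssl.manifest import label_codes
from jigsawssl.model import DualHeadModel
from jigsawssl.trainer import (IMAGENET_MEAN, IMAGENET_STD, TrainConfig,
                               augment, augment_geometric, fit_core,
                               lambda_at_epoch, select_labeled_fraction, train,
                               train_domain_adaptation)


class NoOpRng:
    """Stub rng whose gate draws always exceed 0.5 (every transform skipped)."""

    def random(self):
        return 0.9

    def integers(self, lo, hi=None):
        return lo

    def uniform(self, a, b, size=None):
        return a if size is None else np.full(size, a)


class TestLambdaSchedule:
    def test_growth_schedule_exact_values(self):
        assert lambda_at_epoch(1.5, 0, True) == 1.5
        assert lambda_at_epoch(1.5, 4, True) == 1.5
        assert lambda_at_epoch(1.5, 5, True) == 2.25
        assert lambda_at_epoch(1.5, 9, True) == 2.25
        assert lambda_at_epoch(1.5, 10, True) == 3.375

    def test_growth_off_is_constant(self):
        assert all(lambda_at_epoch(2.0, e, False) == 2.0 for e in range(20))


class TestSelectLabeledFraction:
    def test_k_100_takes_all_remaining_videos(self, small_dataset):
        _, manifest, _ = small_dataset
        sel = select_labeled_fraction(manifest, 100.0, fold=1, seed=0)
        train_lab = manifest[(manifest["split"] == "train")
                             & manifest["label"].isin(["0", "1"])]
        assert set(sel.dk_videos) | set(sel.val_videos) == set(
            train_lab["video_id"].unique())

    def test_validation_identical_across_k(self, small_dataset):
        _, manifest, _ = small_dataset
        vals = [select_labeled_fraction(manifest, k, fold=2, seed=3).val_videos
                for k in (100.0, 50.0, 25.0, 12.5, 6.25)]
        assert all(v == vals[0] for v in vals)

    def test_selections_nested_across_k(self, small_dataset):
        _, manifest, _ = small_dataset
        prev = None
        for k in (6.25, 12.5, 25.0, 50.0, 100.0):
            sel = set(select_labeled_fraction(manifest, k, fold=1, seed=5).dk_videos)
            if prev is not None:
                assert prev <= sel
            prev = sel

    def test_no_video_in_both_dk_and_validation(self, small_dataset):
        _, manifest, _ = small_dataset
        sel = select_labeled_fraction(manifest, 50.0, fold=1, seed=0)
        assert not set(sel.dk_videos) & set(sel.val_videos)
        assert not set(sel.pool["video_id"]) & set(sel.val_videos)

    def test_both_classes_present_at_smallest_k(self, small_dataset):
        _, manifest, _ = small_dataset
        sel = select_labeled_fraction(manifest, 6.25, fold=1, seed=0)
        assert set(sel.dk["label"]) == {"0", "1"}

    def test_too_few_videos_rejected(self, small_dataset):
        _, manifest, _ = small_dataset
        wli_only = manifest[manifest["video_id"].isin(
            manifest["video_id"].unique()[:6])]
        with pytest.raises(ValueError):
            select_labeled_fraction(wli_only, 100.0, fold=1, seed=0)


class TestAugment:
    def test_noop_branch_only_normalizes(self):
        img = np.full((222, 222, 3), 0.5, dtype=np.float64)
        out = augment(img, NoOpRng())
        expected = (0.5 - IMAGENET_MEAN) / IMAGENET_STD
        assert out.shape == (3, 222, 222)
        for c in range(3):
            assert np.allclose(out[c], expected[c], atol=1e-6)

    def test_resizes_to_target_side(self, rng):
        img = rng.integers(0, 256, (300, 300, 3), dtype=np.uint8)
        out = augment(img, NoOpRng())
        assert out.shape == (3, 222, 222)

    def test_rot180_twice_is_identity(self, rng):
        img = rng.integers(0, 256, (222, 222, 3), dtype=np.uint8)
        once = np.rot90(img, k=2)
        twice = np.rot90(once, k=2)
        assert np.array_equal(twice, img)

    def test_geometric_is_deterministic_given_seed(self, rng):
        img = rng.integers(0, 256, (222, 222, 3), dtype=np.uint8)
        a = augment_geometric(img, np.random.default_rng(3))
        b = augment_geometric(img, np.random.default_rng(3))
        assert np.array_equal(a, b)


def _quick_config(**kw):
    base = dict(k_fraction=100.0, fold=1, epochs=2, seed=0, mode="ssl",
                P=4, s=0.5, batch_size=16, lr=1e-3)
    base.update(kw)
    return TrainConfig(**base)


class TestTraining:
    def test_identical_config_identical_trajectories(self, small_dataset):
        _, manifest, images = small_dataset
        cfg = _quick_config()
        h1 = train(manifest, cfg, images).history
        h2 = train(manifest, cfg, images).history
        assert h1.equals(h2)

    def test_jigsaw_head_learns_while_supervised_phase_never_touches_it(
            self, small_dataset):
        _, manifest, images = small_dataset
        cfg = _quick_config(epochs=1)
        init = DualHeadModel(backbone=cfg.backbone, P=cfg.P, seed=cfg.seed)
        init_jig = {k: v.copy() for k, v in init.params.items()
                    if k.startswith("jig/")}
        res = train(manifest, cfg, images)
        assert any(not np.array_equal(res.model.params[k], init_jig[k])
                   for k in init_jig)
        # with the unsupervised step disabled nothing may touch the jigsaw head
        res2 = train(manifest, replace(cfg, unsupervised_step=False), images)
        for k, v in init_jig.items():
            assert np.array_equal(res2.model.params[k], v)

    def test_loss_report_composition(self, small_dataset):
        _, manifest, images = small_dataset
        res = train(manifest, _quick_config(epochs=1, lambda0=2.0), images)
        row = res.history.iloc[0]
        assert row["L_total"] == pytest.approx(row["L_S"] + 2.0 * row["L_U"])
        assert row["L_S"] >= 0 and row["L_U"] >= 0

    def test_empty_pool_falls_back_to_labelled_frames(self, small_dataset, caplog):
        _, manifest, images = small_dataset
        cfg = _quick_config(epochs=1, batch_size=8)
        model = DualHeadModel(backbone=cfg.backbone, P=cfg.P, seed=0)
        labelled = manifest[manifest["label"].isin(["0", "1"])]
        rows = labelled.groupby("label").head(10)
        frames = [images[p] for p in rows["frame_path"]]
        import logging
        with caplog.at_level(logging.WARNING, logger="jigsawssl"):
            res = fit_core(model, frames, label_codes(rows), [], cfg)
        assert "empty" in caplog.text
        assert len(res.history) == 1


class TestDomainAdaptation:
    def test_no_target_frames_in_supervised_batches(self, small_dataset):
        _, manifest, images = small_dataset
        cfg = _quick_config(epochs=1, mode="domain_adaptation")
        res = train_domain_adaptation(manifest, cfg, images)
        assert res.target_in_supervised == 0
        assert set(res.selection.dk["domain"]) == {"WLI"}

    def test_unsupervised_pool_mixes_source_and_unlabeled_target(
            self, small_dataset):
        _, manifest, images = small_dataset
        cfg = _quick_config(epochs=1, mode="domain_adaptation")
        res = train_domain_adaptation(manifest, cfg, images)
        assert res.history["L_U"].iloc[0] > 0

    def test_missing_target_domain_rejected(self, small_dataset):
        _, manifest, images = small_dataset
        wli = manifest[manifest["domain"] == "WLI"]
        cfg = _quick_config(epochs=1, mode="domain_adaptation")
        with pytest.raises(ValueError):
            train_domain_adaptation(wli, cfg,
                                    {p: images[p] for p in wli["frame_path"]})
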