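"""Classifier plumbing: balancing, noise removal, reconstruction, heatmap."""

import itertools

import numpy as np
import pytest

from biopsyqc.classify import (CLASSES, MLPPatchModel, OrganModels,
                               PatchPrediction, ReconstructedSlide, TrainConfig,
                               balance_sample, build_reconstruction,
                               compose_heatmap, noise_removal_keep_indices,
                               normalize_reconstruction, predict_patches,
                               predict_slide, render_heatmap,
                               train_patch_classifier)
from biopsyqc.slide_io import ArraySlide
from biopsyqc.tiling import tile_slide


def toy_db(n_cols=4, n_rows=2, value=128):
    raster = ArraySlide(np.full((n_rows * 256, n_cols * 256, 3), value,
                                dtype=np.uint8), "toy")
    return raster, tile_slide(raster, 256)


class TestBalanceSample:
    def _pool(self, counts):
        patches = np.arange(sum(counts.values()))[:, None]
        labels = np.repeat(list(counts), list(counts.values()))
        return patches, labels

    def test_min_rule(self):
        patches, labels = self._pool({"M": 100, "D": 40, "N": 400})
        _, bl = balance_sample(patches, labels, seed=0)
        assert {c: int((bl == c).sum()) for c in "MDN"} == {"M": 40, "D": 40, "N": 40}

    def test_already_balanced_identity(self):
        patches, labels = self._pool({"M": 5, "D": 5, "N": 5})
        bp, bl = balance_sample(patches, labels, seed=1)
        assert len(bp) == 15
        assert sorted(bp.ravel().tolist()) == list(range(15))

    def test_seeded_determinism(self):
        patches, labels = self._pool({"M": 50, "D": 20, "N": 70})
        a, _ = balance_sample(patches, labels, seed=7)
        b, _ = balance_sample(patches, labels, seed=7)
        assert np.array_equal(a, b)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            balance_sample(np.zeros((4, 1)), ["M", "M", "D", "D"], seed=0)


class TestNoiseRemoval:
    def test_q_zero_keeps_everything(self):
        keep = noise_removal_keep_indices(np.random.default_rng(0).random(100), 0.0)
        assert len(keep) == 100

    def test_exact_drop_count(self):
        losses = np.random.default_rng(1).random(1000)
        keep = noise_removal_keep_indices(losses, 0.02)
        assert len(keep) == 980

    def test_drops_the_largest_losses(self):
        losses = np.arange(10.0)
        keep = noise_removal_keep_indices(losses, 0.1)
        assert 9 not in keep and len(keep) == 9

    def test_config_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(noise_removal_fraction=0.5)


@pytest.fixture(scope="module")
def tiny_model():
    from biopsyqc.synthetic import sample_patches

    patches, labels = sample_patches(30, seed=5)
    cfg = TrainConfig(seed=0, noise_removal_fraction=0.02, warmup_epochs=10)
    return train_patch_classifier(patches, labels, cfg)


class TestPatchModel:
    def test_probabilities_sum_to_one(self, tiny_model):
        from biopsyqc.synthetic import sample_patches

        patches, _ = sample_patches(5, seed=99)
        probs = tiny_model.predict_proba(patches)
        assert probs.shape == (15, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_noise_removal_shrinks_training_set(self, tiny_model):
        # 90 patches, q=0.02 -> floor(1.8) = 1 dropped
        assert tiny_model.train_size_ == 89

    def test_training_determinism(self):
        from biopsyqc.synthetic import sample_patches

        patches, labels = sample_patches(10, seed=3)
        cfg = TrainConfig(seed=4, noise_removal_fraction=0.0)
        probe, _ = sample_patches(3, seed=8)
        p1 = train_patch_classifier(patches, labels, cfg).predict_proba(probe)
        p2 = train_patch_classifier(patches, labels, cfg).predict_proba(probe)
        assert np.array_equal(p1, p2)


class TestArgmaxTieBreak:
    def test_tie_breaks_toward_severe_class(self):
        assert PatchPrediction(0, (0.4, 0.4, 0.2)).argmax_class == "M"
        assert PatchPrediction(0, (0.2, 0.4, 0.4)).argmax_class == "D"
        assert PatchPrediction(0, (1 / 3, 1 / 3, 1 / 3)).argmax_class == "M"


class TestReconstruction:
    def test_placement_identity(self):
        _, db = toy_db(2, 1)
        rs = build_reconstruction([PatchPrediction(0, (0.1, 0.2, 0.7))], db)
        assert rs.grid.shape == (1, 2, 3)
        assert np.allclose(rs.grid[0, 0], (0.1, 0.2, 0.7))
        assert np.allclose(rs.grid[0, 1], 0.0)

    def test_full_grid_no_zero_tissue_cells(self):
        _, db = toy_db(4, 2)
        preds = [PatchPrediction(i, (0.5, 0.25, 0.25)) for i in range(8)]
        rs = build_reconstruction(preds, db)
        assert rs.grid.shape == (2, 4, 3)
        assert (rs.grid.sum(axis=2) > 0).all()

    def test_order_invariance_exhaustive_3x3_subsets(self):
        _, db = toy_db(3, 3)
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(3), size=4)
        preds = [PatchPrediction(i, tuple(p)) for i, p in zip((0, 3, 4, 8), raw)]
        ref = build_reconstruction(preds, db).grid
        for perm in itertools.permutations(preds):
            assert np.array_equal(build_reconstruction(list(perm), db).grid, ref)

    def test_unknown_index_rejected(self):
        _, db = toy_db(2, 1)
        with pytest.raises(KeyError):
            build_reconstruction([PatchPrediction(99, (1.0, 0.0, 0.0))], db)

    def test_no_renormalization(self):
        # reconstruction must carry the vectors through bit-identically
        _, db = toy_db(2, 1)
        v = (0.123456789, 0.2, 0.676543211)
        rs = build_reconstruction([PatchPrediction(1, v)], db)
        assert tuple(rs.grid[0, 1]) == v


class TestNormalization:
    def test_small_grid_centered_in_target(self):
        grid = np.ones((2, 4, 3))
        out = normalize_reconstruction(grid, (64, 64))
        assert out.shape == (64, 64, 3)
        assert out.sum() == pytest.approx(grid.sum())
        assert (out[31:33, 30:34] == 1).all()
        out[31:33, 30:34] = 0
        assert (out == 0).all()

    def test_identity_at_target_size(self):
        grid = np.random.default_rng(2).random((64, 64, 3))
        assert np.array_equal(normalize_reconstruction(grid, (64, 64)), grid)

    def test_downscale_by_block_average(self):
        grid = np.random.default_rng(3).random((128, 128, 3))
        out = normalize_reconstruction(grid, (64, 64))
        assert out.shape == (64, 64, 3)
        assert np.allclose(out[0, 0], grid[:2, :2].mean(axis=(0, 1)))


class TestHeatmap:
    def test_all_n_is_fully_transparent(self):
        _, db = toy_db(4, 2)
        preds = [PatchPrediction(i, (0.1, 0.1, 0.8)) for i in range(8)]
        overlay = render_heatmap(preds, db, scale=0.125)
        assert overlay[..., 3].sum() == 0

    def test_single_m_patch_paints_one_red_rect(self):
        _, db = toy_db(4, 2)
        overlay = render_heatmap([PatchPrediction(0, (0.9, 0.05, 0.05))], db,
                                 scale=0.125, opacity=0.5)
        rect = round(256 * 0.125)
        assert overlay.shape == (2 * rect, 4 * rect, 4)
        red = (overlay[..., 0] == 255) & (overlay[..., 3] > 0)
        assert red[:rect, :rect].all()
        assert red.sum() == rect * rect

    def test_rect_extent_follows_scale(self):
        _, db = toy_db(2, 2)
        for scale in (0.0625, 0.25):
            overlay = render_heatmap([PatchPrediction(3, (0.1, 0.8, 0.1))], db,
                                     scale=scale)
            rect = round(256 * scale)
            assert (overlay[..., 3] > 0).sum() == rect * rect

    def test_mask_off_returns_plain_thumbnail(self):
        _, db = toy_db(2, 1)
        thumb = np.full((32, 64, 3), 200, dtype=np.uint8)
        overlay = render_heatmap([PatchPrediction(0, (0.9, 0.05, 0.05))], db,
                                 scale=0.125)
        off = compose_heatmap(thumb, overlay, mask_on=False)
        assert np.array_equal(off, thumb)
        on = compose_heatmap(thumb, overlay, mask_on=True)
        assert not np.array_equal(on, thumb)


class TestPredictSlide:
    def test_empty_slide_falls_back_to_n(self):
        raster = ArraySlide(np.full((512, 512, 3), 255, dtype=np.uint8), "blank")
        om = OrganModels(patch_model=None, slide_model=None, organ="gastric")
        pred, db = predict_slide({"gastric": om}, raster, "gastric")
        assert pred.final_class == "N"
        assert "no_tissue" in pred.flags

    def test_unknown_organ_rejected(self):
        raster = ArraySlide(np.full((512, 512, 3), 255, dtype=np.uint8), "b")
        with pytest.raises(KeyError):
            predict_slide({}, raster, "gastric")
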