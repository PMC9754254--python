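"""Synthetic generator: determinism, planted truth, corpus, splits, records."""

import numpy as np
import pandas as pd
import pytest

from biopsyqc.dx_rules import classify_dx
from biopsyqc.synthetic import (ArtifactParams, GroundTruth, SyntheticSpec,
                                emit_dx_record, emit_switched_pair,
                                generate_corpus, generate_slide,
                                labels_from_geometry, largest_remainder,
                                split_corpus)

SMALL = dict(width_px=768, height_px=768)


class TestGenerateSlide:
    def test_determinism_bytes(self):
        spec = SyntheticSpec(seed=5, slide_class="M", **SMALL)
        r1, g1 = generate_slide(spec)
        r2, g2 = generate_slide(spec)
        assert np.array_equal(r1.pixels, r2.pixels)
        assert (g1.label_grid == g2.label_grid).all()
        assert g1.diagnosis_text == g2.diagnosis_text

    def test_negative_slide_has_no_lesion(self):
        _, gt = generate_slide(SyntheticSpec(seed=1, slide_class="N", **SMALL))
        assert gt.lesion_polygons == []
        labels = set(gt.label_grid.ravel())
        assert labels <= {"N", "background"}
        assert "N" in labels

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.7])
    def test_lesion_fraction_near_target(self, target):
        _, gt = generate_slide(SyntheticSpec(seed=7, slide_class="M",
                                             lesion_fraction=target))
        assert gt.lesion_patch_fraction() == pytest.approx(target, abs=0.1)

    def test_labels_recomputed_from_polygons_match_grid(self):
        _, gt = generate_slide(SyntheticSpec(seed=9, slide_class="D",
                                             lesion_fraction=0.4))
        recomputed = labels_from_geometry(gt.tissue_geom, gt.lesion_polygons,
                                          "D", gt.width_px, gt.height_px,
                                          gt.patch_size)
        assert (recomputed == gt.label_grid).all()

    def test_lesion_polygons_lie_inside_tissue(self):
        _, gt = generate_slide(SyntheticSpec(seed=13, slide_class="M"))
        assert gt.lesion_polygons
        for poly in gt.lesion_polygons:
            assert poly.difference(gt.tissue_geom.buffer(1e-6)).area < 1e-3

    def test_grid_shape_matches_tiling(self):
        _, gt = generate_slide(SyntheticSpec(seed=2, width_px=1000,
                                             height_px=300, slide_class="N"))
        assert gt.label_grid.shape == (2, 4)  # ceil(300/256) x ceil(1000/256)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_slide(SyntheticSpec(seed=0, width_px=100, height_px=100))

    def test_diagnosis_text_classifies_to_dx_class(self):
        for cls in ("M", "D", "N"):
            _, gt = generate_slide(SyntheticSpec(seed=3, slide_class=cls, **SMALL))
            assert classify_dx(gt.diagnosis_text) == gt.dx_class == cls

    def test_artifacts_perturb_pixels_not_labels(self):
        clean = SyntheticSpec(seed=21, slide_class="M",
                              artifact_params=ArtifactParams(0, 0, 0, 0))
        heavy = SyntheticSpec(seed=21, slide_class="M",
                              artifact_params=ArtifactParams(0.5, 0.5, 0.5, 0.5))
        r_clean, g_clean = generate_slide(clean)
        r_heavy, g_heavy = generate_slide(heavy)
        assert (g_clean.label_grid == g_heavy.label_grid).all()
        assert not np.array_equal(r_clean.pixels, r_heavy.pixels)

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, gt = generate_slide(SyntheticSpec(seed=4, slide_class="D", **SMALL))
        gt.to_json(tmp_path / "gt.json")
        loaded = GroundTruth.from_json(tmp_path / "gt.json")
        assert (loaded.label_grid == gt.label_grid).all()
        assert loaded.diagnosis_text == gt.diagnosis_text
        assert len(loaded.lesion_polygons) == len(gt.lesion_polygons)
        assert loaded.tissue_geom.area == pytest.approx(gt.tissue_geom.area)


class TestLargestRemainder:
    def test_worked_example(self):
        assert largest_remainder(10, (0.2, 0.3, 0.5)) == [2, 3, 5]

    def test_sums_to_n(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(3))
            n = int(rng.integers(1, 200))
            assert sum(largest_remainder(n, p)) == n

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            largest_remainder(10, (0.5, 0.2))


@pytest.fixture(scope="module")
def manifest():
    # spec-only manifest (no slide rendering): corpus structure checks
    return generate_corpus(10, (0.2, 0.3, 0.5), seed=42, serial_rate=0.5)


class TestCorpus:
    def test_class_mix_largest_remainder(self, manifest):
        per_specimen = manifest.drop_duplicates("block_id")
        counts = per_specimen.slide_class.value_counts()
        assert counts["M"] == 2 and counts["D"] == 3 and counts["N"] == 5

    def test_serial_rate(self, manifest):
        sizes = manifest.groupby("block_id").size()
        assert (sizes >= 2).sum() == 5

    def test_manifest_determinism(self, manifest):
        again = generate_corpus(10, (0.2, 0.3, 0.5), seed=42, serial_rate=0.5)
        pd.testing.assert_frame_equal(manifest, again)

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            generate_corpus(0)

    def test_written_corpus_artifacts(self, tmp_path):
        man = generate_corpus(3, (1 / 3, 1 / 3, 1 / 3), seed=1,
                              out_dir=tmp_path, serial_rate=0.4,
                              width_px=768, height_px=768)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "records.jsonl").exists()
        for row in man.itertuples():
            assert (tmp_path / "slides" / f"{row.slide_id}.png").exists()
            gt = GroundTruth.from_json(tmp_path / "gt" / f"{row.slide_id}.json")
            assert gt.slide_class == row.slide_class

    def test_serial_slides_share_report_text(self, tmp_path):
        man = generate_corpus(2, (0, 1, 0), seed=3, out_dir=tmp_path,
                              serial_rate=1.0, width_px=768, height_px=768)
        grp = man.groupby("accession")
        for acc, rows in grp:
            gts = [GroundTruth.from_json(p) for p in
                   (tmp_path / "gt" / f"{sid}.json" for sid in rows.slide_id)]
            assert len({g.diagnosis_text for g in gts}) == 1


class TestSplit:
    def test_80_10_10_on_100_specimens(self):
        man = generate_corpus(100, seed=0, serial_rate=0.0)
        out = split_corpus(man, (0.8, 0.1, 0.1), seed=0)
        counts = out.groupby("split").block_id.nunique()
        assert counts["train"] == 80 and counts["val"] == 10 and counts["test"] == 10

    def test_serial_blocks_never_straddle(self):
        man = generate_corpus(40, seed=5, serial_rate=0.5)
        out = split_corpus(man, (0.8, 0.1, 0.1), seed=5)
        assert (out.groupby("block_id").split.nunique() == 1).all()

    def test_all_in_train(self):
        man = generate_corpus(7, seed=2)
        out = split_corpus(man, (1.0, 0.0, 0.0), seed=2)
        assert (out.split == "train").all()

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            split_corpus(pd.DataFrame(), (0.8, 0.1, 0.1), seed=0)


class TestDxRecordEmission:
    def _gt(self, cls, organ="colorectal", seed=11):
        _, gt = generate_slide(SyntheticSpec(seed=seed, slide_class=cls,
                                             organ=organ, **SMALL))
        return gt

    @pytest.mark.parametrize("cls", ["M", "D", "N"])
    def test_typical_matches_slide_class(self, cls):
        rec = emit_dx_record(self._gt(cls), "typical")
        assert rec.dx_class == cls

    @pytest.mark.parametrize("cls,expected", [("M", "M"), ("D", "D")])
    def test_ambiguous_still_classifies(self, cls, expected):
        rec = emit_dx_record(self._gt(cls), "ambiguous")
        assert rec.dx_class == expected
        assert "Atypical" in rec.diagnosis_text

    def test_entry_error_on_negative_slide(self):
        # the record reads as D while the image truth is N
        gt = self._gt("N")
        rec = emit_dx_record(gt, "entry_error")
        assert gt.slide_class == "N" and rec.dx_class == "D"
        assert len(rec.diagnosis_text.splitlines()) == 2

    def test_switched_pair(self):
        gt_d, gt_n = self._gt("D", seed=1), self._gt("N", seed=2)
        rec_a, rec_b = emit_switched_pair(gt_d, gt_n, "A1", "B1", "A2", "B2")
        # record attached to the D slide carries the N diagnosis and vice versa
        assert rec_a.dx_class == "N" and rec_b.dx_class == "D"

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError):
            emit_dx_record(self._gt("N"), "bogus")
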