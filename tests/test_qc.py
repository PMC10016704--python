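"""Tests of the data-cleaning cascade (blur, blast, manual filters)."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from scemila.qc import (BlastFilterConfig, ConsortReport, EdgeFilterConfig,
                        _SOBEL_8BIT_SCALE, apply_manual_exclusions, edge_sum,
                        filter_blurry, filter_low_blast, run_qc_cascade)
from scemila.synthetic import (SyntheticCohortSpec, SyntheticImageSpec,
                               generate_cell_images, generate_feature_bags,
                               write_cohort)


def _oracle_canny_edges(gray8, low=100.0, high=200.0, sigma=1.0):
    """Independent simplified Canny: Gaussian smoothing, Sobel gradients,
    quantized-direction non-maximum suppression, hysteresis by labeling."""
    g = ndimage.gaussian_filter(gray8 / 255.0, sigma)
    gx = ndimage.sobel(g, axis=1)
    gy = ndimage.sobel(g, axis=0)
    mag = np.hypot(gx, gy)
    ang = np.rad2deg(np.arctan2(gy, gx)) % 180
    nms = np.zeros_like(mag)
    h, w = mag.shape
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            a = ang[i, j]
            if a < 22.5 or a >= 157.5:
                n1, n2 = mag[i, j - 1], mag[i, j + 1]
            elif a < 67.5:
                n1, n2 = mag[i - 1, j + 1], mag[i + 1, j - 1]
            elif a < 112.5:
                n1, n2 = mag[i - 1, j], mag[i + 1, j]
            else:
                n1, n2 = mag[i - 1, j - 1], mag[i + 1, j + 1]
            if mag[i, j] >= n1 and mag[i, j] >= n2:
                nms[i, j] = mag[i, j]
    strong = nms >= high / _SOBEL_8BIT_SCALE
    weak = nms >= low / _SOBEL_8BIT_SCALE
    lbl, n = ndimage.label(weak, structure=np.ones((3, 3)))
    keep = np.zeros(n + 1, bool)
    keep[np.unique(lbl[strong])] = True
    keep[0] = False
    return keep[lbl]


class TestEdgeSum:
    def test_constant_image_is_zero(self):
        assert edge_sum(np.full((64, 64, 3), 77, np.uint8)) == 0.0

    def test_step_edge_matches_analytic_count(self):
        """An ideal vertical step yields exactly two tied edge columns
        spanning the non-border rows: sum = 255 * 2 * (H - 2)."""
        img = np.zeros((64, 64), np.uint8)
        img[:, 32:] = 255
        assert edge_sum(img) == 255 * 2 * 62

    def test_agrees_with_independent_canny_on_checkerboard(self):
        """A from-scratch Canny (different smoothing borders, quantized NMS)
        finds an edge count within 15% of the production path on a coarse
        checkerboard, and both rank blurred far below sharp."""
        tile = np.kron((np.indices((6, 6)).sum(0) % 2) * 255,
                       np.ones((24, 24))).astype(np.uint8)
        prod = edge_sum(tile)
        oracle = 255 * int(_oracle_canny_edges(tile.astype(float)).sum())
        assert abs(prod - oracle) / oracle < 0.15

    def test_blurred_cells_below_default_threshold(self):
        spec = SyntheticImageSpec(blur_fraction=1.0, seed=8)
        imgs, _ = generate_cell_images(spec, [0, 1, 2, 3, 4])
        for img in imgs:
            assert edge_sum(img) < 5e4

    def test_count_mode_is_sum_over_255(self):
        img = np.zeros((64, 64), np.uint8)
        img[:, 32:] = 255
        s = edge_sum(img, EdgeFilterConfig(mode="sum"))
        c = edge_sum(img, EdgeFilterConfig(mode="count"))
        assert s == 255 * c

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="small"):
            edge_sum(np.zeros((4, 4), np.uint8))


class TestFilterBlurry:
    def test_constructed_blur_count_excluded_exactly(self):
        """100 images with 17 blurred by construction -> exactly those 17
        excluded (verified index by index against the generator's flags)."""
        spec = SyntheticImageSpec(blur_fraction=0.17, seed=5)
        imgs, meta = generate_cell_images(spec, [0, 1, 2, 3, 4] * 20)
        kept, excluded = filter_blurry(imgs)
        assert len(excluded) == 17
        assert set(excluded["index"]) == set(np.nonzero(meta["blurred"].to_numpy())[0])
        assert len(kept) + len(excluded) == 100

    def test_zero_threshold_keeps_everything(self):
        spec = SyntheticImageSpec(blur_fraction=1.0, seed=5, image_size=48)
        imgs, _ = generate_cell_images(spec, [0, 1])
        kept, excluded = filter_blurry(imgs, EdgeFilterConfig(edge_sum_threshold=0.0))
        assert len(kept) == 2 and len(excluded) == 0

    def test_exactly_at_threshold_is_kept(self):
        """Exclusion uses strict '<': an image whose edge sum equals the
        threshold stays in."""
        img = np.zeros((64, 64), np.uint8)
        img[:, 32:] = 255
        value = edge_sum(img)
        kept, excluded = filter_blurry([img], EdgeFilterConfig(edge_sum_threshold=value))
        assert kept == [0] and len(excluded) == 0
        _, excluded2 = filter_blurry([img], EdgeFilterConfig(edge_sum_threshold=value + 1))
        assert len(excluded2) == 1

    def test_unreadable_image_counted_excluded(self, tmp_path):
        bad = tmp_path / "broken.tif"
        bad.write_bytes(b"not a tiff")
        kept, excluded = filter_blurry([str(bad)])
        assert kept == [] and excluded.iloc[0]["reason"] == "unreadable"


def _manifest(rows):
    return pd.DataFrame(rows)


class TestBlastFilter:
    def test_below_threshold_excluded(self):
        m = _manifest([{"patient_id": "p1", "label": "NPM1",
                        "pct_myeloblasts": 10.0, "pct_promyelocytes": 5.0,
                        "pct_myelocytes": 4.0}])
        kept, excluded = filter_low_blast(m)
        assert len(kept) == 0 and excluded.iloc[0]["value"] == 19.0

    def test_exactly_at_threshold_kept(self):
        m = _manifest([{"patient_id": "p1", "label": "NPM1",
                        "pct_myeloblasts": 10.0, "pct_promyelocytes": 6.0,
                        "pct_myelocytes": 4.0}])
        kept, _ = filter_low_blast(m)
        assert list(kept["patient_id"]) == ["p1"]

    def test_controls_exempt(self):
        m = _manifest([{"patient_id": "c1", "label": "control",
                        "pct_myeloblasts": 0.0, "pct_promyelocytes": 0.0,
                        "pct_myelocytes": 0.0}])
        kept, _ = filter_low_blast(m)
        assert list(kept["patient_id"]) == ["c1"]

    def test_missing_column_names_patient_and_column(self):
        m = _manifest([{"patient_id": "p9", "label": "NPM1",
                        "pct_myeloblasts": 30.0}])
        with pytest.raises(ValueError, match="pct_promyelocytes"):
            filter_low_blast(m)


class TestManualExclusions:
    def _m(self):
        return _manifest([{"patient_id": p, "label": "NPM1"} for p in "abcd"])

    def test_empty_list_is_identity(self):
        kept = apply_manual_exclusions(self._m(), [])
        assert len(kept) == 4

    def test_known_ids_removed(self):
        kept = apply_manual_exclusions(self._m(), ["a", "c"])
        assert list(kept["patient_id"]) == ["b", "d"]

    def test_unknown_id_warns_and_is_ignored(self):
        with pytest.warns(UserWarning, match="unknown"):
            kept = apply_manual_exclusions(self._m(), ["a", "zz"])
        assert list(kept["patient_id"]) == ["b", "c", "d"]


class TestCascade:
    @pytest.fixture(scope="class")
    def image_cohort(self, tmp_path_factory):
        """Six patients with images; patient 0 designated low-blast, and a
        known number of blurred images spread over the cohort."""
        out = tmp_path_factory.mktemp("cohort")
        spec = SyntheticCohortSpec(
            n_classes=3, bags_per_class=2, bag_size_range=(8, 10),
            feature_dim=8, planted_fraction=(0.3, 0.3, 0.0),
            class_names=("A", "B", "control"), seed=12)
        bags = generate_feature_bags(spec)
        ispec = SyntheticImageSpec(image_size=48, blur_fraction=0.25, seed=12)
        images = {}
        n_blur = 0
        for bag in bags:
            imgs, meta = generate_cell_images(
                SyntheticImageSpec(image_size=48, blur_fraction=0.25,
                                   seed=12 + bag.label), [bag.label] * bag.n_instances)
            images[bag.patient_id] = imgs
            n_blur += int(meta["blurred"].sum())
        write_cohort(bags, out, spec=spec, low_blast_ids=(bags[0].patient_id,),
                     images_by_patient=images)
        return out, bags, n_blur

    def test_counts_match_construction(self, image_cohort, tmp_path):
        out, bags, n_blur = image_cohort
        report, cleaned, kept_images = run_qc_cascade(
            out, manual_exclusions=[bags[1].patient_id], out_dir=tmp_path)
        blur_stage, blast_stage, manual_stage = report.stages
        assert blur_stage["n_excluded"] == n_blur
        assert blast_stage["patients_before"] - blast_stage["patients_after"] == 1
        assert manual_stage["patients_before"] - manual_stage["patients_after"] == 1
        assert len(cleaned) == len(bags) - 2
        data = json.loads((tmp_path / "consort_report.json").read_text())
        assert [s["stage"] for s in data["stages"]] == ["blur", "blast", "manual"]

    def test_counts_monotone_and_partition(self, image_cohort, tmp_path):
        out, bags, _ = image_cohort
        report, cleaned, kept = run_qc_cascade(out, out_dir=tmp_path)
        report.validate_monotone()
        blur = report.stages[0]
        assert blur["images_before"] - blur["images_after"] == blur["n_excluded"]
        blast = report.stages[1]
        assert blast["patients_before"] - blast["patients_after"] == blast["n_excluded"]

    def test_idempotent_on_clean_output(self, image_cohort, tmp_path_factory):
        """Re-running the cascade on its own output excludes nothing more."""
        out, bags, _ = image_cohort
        stage1 = tmp_path_factory.mktemp("stage1")
        report1, cleaned1, kept1 = run_qc_cascade(out, out_dir=stage1)
        # rebuild a cohort containing only the kept images/patients
        rebuilt = tmp_path_factory.mktemp("rebuilt")
        import shutil, os
        cleaned1.to_csv(rebuilt / "manifest.tsv", sep="\t", index=False)
        for pid, files in kept1.items():
            os.makedirs(rebuilt / pid, exist_ok=True)
            np.save(rebuilt / pid / "features.npy", np.zeros((1, 2), np.float32))
            for f in files:
                shutil.copy(out / pid / f, rebuilt / pid / f)
        report2, cleaned2, kept2 = run_qc_cascade(rebuilt)
        assert all(s["n_excluded"] == 0 for s in report2.stages)
        assert len(cleaned2) == len(cleaned1)
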