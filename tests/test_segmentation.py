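"""Threshold QC loop, nuclei counting, marker quantification, co-localization."""

import numpy as np
import pytest

from astroquant.errors import DegenerateImageError, UndefinedPercentageError
from astroquant.imaging import (
    colocalize,
    count_nuclei,
    pearson_cc,
    quantify_marker,
    threshold_with_qc,
)
from astroquant.simulate import generate_micrograph


class TestThresholdWithQC:
    def test_clean_image_passes_first_try(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=1))
        seg = threshold_with_qc(micro.channels["GFAP"])
        assert seg.qc_passed and not seg.fallback_applied
        assert seg.qc_pcc >= 0.8

    def test_strong_gradient_triggers_fallback(self, small_image_spec):
        micro, _ = generate_micrograph(
            small_image_spec(
                seed=2,
                illumination_gradient_amplitude=1.8,
                ambient_level=0.35,
            )
        )
        seg = threshold_with_qc(micro.channels["GFAP"], background_sigma=30)
        assert seg.fallback_applied

    def test_all_background_raises(self):
        with pytest.raises(DegenerateImageError):
            threshold_with_qc(np.zeros((64, 64)))

    def test_exclusion_mask_removed_from_mask(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=3))
        excl = np.zeros(micro.shape, dtype=bool)
        excl[:, :160] = True
        seg = threshold_with_qc(micro.channels["GFAP"], exclusion_mask=excl)
        assert not seg.mask[:, :160].any()

    def test_qc_passed_iff_pcc_at_least_08(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=4))
        seg = threshold_with_qc(micro.channels["GFAP"])
        assert seg.qc_passed == (seg.qc_pcc >= 0.8)


class TestCountNuclei:
    def test_recovers_true_count_and_centroids(self, small_image_spec):
        micro, truth = generate_micrograph(small_image_spec(seed=5))
        n, cents = count_nuclei(micro.channels["nuclei"])
        assert n == truth.spec.n_cells
        # each detected centroid sits within a few px of a true centre
        true = truth.cells[["row", "col"]].to_numpy()
        for r, c in cents:
            d = np.hypot(true[:, 0] - r, true[:, 1] - c).min()
            assert d < 5.0

    def test_full_exclusion_gives_zero(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=6))
        excl = np.ones(micro.shape, dtype=bool)
        n, cents = count_nuclei(micro.channels["nuclei"], exclusion_mask=excl)
        assert n == 0 and cents == []

    def test_touching_pair_split_or_counted_once(self):
        # two discs whose distance-transform peaks are separable -> split in two;
        # a fully merged blob (single peak) counts as one, per the declared rule
        yy, xx = np.mgrid[0:80, 0:80]
        img = np.zeros((80, 80))
        for cy, cx in ((40.0, 30.0), (40.0, 50.0)):
            rho2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img = np.maximum(img, np.where(rho2 <= 81, 1.0, 0.0))
        n, _ = count_nuclei(img)
        assert n == 2
        blob = np.where((yy - 40.0) ** 2 + (xx - 40.0) ** 2 <= 144, 1.0, 0.0)
        n1, _ = count_nuclei(blob)
        assert n1 == 1


class TestQuantifyMarker:
    def test_noiseless_recovery_is_exact(self, small_image_spec):
        spec = small_image_spec(seed=7)
        micro, truth = generate_micrograph(spec)
        _, cents = count_nuclei(micro.channels["nuclei"])
        seg = threshold_with_qc(micro.channels["GFAP"])
        q = quantify_marker(seg, cents, micro.pixel_size_um, marker="GFAP")
        ms = truth.marker_summary["GFAP"]
        assert q.n_positive_cells == ms["n_positive"]
        assert q.percent_positive_cells == pytest.approx(
            100.0 * ms["n_positive"] / spec.n_cells, abs=1e-12
        )
        assert q.percent_area == pytest.approx(ms["true_percent_area"], abs=1e-12)

    def test_per_cell_area_identity(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=8))
        _, cents = count_nuclei(micro.channels["nuclei"])
        seg = threshold_with_qc(micro.channels["GFAP"])
        q = quantify_marker(seg, cents, micro.pixel_size_um)
        if q.n_positive_cells:
            assert q.percent_area_per_avg_cell * q.n_positive_cells == pytest.approx(
                q.percent_area, rel=1e-9
            )

    def test_empty_marker_mask(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=9))
        seg = threshold_with_qc(micro.channels["GFAP"])
        seg.mask = np.zeros_like(seg.mask)
        q = quantify_marker(seg, [(10.0, 10.0)], 0.32)
        assert q.n_positive_cells == 0
        assert q.percent_area == 0.0
        assert q.percent_area_per_avg_cell == 0.0

    def test_whole_frame_mask_single_nucleus(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=10))
        seg = threshold_with_qc(micro.channels["GFAP"])
        seg.mask = np.ones_like(seg.mask)
        q = quantify_marker(seg, [(5.0, 5.0)], 0.32)
        assert q.percent_area == pytest.approx(100.0)
        assert q.n_positive_cells == 1

    def test_zero_nuclei_raises(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=11))
        seg = threshold_with_qc(micro.channels["GFAP"])
        with pytest.raises(UndefinedPercentageError):
            quantify_marker(seg, [], 0.32)


class TestColocalize:
    def test_channel_vs_itself(self, small_image_spec):
        micro, _ = generate_micrograph(small_image_spec(seed=12))
        a = micro.channels["GFAP"]
        res = colocalize(a, a)
        assert res.pcc == pytest.approx(1.0, abs=1e-12)

    def test_high_coexpression_gives_high_pcc(self, small_image_spec):
        spec = small_image_spec(
            seed=13,
            marker_positive_fractions={"GFAP": 0.5, "ALDH1L1": 0.5},
            coexpression_pcc_target=1.0,
        )
        micro, truth = generate_micrograph(spec)
        res = colocalize(micro.channels["GFAP"], micro.channels["ALDH1L1"])
        assert truth.realized_label_pcc == pytest.approx(1.0)
        assert res.pcc > 0.8

    def test_disjoint_cell_sets_anticorrelate(self, small_image_spec):
        spec = small_image_spec(
            seed=14,
            marker_positive_fractions={"GFAP": 0.5, "ALDH1L1": 0.5},
            coexpression_pcc_target=-1.0,
        )
        micro, truth = generate_micrograph(spec)
        # disjoint 50/50 label sets: phi = -p1*p2/sqrt(p1*q1*p2*q2), close to -1
        assert truth.realized_label_pcc < -0.8
        res = colocalize(micro.channels["GFAP"], micro.channels["ALDH1L1"])
        assert res.pcc <= 0.0
        # oracle: direct evaluation of the sum formula on the same pixels
        direct = pearson_cc(micro.channels["GFAP"], micro.channels["ALDH1L1"])
        assert res.pcc == pytest.approx(direct, abs=1e-12)

    def test_union_policy_uses_fewer_pixels(self, small_image_spec):
        spec = small_image_spec(
            seed=15, marker_positive_fractions={"GFAP": 0.5, "ALDH1L1": 0.4}
        )
        micro, _ = generate_micrograph(spec)
        a, b = micro.channels["GFAP"], micro.channels["ALDH1L1"]
        seg_a = threshold_with_qc(a)
        seg_b = threshold_with_qc(b)
        whole = colocalize(a, b, policy="all")
        union = colocalize(a, b, policy="union", masks=(seg_a.mask, seg_b.mask))
        assert union.n_pixels < whole.n_pixels
        assert union.mask_policy == "union"
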