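import numpy as np
import pytest
from skimage.draw import ellipse
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from valvephenoquant import ifquant as iq
from valvephenoquant import synthetic as syn
from valvephenoquant.roi import LeafletROI


@pytest.fixture()
def full_roi():
    return LeafletROI.rectangle(1, 1, 62, 62)


class TestFcm:
    def test_bimodal_partition_matches_otsu_oracle(self, full_roi):
        """On two well-separated modes, fuzzy c-means assigns the bright
        mode exactly like an Otsu threshold does."""
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.3, 10000.0, 100.0)
        img += rng.normal(0, 20, img.shape)
        fg = iq.fcm_foreground(img, full_roi)
        roi_mask = full_roi.mask(img.shape)
        otsu_fg = (img > threshold_otsu(img[roi_mask])) & roi_mask
        assert np.array_equal(fg, otsu_fg)

    def test_constant_image_rejected(self, full_roi):
        with pytest.raises(ValueError):
            iq.fcm_foreground(np.full((64, 64), 7.0), full_roi)

    def test_single_ellipse_area_recovered(self):
        gt = syn.FluorescenceGroundTruth(
            n_nuclei=1, n_touching_pairs=0, noise_sd=50.0, seed=4
        )
        sample = syn.simulate_fluorescence(gt)
        fg = iq.fcm_foreground(sample.dapi, sample.roi)
        truth_area = (sample.truth_labels > 0).sum()
        assert fg.sum() == pytest.approx(truth_area, rel=0.10)


class TestWatershed:
    def test_two_overlapping_circles_split(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = ellipse(32, 22, 10, 10)
        mask[rr, cc] = True
        rr, cc = ellipse(32, 40, 10, 10)  # centers 18 apart: overlap ~20% of r
        mask[rr, cc] = True
        labels = iq.watershed_split(mask)
        assert labels.max() == 2

    def test_single_ellipse_stays_whole(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = ellipse(32, 32, 12, 7)
        mask[rr, cc] = True
        assert iq.watershed_split(mask).max() == 1

    def test_empty_mask_gives_zero_labels(self):
        assert iq.watershed_split(np.zeros((32, 32), dtype=bool)).max() == 0

    def test_small_objects_removed(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5:8, 5:8] = True  # 9 px < default min area 25
        assert iq.watershed_split(mask).max() == 0


class TestConcaveSplit:
    @pytest.fixture()
    def figure_eight(self):
        mask = np.zeros((60, 80), dtype=bool)
        rr, cc = ellipse(30, 30, 10, 7)
        mask[rr, cc] = True
        rr, cc = ellipse(30, 41, 10, 7)
        mask[rr, cc] = True
        return cc_label(mask, connectivity=1).astype(np.int32)

    def test_figure_eight_is_cut_in_two(self, figure_eight):
        assert figure_eight.max() == 1  # watershed would have seen one blob
        assert iq.concave_split(figure_eight).max() == 2

    def test_convex_object_unchanged(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = ellipse(20, 20, 12, 8)
        mask[rr, cc] = True
        labels = cc_label(mask).astype(np.int32)
        assert np.array_equal(iq.concave_split(labels), labels)

    def test_min_area_guard_blocks_tiny_cuts(self, figure_eight):
        # each lobe is ~200 px; demanding 300 px parts vetoes the cut
        out = iq.concave_split(figure_eight, min_area=300)
        assert out.max() == 1

    def test_idempotent_after_allowed_passes(self, figure_eight):
        once = iq.concave_split(figure_eight)
        twice = iq.concave_split(once)
        assert np.array_equal(once > 0, twice > 0)
        assert twice.max() == once.max()


class TestMedianThreshold:
    def test_median_and_positive_count(self):
        # intensities {1..100}: median 50.5, exactly 50 strict exceedances
        ten = np.arange(1.0, 101.0).reshape(10, 10)
        roi10 = LeafletROI.rectangle(0, 0, 9, 9)
        thr = iq.marker_threshold(ten, roi10)
        assert thr == 50.5
        assert int(iq.positive_mask(ten, thr).sum()) == 50

    def test_constant_roi_has_no_positives(self):
        img = np.full((10, 10), 42.0)
        roi = LeafletROI.rectangle(0, 0, 9, 9)
        thr = iq.marker_threshold(img, roi)
        assert iq.positive_mask(img, thr).sum() == 0

    def test_invariance_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(1)
        img = rng.random((48, 48)) * 1000
        roi = LeafletROI.rectangle(2, 2, 45, 45)
        mask_before = iq.positive_mask(img, iq.marker_threshold(img, roi))
        warped = np.exp(img / 300.0) + 5.0  # strictly increasing map
        mask_after = iq.positive_mask(warped, iq.marker_threshold(warped, roi))
        assert np.array_equal(mask_before, mask_after)


class TestAsmaFraction:
    def test_planted_diffuse_fraction_recovered(self):
        gt = syn.FluorescenceGroundTruth(
            n_nuclei=30, n_touching_pairs=0, diffuse_marker_fraction=0.4,
            noise_sd=0.0, seed=2,
        )
        sample = syn.simulate_fluorescence(gt)
        assert iq.asma_area_fraction(sample.marker, sample.roi) == pytest.approx(0.4, abs=0.05)

    def test_continuous_noise_image_pins_at_half(self):
        rng = np.random.default_rng(3)
        img = rng.random((64, 64))
        roi = LeafletROI.rectangle(1, 1, 62, 62)
        assert iq.asma_area_fraction(img, roi) == pytest.approx(0.5, abs=0.01)

    def test_flat_image_has_zero_fraction(self):
        img = np.full((32, 32), 9.0)
        roi = LeafletROI.rectangle(1, 1, 30, 30)
        assert iq.asma_area_fraction(img, roi) == 0.0


class TestRunx2Positivity:
    def _two_nuclei(self, cov_a, cov_b):
        labels = np.zeros((20, 30), dtype=np.int32)
        labels[5:15, 2:12] = 1  # 100 px
        labels[5:15, 16:26] = 2  # 100 px
        marker = np.zeros((20, 30))
        marker[5:15, 2:12].flat[: int(cov_a * 100)] = 100.0
        marker[5:15, 16:26].flat[: int(cov_b * 100)] = 100.0
        return labels, marker

    def test_majority_coverage_rule(self):
        labels, marker = self._two_nuclei(0.6, 0.4)
        quant = iq.runx2_positivity(labels, marker, threshold=50.0)
        assert quant.runx2_positive_fraction == 0.5
        assert quant.n_nuclei == 2

    def test_exact_half_coverage_is_negative(self):
        labels, marker = self._two_nuclei(0.5, 0.5)
        quant = iq.runx2_positivity(labels, marker, threshold=50.0)
        assert quant.runx2_positive_fraction == 0.0

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValueError):
            iq.runx2_positivity(np.zeros((10, 10), dtype=np.int32), np.zeros((10, 10)), 1.0)


class TestLabelInvariants:
    def test_labels_partition_foreground(self, nuclei_field):
        _, sample = nuclei_field
        fg = iq.fcm_foreground(sample.dapi, sample.roi)
        labels = iq.watershed_split(fg)
        # every labeled pixel is foreground; labels are disjoint by array def
        assert np.all(fg[labels > 0])
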