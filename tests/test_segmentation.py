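"""Active-contour ROI and fuzzy c-means: exactness, recovery, invariants."""

import numpy as np
import pytest

import semmorph as sm
from semmorph.segmentation import DegenerateFeatureError, EmptyROIError


class TestActiveContour:
    def test_two_valued_disc_partitioned_exactly(self, disc_image):
        image, mask = disc_image
        roi = sm.active_contour_roi(image, smoothing=0, max_iter=50)
        assert np.array_equal(roi.mask, mask)
        assert not roi.degenerate_contrast

    def test_noisy_body_dice_above_095(self):
        body = sm.Body(center=(100, 100), outer_diameter_nm=6000, contrast=0.5)
        image, truth = sm.generate_scene(
            [body], sm.NoiseModel(gaussian_sigma=0.05), (200, 200), 50.0, seed=3
        )
        den = sm.wavelet_denoise(image)
        roi = sm.active_contour_roi(den)
        t = truth.records[0].mask
        dice = 2 * (roi.mask & t).sum() / (roi.mask.sum() + t.sum())
        assert dice >= 0.95

    def test_constant_image_returns_init_with_warning(self):
        image = sm.CalibratedImage(np.full((40, 40), 0.5), 10.0)
        init = sm.ROI(np.zeros((40, 40), bool) | (np.arange(40)[:, None] < 20))
        roi = sm.active_contour_roi(image, init=init)
        assert roi.degenerate_contrast
        assert np.array_equal(roi.mask, init.mask)


class TestFuzzyCMeans:
    def test_two_constant_regions_crisp_memberships_and_centers(self):
        px = np.full((40, 40), 0.2)
        px[:, 20:] = 0.8
        image = sm.CalibratedImage(px, 10.0)
        lab = sm.fuzzy_cluster_segment(image, sm.ROI.full(image.shape), 2)
        assert lab.memberships.max(axis=1).min() >= 0.99
        assert np.allclose(lab.class_centers.ravel(), [0.2, 0.8], atol=1e-3)

    def test_three_gaussian_mixture_center_recovery(self):
        rng = np.random.default_rng(11)
        means = [0.2, 0.5, 0.8]
        vals = np.concatenate([rng.normal(m, 0.03, 1200) for m in means])
        px = np.clip(vals, 0, 1).reshape(60, 60)
        image = sm.CalibratedImage(px, 10.0)
        lab = sm.fuzzy_cluster_segment(image, sm.ROI.full(image.shape), 3,
                                       fuzziness=2.0, tol=1e-7, max_iter=500)
        assert np.abs(lab.class_centers.ravel() - means).max() <= 0.02

    def test_constant_image_degenerate_for_two_classes(self):
        image = sm.CalibratedImage(np.full((20, 20), 0.5), 10.0)
        with pytest.raises(DegenerateFeatureError):
            sm.fuzzy_cluster_segment(image, sm.ROI.full(image.shape), 2)

    def test_empty_roi_rejected(self):
        image = sm.CalibratedImage(np.linspace(0, 1, 400).reshape(20, 20), 10.0)
        with pytest.raises(EmptyROIError):
            sm.fuzzy_cluster_segment(image, sm.ROI(np.zeros((20, 20), bool)), 2)

    def test_memberships_normalized_and_objective_monotone(self):
        rng = np.random.default_rng(12)
        px = np.clip(rng.normal(0.5, 0.2, (50, 50)), 0, 1)
        image = sm.CalibratedImage(px, 10.0)
        lab = sm.fuzzy_cluster_segment(image, sm.ROI.full(image.shape), 3)
        sums = lab.memberships.sum(axis=1)
        assert np.abs(sums - 1).max() <= 1e-6
        trace = lab.objective_trace
        assert all(a >= b - 1e-10 for a, b in zip(trace, trace[1:]))

    def test_classes_sorted_by_center_intensity(self):
        rng = np.random.default_rng(13)
        px = np.clip(rng.uniform(0, 1, (30, 30)), 0, 1)
        image = sm.CalibratedImage(px, 10.0)
        lab = sm.fuzzy_cluster_segment(image, sm.ROI.full(image.shape), 4)
        centers = lab.class_centers[:, 0]
        assert (np.diff(centers) >= 0).all()

    def test_small_image_hard_labels_match_exhaustive_threshold_oracle(self):
        """On <= 64-pixel images with K=2, FCM's hard labels must agree
        with exhaustive two-threshold search minimizing the same
        membership-weighted objective."""
        rng = np.random.default_rng(21)
        m = 2.0
        for _ in range(5):
            vals = np.clip(np.concatenate([rng.normal(0.3, 0.05, 30),
                                           rng.normal(0.7, 0.05, 34)]), 0, 1)
            image = sm.CalibratedImage(vals.reshape(8, 8), 10.0)
            lab = sm.fuzzy_cluster_segment(image, sm.ROI.full((8, 8)), 2,
                                           tol=1e-9, max_iter=1000)
            hard = lab.hard_labels.ravel()
            best, best_j = None, np.inf
            for cut in np.sort(np.unique(vals))[:-1]:
                lo, hi = vals[vals <= cut], vals[vals > cut]
                centers = np.array([lo.mean(), hi.mean()])
                d2 = np.maximum((vals[:, None] - centers[None, :]) ** 2, 1e-24)
                u = (1 / d2) / (1 / d2).sum(axis=1, keepdims=True)
                j = (u**m * d2).sum()
                if j < best_j:
                    best_j, best = j, (vals > cut).astype(int)
            assert (hard == best).all() or (hard == 1 - best).all()


class TestProgressiveRefine:
    def _labeling(self, seed=31):
        rng = np.random.default_rng(seed)
        px = np.clip(np.concatenate([rng.normal(0.35, 0.08, 800),
                                     rng.normal(0.65, 0.08, 800)]), 0, 1)
        image = sm.CalibratedImage(px.reshape(40, 40), 10.0)
        lab = sm.fuzzy_cluster_segment(image, sm.ROI.full((40, 40)), 2)
        return image, lab

    def test_unambiguous_labeling_is_fixed_point(self):
        px = np.full((20, 20), 0.2)
        px[:, 10:] = 0.8
        image = sm.CalibratedImage(px, 10.0)
        lab = sm.fuzzy_cluster_segment(image, sm.ROI.full((20, 20)), 2)
        out = sm.progressive_refine(lab, image, ambiguity_threshold=0.9)
        assert np.array_equal(out.memberships, lab.memberships)
        assert np.array_equal(out.hard_labels, lab.hard_labels)

    def test_zero_rounds_returns_input(self):
        image, lab = self._labeling()
        out = sm.progressive_refine(lab, image, ambiguity_threshold=0.99,
                                    max_rounds=0)
        assert np.array_equal(out.memberships, lab.memberships)

    def test_refinement_preserves_normalization_and_does_not_worsen(self):
        # two spatially contiguous strata (rows 0-19 low, rows 20-39 high);
        # misassignments are isolated noisy pixels that context resolves
        image, lab = self._labeling()
        truth = np.zeros((40, 40), dtype=int)
        truth[20:] = 1
        out = sm.progressive_refine(lab, image, ambiguity_threshold=0.9,
                                    max_rounds=2)
        assert np.abs(out.memberships.sum(axis=1) - 1).max() <= 1e-6
        before = (lab.hard_labels != truth).sum()
        after = (out.hard_labels != truth).sum()
        assert after <= before


def test_permutation_equivalence_of_class_order():
    """Relabeling feature order must not change the partition geometry:
    centers come back sorted, memberships aligned to them."""
    rng = np.random.default_rng(41)
    px = np.clip(np.concatenate([rng.normal(0.25, 0.04, 450),
                                 rng.normal(0.75, 0.04, 450)]), 0, 1)
    image = sm.CalibratedImage(px.reshape(30, 30), 10.0)
    flipped = sm.CalibratedImage(1.0 - image.pixels, 10.0)
    a = sm.fuzzy_cluster_segment(image, sm.ROI.full((30, 30)), 2)
    b = sm.fuzzy_cluster_segment(flipped, sm.ROI.full((30, 30)), 2)
    assert np.allclose(np.sort(a.class_centers.ravel()),
                       np.sort(1.0 - b.class_centers.ravel()), atol=1e-6)
    assert np.array_equal(a.hard_labels, 1 - b.hard_labels)
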