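"""Overlap fractions, shuffle nulls, threshold sweeps, and patch counting."""

import numpy as np
import pytest

from columnscope import glm
from columnscope import interdigitation as inter
from columnscope import synthetic as syn


def _disc_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


@pytest.fixture(scope="module")
def full_roi():
    return np.ones((32, 32), bool)


class TestOverlapFraction:
    def test_identical_masks_return_their_density(self, full_roi):
        mask = np.zeros_like(full_roi)
        mask[:8, :] = True  # 25% of the ROI
        m = inter.BinaryMask(mask, full_roi)
        assert inter.overlap_fraction(m, m) == pytest.approx(25.0)

    def test_disjoint_masks_give_zero(self, full_roi):
        m1 = inter.BinaryMask(_disc_mask(full_roi.shape, 8, 8, 4), full_roi)
        m2 = inter.BinaryMask(_disc_mask(full_roi.shape, 24, 24, 4), full_roi)
        assert inter.overlap_fraction(m1, m2) == 0.0

    def test_symmetry(self, full_roi, rng):
        m1 = inter.BinaryMask(rng.random(full_roi.shape) < 0.3, full_roi)
        m2 = inter.BinaryMask(rng.random(full_roi.shape) < 0.4, full_roi)
        assert inter.overlap_fraction(m1, m2) == inter.overlap_fraction(m2, m1)

    def test_independent_masks_overlap_near_product(self, full_roi):
        # E[overlap%] = 100 p1 p2 for independent Bernoulli masks
        rng = np.random.default_rng(1)
        p1, p2 = 0.3, 0.4
        vals = [inter.overlap_fraction(
            inter.BinaryMask(rng.random(full_roi.shape) < p1, full_roi),
            inter.BinaryMask(rng.random(full_roi.shape) < p2, full_roi))
            for _ in range(200)]
        assert np.mean(vals) == pytest.approx(100 * p1 * p2, rel=0.05)

    def test_mismatched_roi_rejected(self, full_roi):
        other_roi = full_roi.copy()
        other_roi[0, 0] = False
        m1 = inter.BinaryMask(np.zeros_like(full_roi), full_roi)
        m2 = inter.BinaryMask(np.zeros_like(full_roi), other_roi)
        with pytest.raises(ValueError):
            inter.overlap_fraction(m1, m2)

    def test_mask_outside_roi_rejected(self, full_roi):
        roi = full_roi.copy()
        roi[0, 0] = False
        mask = np.zeros_like(full_roi)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            inter.BinaryMask(mask, roi)


class TestShuffledNull:
    def test_shifts_preserve_mask_area(self, full_roi, rng):
        mask = rng.random(full_roi.shape) < 0.2
        for dy, dx in [(0, 5), (7, 3), (31, 31)]:
            shifted = inter._roll_within_roi(mask, full_roi, dy, dx)
            assert shifted.sum() == mask.sum()

    def test_uniform_mask_gives_degenerate_null(self, full_roi, rng):
        m1 = inter.BinaryMask(rng.random(full_roi.shape) < 0.3, full_roi)
        m2 = inter.BinaryMask(full_roi.copy(), full_roi)
        res = inter.shuffled_null(m1, m2, 50, seed=0)
        np.testing.assert_allclose(res.null, res.aligned_overlap)

    def test_planted_interdigitated_masks_fall_below_null(self):
        sheet = syn.make_sheet(96, 96, 0.5)
        labels = syn.plant_columns(sheet, {"PA": 1.2, "PW": 1.2},
                                   (1.6, 2.2), min_gap_mm=0.3, seed=3)
        roi = np.ones(labels.shape, bool)
        m1 = inter.BinaryMask(labels.mask("PA"), roi)
        m2 = inter.BinaryMask(labels.mask("PW"), roi)
        res = inter.shuffled_null(m1, m2, 1000, seed=5)
        assert res.aligned_overlap < res.null_percentile(2.5)
        assert res.p_lower < 0.025

    def test_pvalues_superuniform_for_independent_masks(self, full_roi):
        # permutation p under a true null: P(p <= a) should be ~ a
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(40):
            m1 = inter.BinaryMask(rng.random(full_roi.shape) < 0.3, full_roi)
            m2 = inter.BinaryMask(rng.random(full_roi.shape) < 0.3, full_roi)
            res = inter.shuffled_null(m1, m2, 99, mode="permute",
                                      seed=int(rng.integers(2**31)))
            pvals.append(res.p_upper)
        assert np.mean(np.asarray(pvals) <= 0.1) < 0.25

    def test_permute_mode_preserves_area_too(self, full_roi, rng):
        m1 = inter.BinaryMask(rng.random(full_roi.shape) < 0.25, full_roi)
        m2 = inter.BinaryMask(rng.random(full_roi.shape) < 0.25, full_roi)
        res = inter.shuffled_null(m1, m2, 20, mode="permute", seed=1)
        assert res.n_shuffles == 20 and len(res.null) == 20


class TestOverlapCurve:
    @pytest.fixture(scope="class")
    def signed_map(self):
        labels = syn.plant_columns(syn.make_sheet(48, 48, 0.5),
                                   {"PA": 0.8, "PW": 0.8}, seed=9)
        events, n_tp = syn.block_design(seed=9)
        amps = {"approach": {"PA": 2.0, "PW": 0.5},
                "withdrawal": {"PA": 0.5, "PW": 2.0}}
        run = syn.simulate_bold_run(labels, events, n_tp, amps, noise_sd=1.0,
                                    seed=9)
        design = glm.build_design_matrix(run.events, n_tp, run.tr)
        fit = glm.fit_glm(run.series, design)
        cmap = glm.contrast_map(fit, design.condition_contrast(
            "approach", "withdrawal"))
        return labels, cmap

    def test_self_overlap_equals_selectivity_fraction(self, signed_map):
        _, cmap = signed_map
        curve = inter.overlap_curve(cmap, cmap, (1.3, 2.0, 3.0),
                                    n_shuffles=10, seed=0)
        roi_n = cmap.signed_logp.size
        for _, row in curve.iterrows():
            expected = 100.0 * (cmap.signed_logp >= row["threshold"]).sum() / roi_n
            assert row["aligned"] == pytest.approx(expected)

    def test_mask_sizes_shrink_with_threshold(self, signed_map):
        _, cmap = signed_map
        curve = inter.overlap_curve(cmap, cmap, (1.3, 2.0, 4.0, 8.0),
                                    n_shuffles=5, seed=0)
        assert (np.diff(curve["area1"]) <= 0).all()

    def test_empty_masks_flagged_as_zero_overlap(self, signed_map):
        _, cmap = signed_map
        curve = inter.overlap_curve(cmap, cmap, (200.0,), n_shuffles=5,
                                    seed=0)
        assert curve.iloc[0]["empty"] and curve.iloc[0]["aligned"] == 0.0


class TestPatchesAndConjunction:
    def test_two_blobs_counted(self):
        mask = (_disc_mask((32, 32), 8, 8, 3)
                | _disc_mask((32, 32), 24, 24, 3))
        assert inter.count_patches(mask, min_size=5) == 2

    def test_empty_mask_counts_zero(self):
        assert inter.count_patches(np.zeros((16, 16), bool)) == 0

    def test_min_size_filters_specks(self):
        mask = _disc_mask((32, 32), 8, 8, 3).copy()
        mask[0, 0] = True  # single-vertex speck
        assert inter.count_patches(mask, min_size=5) == 1
        assert inter.count_patches(mask, min_size=1) == 2

    def test_planted_columns_recovered_noiselessly(self, small_sheet):
        labels = syn.plant_columns(small_sheet, {"PA": 0.8, "PW": 0.5},
                                   seed=4)
        k = (labels.centers["label"] == "PA").sum()
        vol = syn.render_volume(labels, small_sheet, {"PA": 1.0})
        mask = vol.data[:, :, 5] > 0.5
        assert inter.count_patches(mask, min_size=1) == k

    def test_conjunction_labels_exclusive_and_overlap(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[2:5, 2:5] = 3.0  # signed -log10 p above threshold
        b[4:7, 4:7] = 3.0
        cm_a = glm.ContrastMap(beta=a, t=a, p=10.0**-a, signed_logp=a)
        cm_b = glm.ContrastMap(beta=b, t=b, p=10.0**-b, signed_logp=b)
        cat, legend = inter.conjunction_map({"A": cm_a, "B": cm_b}, 1.3)
        assert cat[2, 2] == 1 and legend[1] == "A"
        assert cat[6, 6] == 2 and legend[2] == "B"
        assert cat[4, 4] == -1 and legend[-1] == "overlap"
        assert cat[0, 0] == 0
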