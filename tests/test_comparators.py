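"""Threshold comparator methods: 2SD-from-remote, FWHM, Otsu."""

import numpy as np
import pytest

from segmentmar import (
    Artifact,
    PhantomSpec,
    ShortAxisStack,
    compute_sector_grid,
    generate_phantom,
    load_extent_model,
    mar_percent_lvm,
    remote_mask,
    threshold_2sd,
    threshold_fwhm,
    threshold_otsu,
)
from segmentmar.comparators import otsu_threshold_from_histogram


def simple_stack(myo_values, remote_sel):
    """Single-slice stack from a 1-D intensity list laid on a strip; the
    remote mask selects the listed positions."""
    n = len(myo_values)
    image = np.zeros((1, 1, n))
    image[0, 0, :] = myo_values
    myo = np.ones((1, 1, n), bool)
    remote = np.zeros((1, 1, n), bool)
    remote[0, 0, remote_sel] = True
    return ShortAxisStack(image=image, myo_mask=myo), remote


class Test2SD:
    def test_zero_variance_remote_threshold_equals_remote_value(self):
        stack, remote = simple_stack([10.0, 10.0, 10.0, 50.0, 5.0], [0, 1, 2])
        res = threshold_2sd(stack, remote)
        assert res.per_slice_threshold[0] == pytest.approx(10.0)
        assert res.pixel_mask[0, 0].tolist() == [True, True, True, True, False]

    def test_mean_plus_two_sd_formula(self):
        stack, remote = simple_stack([8.0, 12.0, 100.0, 13.0], [0, 1])
        res = threshold_2sd(stack, remote)        # mean 10, SD 2 -> 14
        assert res.per_slice_threshold[0] == pytest.approx(14.0)
        assert res.pixel_mask[0, 0].tolist() == [False, False, True, False]

    def test_empty_remote_slice_excluded(self, default_truth, default_grid,
                                         lad_model):
        rem = remote_mask(default_truth.stack, default_grid, lad_model)
        res = threshold_2sd(default_truth.stack, rem)
        assert np.isnan(res.per_slice_threshold[8])   # apex ring fully in LAD
        assert not res.pixel_mask[8].any()

    def test_underestimates_large_mar(self):
        biases = []
        for seed in range(5):
            truth = generate_phantom(PhantomSpec(
                seed=seed, wedge_center_sector=16.0,
                wedge_width_base=10.0, wedge_width_apex=10.0))
            grid = compute_sector_grid(truth.stack, truth.orient)
            rem = remote_mask(truth.stack, grid, load_extent_model("LAD"))
            res = threshold_2sd(truth.stack, rem)
            biases.append(mar_percent_lvm(res.pixel_mask, truth.stack.myo_mask)
                          - truth.truth_percent_lvm)
        assert np.median(biases) < 0


class TestFWHM:
    def test_midway_between_remote_mean_and_myocardial_max(self):
        stack, remote = simple_stack([10.0, 10.0, 30.0, 25.0], [0, 1])
        res = threshold_fwhm(stack, remote)
        assert res.per_slice_threshold[0] == pytest.approx(20.0)
        assert res.pixel_mask[0, 0].tolist() == [False, False, True, True]

    def test_degenerate_midpoint_when_remote_mean_equals_max(self):
        stack, remote = simple_stack([10.0, 10.0, 10.0], [0, 1, 2])
        res = threshold_fwhm(stack, remote)
        assert res.per_slice_threshold[0] == pytest.approx(10.0)

    def test_bright_artifact_pulls_threshold_to_the_artifact(self):
        values = [10.0] * 50 + [100.0] * 50 + [1000.0]
        stack, remote = simple_stack(values, list(range(50)))
        res = threshold_fwhm(stack, remote)
        assert res.per_slice_threshold[0] == pytest.approx(505.0)
        assert res.pixel_mask.sum() == 1   # only the artifact survives


class TestOtsu:
    def test_two_equal_spikes_split_between_them(self):
        values = [50.0] * 40 + [100.0] * 40
        stack, _ = simple_stack(values, [0])
        res = threshold_otsu(stack)
        thr = res.per_slice_threshold[0]
        assert 50.0 < thr <= 100.0
        assert res.pixel_mask.sum() == 40
        assert (stack.image[0, 0][res.pixel_mask[0, 0]] == 100.0).all()

    def test_matches_exhaustive_within_class_variance_search(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            nbins = 64
            hist = rng.integers(0, 50, nbins).astype(float)
            if np.count_nonzero(hist) < 2:
                hist[:2] += 1
            edges = np.linspace(0.0, 1.0, nbins + 1)
            split, thr = otsu_threshold_from_histogram(hist, edges)
            centers = (edges[:-1] + edges[1:]) / 2
            best, best_k = np.inf, None
            for k in range(1, nbins):
                w0, w1 = hist[:k].sum(), hist[k:].sum()
                if w0 == 0 or w1 == 0:
                    continue
                m0 = (hist[:k] * centers[:k]).sum() / w0
                m1 = (hist[k:] * centers[k:]).sum() / w1
                v0 = (hist[:k] * (centers[:k] - m0) ** 2).sum()
                v1 = (hist[k:] * (centers[k:] - m1) ** 2).sum()
                within = v0 + v1
                if within < best - 1e-12:
                    best, best_k = within, k
            assert split == best_k
            assert thr == pytest.approx(edges[best_k])

    def test_cross_check_against_skimage(self):
        filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(60, 8, 800),
                                 rng.normal(120, 10, 300)])
        stack, _ = simple_stack(values.tolist(), [0])
        res = threshold_otsu(stack)
        ref = filters.threshold_otsu(values, nbins=256)
        binwidth = np.ptp(values) / 256
        assert abs(res.per_slice_threshold[0] - ref) <= 2 * binwidth

    def test_labels_spurious_mar_on_mar_free_slice(self):
        truth = generate_phantom(PhantomSpec(
            seed=4, wedge_width_base=0.0, wedge_width_apex=0.0))
        res = threshold_otsu(truth.stack)
        assert truth.mar_truth.sum() == 0
        assert res.pixel_mask.sum() > 0

    def test_constant_slice_excluded(self):
        stack, _ = simple_stack([7.0] * 20, [0])
        res = threshold_otsu(stack)
        assert np.isnan(res.per_slice_threshold[0])
        assert not res.pixel_mask.any()


@pytest.fixture(scope="module")
def phantom_setup():
    truth = generate_phantom(PhantomSpec(seed=9))
    grid = compute_sector_grid(truth.stack, truth.orient)
    rem = remote_mask(truth.stack, grid, load_extent_model("LAD"))
    return truth.stack, rem


class TestSharedProperties:
    def test_masks_are_subsets_of_myocardium(self, phantom_setup):
        stack, rem = phantom_setup
        for res in (threshold_2sd(stack, rem), threshold_fwhm(stack, rem),
                    threshold_otsu(stack)):
            assert not np.any(res.pixel_mask & ~stack.myo_mask)

    def test_shift_equivariance_of_all_thresholds(self, phantom_setup):
        stack, rem = phantom_setup
        shift = 57.0
        shifted = ShortAxisStack(image=stack.image + shift,
                                 myo_mask=stack.myo_mask)
        for fn, tol in ((threshold_2sd, 1e-9), (threshold_fwhm, 1e-9)):
            a = fn(stack, rem).per_slice_threshold
            b = fn(shifted, rem).per_slice_threshold
            ok = np.isfinite(a)
            assert np.allclose(b[ok] - a[ok], shift, atol=tol)
        a = threshold_otsu(stack).per_slice_threshold
        b = threshold_otsu(shifted).per_slice_threshold
        ok = np.isfinite(a)
        binwidth = max(np.ptp(stack.image[s][stack.myo_mask[s]]) / 256
                       for s in range(stack.n_slices))
        assert np.allclose(b[ok] - a[ok], shift, atol=binwidth + 1e-9)

    def test_mask_intensities_respect_the_threshold(self, phantom_setup):
        stack, rem = phantom_setup
        res = threshold_2sd(stack, rem)
        for s in range(stack.n_slices):
            thr = res.per_slice_threshold[s]
            if np.isfinite(thr) and res.pixel_mask[s].any():
                assert stack.image[s][res.pixel_mask[s]].min() >= thr
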