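"""Boundary-shift-integral components against analytic and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serialbsi import (ImagePair, IntensityWindow, PhantomSpec,
                       boundary_region, clipped_bsi,
                       differential_bias_correct, double_window_bsi, kn_bsi,
                       make_phantom_pair, normalise_pair, tissue_means_kmeans)

from conftest import noisy_pair


class TestTissueMeansKmeans:
    def test_three_cluster_recovery(self, rng):
        vals = np.concatenate([rng.normal(10, 1, 400), rng.normal(50, 1, 300),
                               rng.normal(90, 1, 300)])
        img = vals.reshape(10, 10, 10)
        cents = tissue_means_kmeans(img, np.ones(img.shape, bool), k=3)
        np.testing.assert_allclose(cents, [10, 50, 90], atol=1.0)

    def test_constant_image_rejected(self):
        img = np.full((4, 4, 4), 7.0)
        with pytest.raises(ValueError, match="distinct"):
            tissue_means_kmeans(img, np.ones(img.shape, bool), k=2)

    def test_k1_equals_masked_mean(self, rng):
        img = rng.normal(size=(6, 6, 6))
        mask = img > 0
        cents = tissue_means_kmeans(img, mask, k=1)
        assert cents[0] == pytest.approx(img[mask].mean(), abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tissue_means_kmeans(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))

    def test_matches_sklearn_lloyd(self, rng):
        """Independent library oracle on a well-separated mixture."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        vals = np.concatenate([rng.normal(20, 3, 500), rng.normal(70, 3, 800),
                               rng.normal(120, 3, 700)])
        img = vals.reshape(20, 10, 10)
        ours = tissue_means_kmeans(img, np.ones(img.shape, bool), k=3)
        km = sklearn_cluster.KMeans(
            n_clusters=3, n_init=1,
            init=np.array([[20.0], [70.0], [120.0]])).fit(vals[:, None])
        np.testing.assert_allclose(ours, np.sort(km.cluster_centers_.ravel()),
                                   rtol=1e-4)


class TestNormalisePair:
    def test_identity_when_already_at_targets(self, rng):
        img = rng.uniform(0, 1, (5, 5, 5))
        pair = ImagePair(img, img.copy(), 0.001)
        out = normalise_pair(pair, [0.0, 1.0], [0.0, 1.0], (0.0, 1.0))
        np.testing.assert_allclose(out.baseline, img, atol=1e-12)

    def test_scaled_followup_agrees_after_normalisation(self, rng):
        base = rng.uniform(10, 100, (6, 6, 6))
        pair = ImagePair(base, 2.0 * base, 0.001)
        cents = np.array([20.0, 60.0, 90.0])
        out = normalise_pair(pair, cents, 2.0 * cents)
        np.testing.assert_allclose(out.baseline, out.followup, atol=1e-9)

    def test_csf_centroid_maps_to_target_exactly(self):
        img = np.linspace(0, 200, 64).reshape(4, 4, 4)
        pair = ImagePair(img, img, 0.001)
        cents = [30.0, 90.0, 150.0]
        out = normalise_pair(pair, cents, cents, (0.2, 0.8))
        mapped = 0.2 + (0.8 - 0.2) / (150 - 30) * (30.0 - 30.0)
        assert mapped == pytest.approx(0.2, abs=1e-9)
        # a voxel exactly at the CSF centroid lands on the target
        probe = ImagePair(np.full((2, 2, 2), 30.0), np.full((2, 2, 2), 30.0),
                          0.001)
        out = normalise_pair(probe, cents, cents, (0.2, 0.8))
        np.testing.assert_allclose(out.baseline, 0.2, atol=1e-9)

    def test_coincident_centroids_rejected(self):
        pair = ImagePair(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), 0.001)
        with pytest.raises(ValueError, match="ascending"):
            normalise_pair(pair, [1.0, 1.0], [0.0, 1.0])


class TestBoundaryRegion:
    def test_sphere_shell_thickness(self):
        x, y, z = np.mgrid[:32, :32, :32]
        d = np.sqrt((x - 15.6) ** 2 + (y - 15.6) ** 2 + (z - 15.6) ** 2)
        sphere = d <= 10
        shell = boundary_region(sphere, sphere, dilate=1, erode=1)
        assert not shell[sphere & (d < 8.0)].any()      # interior excluded
        assert shell[(d > 9.7) & (d <= 10.0)].all()     # surface included
        assert not shell[d > 12.0].any()                # exterior excluded

    def test_disjoint_masks_cover_both(self):
        a = np.zeros((20, 20, 20), bool)
        b = np.zeros((20, 20, 20), bool)
        a[3:6, 3:6, 3:6] = True
        b[12:15, 12:15, 12:15] = True
        region = boundary_region(a, b, dilate=1, erode=1)
        assert region[a].all() and region[b].all()

    def test_matches_skimage_morphology_oracle(self, rng):
        skmorph = pytest.importorskip("skimage.morphology")
        blob_a = rng.random((32, 32, 32)) > 0.7
        blob_b = rng.random((32, 32, 32)) > 0.7
        ours = boundary_region(blob_a, blob_b, dilate=1, erode=1)
        fp = np.zeros((3, 3, 3), bool)  # 6-connected cross, the default element
        fp[1, 1, :] = fp[1, :, 1] = fp[:, 1, 1] = True
        expected = skmorph.binary_dilation(blob_a | blob_b, fp) \
            & ~skmorph.binary_erosion(blob_a & blob_b, fp)
        np.testing.assert_array_equal(ours, expected)

    def test_negative_parameters_rejected(self):
        m = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError):
            boundary_region(m, m, dilate=-1)


class TestClippedBsi:
    def test_identical_pair_is_zero(self, rng):
        img = rng.uniform(0, 1, (8, 8, 8))
        pair = ImagePair(img, img.copy(), 0.001)
        region = np.ones(img.shape, bool)
        res = clipped_bsi(pair, region, IntensityWindow(0.25, 0.75))
        assert res.value_ml == 0.0

    def test_single_voxel_full_transition_is_one_voxel_volume(self):
        base = np.full((8, 8, 8), 0.75)
        follow = base.copy()
        follow[4, 4, 4] = 0.25
        pair = ImagePair(base, follow, 0.001)
        region = np.zeros(base.shape, bool)
        region[3:6, 3:6, 3:6] = True
        res = clipped_bsi(pair, region, IntensityWindow(0.25, 0.75))
        assert res.value_ml == pytest.approx(0.001, abs=1e-15)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_antisymmetry_and_boundedness(self, seed):
        r = np.random.default_rng(seed)
        base = r.uniform(0, 1, (6, 6, 6))
        follow = r.uniform(0, 1, (6, 6, 6))
        region = r.random((6, 6, 6)) > 0.5
        pair = ImagePair(base, follow, 0.001)
        w = IntensityWindow(0.3, 0.7)
        fwd = clipped_bsi(pair, region, w)
        rev = clipped_bsi(pair.swapped(), region, w)
        assert fwd.value_ml == pytest.approx(-rev.value_ml, abs=1e-15)
        assert abs(fwd.value_ml) <= 0.001 * fwd.n_boundary_voxels + 1e-12

    def test_window_scale_invariance(self, rng):
        base = rng.uniform(0, 1, (6, 6, 6))
        follow = rng.uniform(0, 1, (6, 6, 6))
        region = np.ones(base.shape, bool)
        w = IntensityWindow(0.3, 0.7)
        ref = clipped_bsi(ImagePair(base, follow, 0.001), region, w).value_ml
        a, b = 37.5, -4.2  # arbitrary positive affine map
        scaled = clipped_bsi(
            ImagePair(a * base + b, a * follow + b, 0.001), region,
            IntensityWindow(a * w.lo + b, a * w.hi + b)).value_ml
        assert scaled == pytest.approx(ref, abs=1e-9)

    def test_empty_region_warns_and_returns_zero(self, rng):
        img = rng.uniform(0, 1, (4, 4, 4))
        pair = ImagePair(img, img, 0.001)
        with pytest.warns(UserWarning, match="empty"):
            res = clipped_bsi(pair, np.zeros(img.shape, bool),
                              IntensityWindow(0.2, 0.8))
        assert res.value_ml == 0.0 and res.n_boundary_voxels == 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            IntensityWindow(0.8, 0.2)


class TestKnBsi:
    def test_zero_atrophy_noiseless_is_zero(self):
        spec = PhantomSpec(atrophy_ml=0.0, ventricle_growth_ml=0.0,
                           hippo_atrophy_ml=0.0)
        pair, masks, _ = make_phantom_pair(spec)
        res = kn_bsi(pair, *masks["brain"])
        assert abs(res.value_ml) <= 1e-6

    def test_recovers_truth_at_snr25(self, default_phantom):
        pair, masks, truth = default_phantom
        res = kn_bsi(noisy_pair(pair, seed=42), *masks["brain"])
        assert res.value_ml == pytest.approx(truth["brain_loss_ml"], rel=0.10)

    def test_scan_type_noise_profiles_equally_accurate_without_motion(
            self, default_phantom):
        """Radial-SNR (accelerated) vs uniform-SNR noise: same mean BSI error."""
        from serialbsi import NoiseSpec
        from serialbsi.phantom import add_acquisition_noise
        pair, masks, truth = default_phantom
        errs = {"acc": [], "nonacc": []}
        for seed in range(12):
            for key, grad, snr in (("acc", 0.01, 25.0), ("nonacc", 0.0, 30.0)):
                scan = "accelerated" if key == "acc" else "non_accelerated"
                p = ImagePair(
                    add_acquisition_noise(pair.baseline, NoiseSpec(
                        scan_type=scan, snr_center=snr, snr_gradient=grad,
                        seed=3 * seed)),
                    add_acquisition_noise(pair.followup, NoiseSpec(
                        scan_type=scan, snr_center=snr, snr_gradient=grad,
                        seed=3 * seed + 1)),
                    pair.voxel_volume)
                errs[key].append(abs(kn_bsi(p, *masks["brain"]).value_ml
                                     - truth["brain_loss_ml"]))
        # comparable accuracy: neither protocol dominates by more than 3 mse
        assert np.mean(errs["acc"]) <= 3 * np.mean(errs["nonacc"]) + 0.05
        assert np.mean(errs["nonacc"]) <= 3 * np.mean(errs["acc"]) + 0.05

    def test_monotone_in_true_atrophy(self):
        means = []
        for atrophy in (0.5, 2.0, 4.0):
            spec = PhantomSpec(atrophy_ml=atrophy)
            pair, masks, _ = make_phantom_pair(spec)
            vals = [kn_bsi(noisy_pair(pair, seed=s), *masks["brain"]).value_ml
                    for s in range(5)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestDoubleWindowBsi:
    def test_identical_pair_is_zero(self, rng):
        img = rng.uniform(0, 1, (8, 8, 8))
        pair = ImagePair(img, img.copy(), 0.001)
        mask = np.zeros(img.shape, bool)
        mask[2:6, 2:6, 2:6] = True
        res = double_window_bsi(pair, mask, mask, IntensityWindow(0.0, 0.5),
                                IntensityWindow(0.5, 1.0))
        assert res.value_ml == 0.0

    def test_gm_wm_confined_change_equals_single_window(self, rng):
        """Change inside the GM/WM window only: double = oriented single."""
        base = rng.uniform(0.55, 0.95, (8, 8, 8))
        follow = rng.uniform(0.55, 0.95, (8, 8, 8))
        pair = ImagePair(base, follow, 0.001)
        mask = np.ones(base.shape, bool)
        w1, w2 = IntensityWindow(0.0, 0.5), IntensityWindow(0.5, 1.0)
        region = boundary_region(mask, mask, 1, 1)
        double = double_window_bsi(pair, mask, mask, w1, w2)
        single = clipped_bsi(pair, region, w2)
        assert double.value_ml == pytest.approx(-single.value_ml, abs=1e-12)

    def test_overlapping_windows_rejected(self, rng):
        img = rng.uniform(0, 1, (4, 4, 4))
        pair = ImagePair(img, img, 0.001)
        m = np.ones(img.shape, bool)
        with pytest.raises(ValueError, match="overlap"):
            double_window_bsi(pair, m, m, IntensityWindow(0.0, 0.6),
                              IntensityWindow(0.5, 1.0))

    def test_hippocampal_loss_recovered_noiseless(self, default_phantom):
        from serialbsi.config import RunConfig
        from serialbsi.pipeline import measure_structures
        pair, masks, truth = default_phantom
        res = measure_structures(pair, masks, RunConfig().bsi)
        assert res["hippocampus"].value_ml == pytest.approx(
            truth["hippo_loss_ml"], abs=1e-9)


class TestDifferentialBiasCorrect:
    def test_identical_pair_is_fixed_point(self, default_phantom):
        pair, masks, _ = default_phantom
        same = ImagePair(pair.baseline, pair.baseline.copy(),
                         pair.voxel_volume)
        out = differential_bias_correct(same, masks["brain"][0])
        np.testing.assert_allclose(out.baseline, out.followup, atol=1e-9)

    def test_removes_constructed_smooth_field(self, default_phantom):
        pair, masks, _ = default_phantom
        x = np.linspace(-1, 1, 64)
        field = np.exp(0.15 * x[:, None, None] + 0.1 * x[None, :, None])
        biased = ImagePair(pair.baseline, pair.baseline * field,
                           pair.voxel_volume)
        mask = masks["brain"][0]
        out = differential_bias_correct(biased, mask, smoothing_fwhm=10.0)
        from scipy import ndimage
        # judge on a deep core, clear of mask-edge smoothing asymmetry
        core = ndimage.binary_erosion(mask, iterations=10)
        sd_before = np.std(biased.followup[core] / biased.baseline[core])
        sd_after = np.std(out.followup[core] / out.baseline[core])
        assert sd_after <= sd_before / 10.0

    def test_idempotent_within_tolerance(self, default_phantom):
        pair, masks, _ = default_phantom
        x = np.linspace(-1, 1, 64)
        field = np.exp(0.1 * x[:, None, None])
        biased = ImagePair(pair.baseline, pair.baseline * field,
                           pair.voxel_volume)
        mask = masks["brain"][0]
        # mask-edge smoothing asymmetry grows with kernel width, so judge
        # idempotence at a moderate FWHM (RMS over the mask)
        once = differential_bias_correct(biased, mask, smoothing_fwhm=8.0)
        twice = differential_bias_correct(once, mask, smoothing_fwhm=8.0)
        ratio = twice.followup[mask] / np.maximum(once.followup[mask], 1e-12)
        assert np.sqrt(np.mean((ratio - 1.0) ** 2)) <= 1e-3

    def test_nonpositive_intensities_rejected(self):
        pair = ImagePair(np.zeros((4, 4, 4)), np.ones((4, 4, 4)), 0.001)
        with pytest.raises(ValueError, match="positive"):
            differential_bias_correct(pair, np.ones((4, 4, 4), bool))
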