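"""The 38-feature extraction: closed-form oracles, dimensional scaling,
monotonicity on phantom pairs, and the feature-table contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from radiogen.phantom import DceMriSeries, PhantomSpec, generate_lesion_phantom
from radiogen.radiomics import (
    CATEGORIES,
    FEATURE_NAMES,
    compute_enhancement_map,
    compute_kinetic_features,
    compute_morphology_features,
    compute_shape_features,
    compute_size_features,
    compute_variance_kinetic_features,
    extract_all,
    normalize_features,
)


def _series_from_frames(frames, spacing=(1.0, 1.0, 1.0)):
    times = tuple(75.0 * i for i in range(len(frames)))
    return DceMriSeries(frames=np.asarray(frames, float), spacing=spacing,
                        frame_times=times)


class TestEnhancementMap:
    def test_equal_frames_give_zero(self):
        f = np.full((3, 6, 6, 6), 50.0)
        emap = compute_enhancement_map(_series_from_frames(f), 1)
        assert np.allclose(emap, 0.0)

    def test_doubling_gives_one(self):
        f = np.stack([np.full((6, 6, 6), 100.0), np.full((6, 6, 6), 200.0),
                      np.full((6, 6, 6), 200.0)])
        emap = compute_enhancement_map(_series_from_frames(f), 1)
        assert np.allclose(emap, 1.0, atol=1e-5)

    def test_matches_scalar_loop_oracle(self, rng):
        frames = rng.uniform(50, 200, size=(3, 5, 5, 5))
        series = _series_from_frames(frames)
        emap = compute_enhancement_map(series, 2)
        eps = 1e-6 * np.abs(frames).max()
        for idx in np.ndindex(5, 5, 5):
            expected = (frames[2][idx] - frames[0][idx]) / (frames[0][idx] + eps)
            assert emap[idx] == pytest.approx(expected, abs=1e-12)

    def test_frame_index_out_of_range(self):
        f = np.zeros((3, 4, 4, 4)) + 1
        with pytest.raises(ValueError, match="frame_index"):
            compute_enhancement_map(_series_from_frames(f), 5)


class TestSizeFeatures:
    def test_single_voxel_closed_form(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        s = compute_size_features(mask, (1, 1, 1))
        assert s["S1_volume"] == pytest.approx(1.0)
        assert s["S2_effective_diameter"] == pytest.approx((6 / np.pi) ** (1 / 3),
                                                           abs=1e-4)

    def test_digital_sphere_against_analytic_oracle(self):
        spec = PhantomSpec(grid_shape=(28, 28, 28), voxel_spacing=(1, 1, 1),
                           lesion_radius=10.0)
        _, mask = generate_lesion_phantom(spec, 0)
        s = compute_size_features(mask, (1, 1, 1))
        assert abs(s["S1_volume"] / (4 / 3 * np.pi * 1000) - 1) < 0.03
        assert abs(s["S3_surface_area"] / (4 * np.pi * 100) - 1) < 0.05
        assert s["S4_maximum_linear_size"] == pytest.approx(20.0, rel=0.05)

    def test_dimensional_scaling_laws(self):
        spec = PhantomSpec(grid_shape=(28, 28, 28), voxel_spacing=(1, 1, 1),
                           lesion_radius=9.0)
        _, mask = generate_lesion_phantom(spec, 0)
        s1 = compute_size_features(mask, (1, 1, 1))
        s2 = compute_size_features(mask, (2, 2, 2))
        assert s2["S1_volume"] == pytest.approx(8 * s1["S1_volume"])
        assert s2["S2_effective_diameter"] == pytest.approx(
            2 * s1["S2_effective_diameter"])
        assert s2["S3_surface_area"] == pytest.approx(
            4 * s1["S3_surface_area"], rel=1e-6)
        assert s2["S4_maximum_linear_size"] == pytest.approx(
            2 * s1["S4_maximum_linear_size"])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_size_features(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestShapeFeatures:
    def test_large_sphere_approaches_unit_sphericity(self):
        spec = PhantomSpec(grid_shape=(40, 40, 40), voxel_spacing=(1, 1, 1),
                           lesion_radius=16.0)
        _, mask = generate_lesion_phantom(spec, 0)
        g = compute_shape_features(mask, (1, 1, 1))
        assert g["G1_sphericity"] >= 0.97
        assert g["G2_irregularity"] == pytest.approx(1 - g["G1_sphericity"])

    def test_sphericity_scale_invariant(self):
        spec = PhantomSpec(grid_shape=(28, 28, 28), voxel_spacing=(1, 1, 1),
                           lesion_radius=9.0)
        _, mask = generate_lesion_phantom(spec, 0)
        g1 = compute_shape_features(mask, (1, 1, 1))["G1_sphericity"]
        g2 = compute_shape_features(mask, (3, 3, 3))["G1_sphericity"]
        assert g1 == pytest.approx(g2, rel=1e-6)

    @pytest.mark.parametrize("seed", [3, 11, 29])
    def test_spiculation_strictly_lowers_sphericity(self, seed):
        smooth = PhantomSpec(lesion_radius=8.0, spiculation_amplitude=0.0)
        spiky = PhantomSpec(lesion_radius=8.0, spiculation_amplitude=0.3)
        _, m0 = generate_lesion_phantom(smooth, seed)
        _, m1 = generate_lesion_phantom(spiky, seed)
        g0 = compute_shape_features(m0, smooth.voxel_spacing)["G1_sphericity"]
        g1 = compute_shape_features(m1, spiky.voxel_spacing)["G1_sphericity"]
        assert g1 < g0


class TestMorphologyFeatures:
    @staticmethod
    def _slab_series(blur_sigma=0.0):
        """Slab lesion bounded only along z: all interior boundary normals
        are +/- z, so the margin gradient is identical everywhere."""
        shape = (16, 16, 24)
        mask = np.zeros(shape, bool)
        mask[:, :, 8:16] = True
        pre = np.full(shape, 100.0)
        post = np.where(mask, 300.0, 100.0)
        if blur_sigma > 0:
            post = ndimage.gaussian_filter(post, blur_sigma)
        frames = np.stack([pre, post, post])
        return _series_from_frames(frames), mask

    def test_uniform_step_edge_has_zero_margin_variance(self):
        series, mask = self._slab_series()
        with pytest.warns(UserWarning, match="volume border"):
            m = compute_morphology_features(series, mask)
        assert m["M1_margin_sharpness"] > 0
        assert m["M2_variance_of_margin_sharpness"] <= 1e-6 * m[
            "M1_margin_sharpness"] ** 2

    def test_blurring_the_edge_decreases_sharpness(self):
        sharp_series, mask = self._slab_series(blur_sigma=0.0)
        blurred1, _ = self._slab_series(blur_sigma=1.0)
        blurred2, _ = self._slab_series(blur_sigma=2.0)
        with pytest.warns(UserWarning):
            m0 = compute_morphology_features(sharp_series, mask)
            m1 = compute_morphology_features(blurred1, mask)
            m2 = compute_morphology_features(blurred2, mask)
        assert m0["M1_margin_sharpness"] > m1["M1_margin_sharpness"] > m2[
            "M1_margin_sharpness"]

    def test_margin_sharpness_matches_central_difference_oracle(
            self, heterogeneous_phantom):
        """M1 recomputed voxel-by-voxel with explicit central differences."""
        spec, series, mask = heterogeneous_phantom
        m = compute_morphology_features(series, mask)
        emap = compute_enhancement_map(series, 1)
        spacing = np.asarray(series.spacing)
        sigma_vox = 1.5 / spacing
        smooth = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
        boundary = mask & ~ndimage.binary_erosion(mask)
        vals = []
        for x, y, z in np.argwhere(boundary):
            grad = np.zeros(3)
            normal = np.zeros(3)
            for ax, arr in ((0, None), (1, None), (2, None)):
                step = np.zeros(3, int)
                step[ax] = 1
                p = (x + step[0], y + step[1], z + step[2])
                q = (x - step[0], y - step[1], z - step[2])
                grad[ax] = (emap[p] - emap[q]) / (2 * spacing[ax])
                normal[ax] = -(smooth[p] - smooth[q]) / (2 * spacing[ax])
            n = np.linalg.norm(normal)
            if n > 0:
                normal /= n
            vals.append(abs(grad @ normal))
        assert m["M1_margin_sharpness"] == pytest.approx(np.mean(vals),
                                                         abs=1e-10)


class TestKineticFeatures:
    @staticmethod
    def _uniform_series(curve, value=100.0):
        """Small uniform lesion with an exact prescribed enhancement curve."""
        shape = (10, 10, 10)
        mask = np.zeros(shape, bool)
        mask[3:7, 3:7, 3:7] = True
        frames = []
        for c in curve:
            f = np.full(shape, value)
            f[mask] = value * (1 + c)
            frames.append(f)
        return _series_from_frames(np.stack(frames)), mask

    def test_plateau_curve_definition(self):
        series, mask = self._uniform_series([0, 1, 1, 1, 1, 1])
        k = compute_kinetic_features(series, mask)
        assert k["K1_maximum_enhancement"] == pytest.approx(1.0, rel=1e-5)
        assert k["K2_time_to_peak"] == 75.0
        assert k["K4_washout_rate"] == pytest.approx(0.0, abs=1e-9)

    def test_persistent_curve_peaks_at_last_frame(self):
        series, mask = self._uniform_series([0, 0.3, 0.5, 0.7, 0.9, 1.0])
        k = compute_kinetic_features(series, mask)
        assert k["K2_time_to_peak"] == 375.0
        assert k["K4_washout_rate"] == 0.0

    def test_washout_rate_closed_form(self):
        """Peak at 150 s, 30% linear decay by 375 s: K4 = 1/750 per second."""
        spec = PhantomSpec(grid_shape=(48, 48, 32), lesion_radius=7.0,
                           kinetic_type="washout", noise_sd=0.0,
                           heterogeneity_sd=0.0)
        series, mask = generate_lesion_phantom(spec, 0)
        k = compute_kinetic_features(series, mask)
        assert k["K2_time_to_peak"] == 150.0
        assert k["K4_washout_rate"] == pytest.approx(1 / 750, rel=1e-4)

    def test_invariant_to_global_intensity_scaling(self, heterogeneous_phantom):
        _, series, mask = heterogeneous_phantom
        scaled = DceMriSeries(frames=series.frames * 3.0,
                              spacing=series.spacing,
                              frame_times=series.frame_times)
        k0 = compute_kinetic_features(series, mask)
        k1 = compute_kinetic_features(scaled, mask)
        for name in k0:
            assert k0[name] == pytest.approx(k1[name], rel=1e-6), name


class TestVarianceKinetics:
    def test_uniform_lesion_has_zero_variance(self, clean_sphere_phantom):
        _, series, mask = clean_sphere_phantom
        v = compute_variance_kinetic_features(series, mask)
        assert v["V1_maximum_variance_of_enhancement"] == pytest.approx(
            0.0, abs=1e-12)

    def test_variance_peaks_at_enhancement_peak_for_plateau(self):
        """Multiplicative heterogeneity makes variance proportional to the
        squared mean curve, so the variance peak time equals the
        enhancement peak time."""
        spec = PhantomSpec(grid_shape=(48, 48, 32), lesion_radius=7.0,
                           kinetic_type="plateau", heterogeneity_sd=0.2,
                           noise_sd=0.0)
        series, mask = generate_lesion_phantom(spec, 4)
        v = compute_variance_kinetic_features(series, mask)
        assert v["V2_time_to_peak_of_variance"] == 150.0

    def test_matches_two_pass_variance_oracle(self, heterogeneous_phantom):
        _, series, mask = heterogeneous_phantom
        v = compute_variance_kinetic_features(series, mask)
        best = -1.0
        for t in range(1, series.frames.shape[0]):
            e = compute_enhancement_map(series, t)[mask]
            mean = e.sum() / e.size
            var = ((e - mean) ** 2).sum() / e.size
            best = max(best, var)
        assert v["V1_maximum_variance_of_enhancement"] == pytest.approx(
            best, abs=1e-10)


class TestExtractAll:
    def test_exactly_38_named_features_in_six_categories(
            self, heterogeneous_phantom):
        _, series, mask = heterogeneous_phantom
        vec = extract_all(series, mask)
        assert len(vec) == 38
        assert list(vec.index) == FEATURE_NAMES
        sizes = [len(v) for v in CATEGORIES.values()]
        assert sizes == [4, 3, 3, 14, 10, 4]
        assert sum(sizes) == 38

    def test_extraction_is_deterministic(self, heterogeneous_phantom):
        _, series, mask = heterogeneous_phantom
        v1 = extract_all(series, mask)
        v2 = extract_all(series, mask)
        pd.testing.assert_series_equal(v1, v2)

    def test_heterogeneity_raises_entropy_lowers_energy(self):
        lo = PhantomSpec(grid_shape=(48, 48, 32), lesion_radius=7.0,
                         heterogeneity_sd=0.05, noise_sd=0.0)
        hi = PhantomSpec(grid_shape=(48, 48, 32), lesion_radius=7.0,
                         heterogeneity_sd=0.3, noise_sd=0.0)
        s_lo, m_lo = generate_lesion_phantom(lo, 8)
        s_hi, m_hi = generate_lesion_phantom(hi, 8)
        v_lo = extract_all(s_lo, m_lo)
        v_hi = extract_all(s_hi, m_hi)
        assert v_hi["T5_entropy"] > v_lo["T5_entropy"]
        assert v_hi["T1_energy"] < v_lo["T1_energy"]

    def test_volume_increases_with_radius_and_washout_sign(self):
        small = PhantomSpec(lesion_radius=6.0, kinetic_type="persistent")
        large = PhantomSpec(lesion_radius=10.0, kinetic_type="washout")
        s_s, m_s = generate_lesion_phantom(small, 2)
        s_l, m_l = generate_lesion_phantom(large, 2)
        v_s = extract_all(s_s, m_s)
        v_l = extract_all(s_l, m_l)
        assert v_l["S1_volume"] > v_s["S1_volume"]
        assert v_s["K4_washout_rate"] == 0.0
        assert v_l["K4_washout_rate"] > 0.0


class TestNormalizeFeatures:
    def test_column_z_scoring_closed_form(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        z, flagged = normalize_features(table)
        assert np.allclose(z["a"], [-1, 0, 1])
        assert flagged == ["b"]
        assert np.allclose(z["b"], 0.0)

    def test_idempotent_on_z_scored_input(self, rng):
        table = pd.DataFrame(rng.normal(size=(20, 5)))
        z1, _ = normalize_features(table)
        z2, _ = normalize_features(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_zero_mean_unit_variance(self, rng):
        table = pd.DataFrame(rng.uniform(0, 100, size=(30, 4)))
        z, _ = normalize_features(table)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_single_case_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            normalize_features(pd.DataFrame({"a": [1.0]}))
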