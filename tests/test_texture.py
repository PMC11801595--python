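import numpy as np
import pytest
from skimage.feature import graycoprops

from conftest import brute_force_glcm
from cervitex.image_io import GrayImage
from cervitex.texture import (BAND_NAMES, FEATURE_NAMES, CooccurrenceMatrix,
                              DataError, FeatureMatrix, GLCMConfig,
                              compute_features, compute_glcm, feature_matrix,
                              quantize)
from cervitex.wavelets import WaveletSpec

IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


class TestQuantize:
    def test_constant_band_maps_to_zero(self):
        assert np.all(quantize(np.full((8, 8), 3.7), 16) == 0)

    def test_endpoints(self):
        q = quantize(np.array([[0.0, 1.0]]), 2)
        assert q.tolist() == [[0, 1]]

    def test_uniform_band_occupancy_is_flat(self, rng):
        x = rng.uniform(0, 1, 10_000)
        q = quantize(x.reshape(100, 100), 16)
        counts = np.bincount(q.ravel(), minlength=16)
        # chi-square against uniform occupancy: 15 dof, generous bound
        chi2 = float(((counts - 625.0) ** 2 / 625.0).sum())
        assert chi2 < 40

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            quantize(np.array([[1.0, np.nan]]), 4)


class TestGLCM:
    def test_constant_raster_single_entry(self):
        P = compute_glcm(np.zeros((5, 5), dtype=np.uint8),
                         GLCMConfig(levels=4)).P
        assert P[0, 0] == 1.0
        assert P.sum() == 1.0

    def test_two_by_two_single_angle(self):
        q = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        P = compute_glcm(q, GLCMConfig(levels=2, angles=(0,))).P
        assert P[0, 1] == P[1, 0] == 0.5

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(100):
            h, w = rng.integers(2, 9, 2)
            G = int(rng.integers(2, 17))
            q = rng.integers(0, G, (h, w)).astype(np.uint8)
            P = compute_glcm(q, GLCMConfig(levels=G)).P
            assert np.array_equal(P, brute_force_glcm(q, G))

    def test_normalization_and_symmetry(self, rng):
        q = rng.integers(0, 8, (20, 20)).astype(np.uint8)
        P = compute_glcm(q, GLCMConfig(levels=8)).P
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(P, P.T)


class TestFeatures:
    def test_single_entry_glcm(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = compute_features(CooccurrenceMatrix(P, GLCMConfig(levels=4)))
        assert f[IDX["homogeneity"]] == 1.0
        assert f[IDX["contrast"]] == 0.0
        assert f[IDX["angular_second_moment"]] == 1.0
        assert f[IDX["entropy"]] == 0.0
        assert f[IDX["dissimilarity"]] == 0.0
        assert f[IDX["correlation"]] == 0.0  # degenerate rule

    def test_two_level_diagonal_glcm(self):
        P = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = compute_features(CooccurrenceMatrix(P, GLCMConfig(levels=2)))
        assert f[IDX["entropy"]] == pytest.approx(1.0)      # 1 bit
        assert f[IDX["angular_second_moment"]] == pytest.approx(0.5)
        assert f[IDX["contrast"]] == 0.0
        assert f[IDX["correlation"]] == pytest.approx(1.0)
        assert f[IDX["mean"]] == pytest.approx(0.5)

    def test_correlation_bounded(self, rng):
        for _ in range(20):
            C = rng.uniform(0, 1, (6, 6))
            C = C + C.T
            glcm = CooccurrenceMatrix(C / C.sum(), GLCMConfig(levels=6))
            assert -1.0 - 1e-9 <= compute_features(glcm)[IDX["correlation"]] <= 1.0 + 1e-9

    def test_against_skimage_formulas(self, rng):
        """Cross-check the shared subset of features with graycoprops."""
        q = rng.integers(0, 16, (32, 32)).astype(np.uint8)
        cm = compute_glcm(q, GLCMConfig(levels=16))
        ours = compute_features(cm)
        P4 = cm.P[:, :, None, None]
        for name, sk_name in [("contrast", "contrast"),
                              ("dissimilarity", "dissimilarity"),
                              ("homogeneity", "homogeneity"),
                              ("angular_second_moment", "ASM"),
                              ("correlation", "correlation"),
                              ("mean", "mean"),
                              ("standard_deviation", "std")]:
            expected = float(graycoprops(P4, sk_name)[0, 0])
            assert ours[IDX[name]] == pytest.approx(expected, rel=1e-10), name

    def test_noise_increases_entropy_and_contrast(self, rng):
        from cervitex.texture import band_features
        base = np.full((64, 64), 10.0)
        cfg = GLCMConfig()
        for _ in range(20):
            noisy = base + rng.standard_normal(base.shape)
            fb = band_features(base, cfg)
            fn = band_features(noisy, cfg)
            assert fn[IDX["entropy"]] > fb[IDX["entropy"]]
            assert fn[IDX["contrast"]] > fb[IDX["contrast"]]


class TestFeatureMatrix:
    def _tile(self, pixels):
        return GrayImage(pixels=pixels, modality="SEM", label="benign",
                         source_id="t", tile_index=2)

    def test_shape_determinism_and_metadata(self, rng):
        tile = self._tile(rng.integers(0, 256, (256, 256)).astype(np.uint8))
        spec = WaveletSpec("sym3")
        fm1 = feature_matrix(tile, spec)
        fm2 = feature_matrix(tile, spec)
        assert fm1.values.shape == (4, 10)
        assert np.all(np.isfinite(fm1.values))
        assert np.array_equal(fm1.values, fm2.values)
        assert fm1.flatten().shape == (40,)
        assert len(FeatureMatrix.column_names()) == 40
        assert fm1.label == "benign" and fm1.tile_index == 2

    def test_constant_tile_detail_rows_are_degenerate(self):
        tile = self._tile(np.full((256, 256), 77, dtype=np.uint8))
        fm = feature_matrix(tile, WaveletSpec("db4"))
        for row in range(1, 4):  # CD1..CD3
            assert fm.values[row, IDX["homogeneity"]] == 1.0
            assert fm.values[row, IDX["contrast"]] == 0.0
            assert fm.values[row, IDX["entropy"]] == 0.0

    def test_invariant_ranges(self, rng):
        tile = self._tile(rng.integers(0, 256, (256, 256)).astype(np.uint8))
        fm = feature_matrix(tile, WaveletSpec("coif5"))
        v = fm.values
        assert np.all((v[:, IDX["homogeneity"]] > 0) & (v[:, IDX["homogeneity"]] <= 1))
        assert np.all((v[:, IDX["angular_second_moment"]] > 0) &
                      (v[:, IDX["angular_second_moment"]] <= 1))
        assert np.all(v[:, IDX["entropy"]] >= 0)
        assert np.all(v[:, IDX["contrast"]] >= 0)
        assert np.all(v[:, IDX["dissimilarity"]] >= 0)
        assert np.all(v[:, IDX["standard_deviation"]] >= 0)
        assert np.all(np.abs(v[:, IDX["correlation"]]) <= 1 + 1e-9)
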