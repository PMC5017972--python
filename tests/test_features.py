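import numpy as np
import pytest
from scipy import ndimage

from glaucoscreen.features import (autocorrelogram,
                                   build_feature_vector, color_moments,
                                   feature_names, gabor_features,
                                   gabor_kernel, glcm_fused,
                                   haralick_features, lbp_riu2_histogram,
                                   quantize, riu2_code)


class TestGabor:
    def test_kernel_matches_pointwise_formula(self):
        f, theta, gamma, eta = 0.2, 0.6, 1.3, 0.9
        k = gabor_kernel(f, theta, gamma, eta, half_size=7)
        for (x, y) in [(0, 0), (3, -2), (-5, 6), (7, 7)]:
            xr = x * np.cos(theta) + y * np.sin(theta)
            yr = -x * np.sin(theta) + y * np.cos(theta)
            expect = (f ** 2 / (np.pi * gamma * eta)
                      * np.exp(-((f / gamma) ** 2 * xr ** 2
                                 + (f / eta) ** 2 * yr ** 2))
                      * np.exp(2j * np.pi * f * xr))
            assert k[y + 7, x + 7] == pytest.approx(expect, rel=1e-12)

    def test_grating_orientation_selectivity(self):
        f = 0.1
        x = np.arange(96)
        grating = 0.5 + 0.4 * np.cos(2 * np.pi * f * x)[None, :] \
            * np.ones((96, 1))
        feats = gabor_features(grating, [f], n_orientations=2)
        mean_0, mean_90 = feats[0], feats[2]
        assert mean_0 > 2 * mean_90

    def test_block_length_contract(self, rng):
        plane = rng.random((80, 80))
        feats = gabor_features(plane, [0.1, 0.2], n_orientations=4)
        assert len(feats) == 2 * 2 * 4

    def test_kernel_larger_than_plane_rejected(self):
        with pytest.raises(ValueError):
            gabor_features(np.zeros((10, 10)), [0.05], 2)


class TestLbp:
    def test_histogram_shape_and_mass(self, rng):
        h = lbp_riu2_histogram(rng.random((40, 40)), P=8, R=3)
        assert len(h) == 10
        assert h.sum() == pytest.approx(1.0)

    def test_constant_plane_all_mass_at_bin_p(self):
        h = lbp_riu2_histogram(np.full((30, 30), 0.5), P=8, R=3)
        assert h[8] == pytest.approx(1.0)   # s(0)=1 for all 8 neighbours

    def test_riu2_exhaustive_256_pattern_oracle(self):
        """riu2 mapping agrees with a bitwise transition-counting oracle."""
        for code in range(256):
            bits = np.array([(code >> p) & 1 for p in range(8)])
            transitions = sum(bits[p] != bits[(p + 1) % 8] for p in range(8))
            expect = bits.sum() if transitions <= 2 else 9
            assert riu2_code(bits)[0] == expect

    def test_matches_skimage_reference(self, rng):
        """Cross-check histogram against skimage's riu2 ('uniform') LBP."""
        import warnings
        from skimage.feature import local_binary_pattern
        plane = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 2)
        for R in (1, 3):
            mine = lbp_riu2_histogram(plane, 8, R)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sk = local_binary_pattern(plane, 8, R, method="uniform")
            m = int(np.ceil(R))
            codes = sk[m:-m, m:-m].astype(int).ravel()
            ref = np.bincount(codes, minlength=10) / codes.size
            assert np.allclose(mine, ref)

    def test_invariant_under_affine_intensity_map(self, rng):
        plane = ndimage.gaussian_filter(rng.random((50, 50)), 1.5)
        a = lbp_riu2_histogram(plane, 8, 3)
        b = lbp_riu2_histogram(2.5 * plane + 0.3, 8, 3)
        assert np.allclose(a, b)

    def test_rotation_invariance_90deg(self, rng):
        plane = ndimage.gaussian_filter(rng.standard_normal((60, 60)), 2.5)
        a = lbp_riu2_histogram(plane, 8, 3)
        b = lbp_riu2_histogram(np.rot90(plane), 8, 3)
        assert np.allclose(a, b, atol=0.03)

    def test_too_small_plane_rejected(self):
        with pytest.raises(ValueError):
            lbp_riu2_histogram(np.zeros((10, 10)), 8, 12)


class TestGlcm:
    def test_constant_plane_single_diagonal_cell(self):
        q = np.full((12, 12), 5, dtype=np.int64)
        m = glcm_fused(q, 8)
        assert m[5, 5] == pytest.approx(1.0)
        assert m.sum() == pytest.approx(1.0)

    def test_toy_plane_pair_enumeration_oracle(self):
        """3x3 plane: fused counts equal exhaustive enumeration of all
        in-bounds pixel pairs for the four displacement vectors."""
        q = np.array([[0, 1, 1],
                      [2, 0, 1],
                      [2, 2, 0]])
        counts = np.zeros((3, 3))
        for dr, dc in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
            for r in range(3):
                for c in range(3):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 3 and 0 <= cc < 3:
                        counts[q[r, c], q[rr, cc]] += 1
        expect = (counts / 4.0) / (counts / 4.0).sum()
        assert np.allclose(glcm_fused(q, 3), expect)

    def test_transpose_permutation_identity(self, rng):
        """Transposing the image swaps the displacement components, so the
        fused matrix of the transpose is the 0/45/90-degree matrices
        transposed plus the (invariant) 135-degree matrix."""
        q = rng.integers(0, 6, size=(15, 15))

        def directional(img, dr, dc):
            counts = np.zeros((6, 6))
            H, W = img.shape
            for r in range(H):
                for c in range(W):
                    if 0 <= r + dr < H and 0 <= c + dc < W:
                        counts[img[r, c], img[r + dr, c + dc]] += 1
            return counts

        d0 = directional(q, 0, 1)
        d45 = directional(q, -1, 1)
        d90 = directional(q, -1, 0)
        d135 = directional(q, -1, -1)
        expect = (d0.T + d45.T + d90.T + d135) / 4.0
        expect /= expect.sum()
        assert np.allclose(glcm_fused(q.T, 6), expect)

    def test_matches_skimage_reference(self, rng):
        """skimage's angle convention flips the row offset, so its 45/90/135
        matrices are the transposes of the printed displacement set."""
        from skimage.feature import graycomatrix
        q = rng.integers(0, 8, size=(16, 16))
        sk = graycomatrix(q.astype(np.uint8), distances=[1],
                          angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                          levels=8)
        fused = (sk[:, :, 0, 0] + sk[:, :, 0, 1].T
                 + sk[:, :, 0, 2].T + sk[:, :, 0, 3].T).astype(float) / 4
        fused /= fused.sum()
        assert np.allclose(glcm_fused(q, 8), fused)

    def test_nonnegative_unit_mass(self, rng):
        m = glcm_fused(rng.integers(0, 16, size=(30, 30)), 16, delta=2)
        assert (m >= 0).all() and m.sum() == pytest.approx(1.0)


class TestHaralick:
    def test_two_cell_diagonal(self):
        g = np.zeros((4, 4))
        g[0, 0] = g[1, 1] = 0.5
        f = haralick_features(g)
        assert f[8] == pytest.approx(1.0)    # entropy: 1 bit
        assert f[1] == pytest.approx(0.0)    # contrast: both on diagonal
        assert f[0] == pytest.approx(0.5)    # ASM

    def test_single_cell(self):
        g = np.zeros((4, 4))
        g[1, 3] = 1.0
        f = haralick_features(g)
        assert f[0] == pytest.approx(1.0)         # ASM
        assert f[8] == pytest.approx(0.0)         # entropy
        assert f[1] == pytest.approx((1 - 3) ** 2)  # contrast (i-j)^2

    def test_finite_on_random_matrices(self, rng):
        """500 random (incl. near-degenerate) normalized GLCMs give finite
        values for all 14 statistics."""
        for i in range(500):
            n = int(rng.integers(2, 9))
            g = rng.random((n, n)) ** (8 if i % 5 == 0 else 1)
            if i % 7 == 0:          # sparsify towards degeneracy
                g[g < np.quantile(g, 0.9)] = 0.0
            if g.sum() == 0:
                g[0, 0] = 1.0
            g /= g.sum()
            assert np.isfinite(haralick_features(g)).all()

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(np.ones((3, 3)))


class TestColorMoments:
    def test_constant_channel(self):
        arr = np.full((5, 5, 3), 0.7)
        f = color_moments(arr)
        for c in range(3):
            assert f[3 * c:3 * c + 3] == pytest.approx([0.7, 0.0, 0.0])

    def test_hand_computed_case(self):
        ch = np.array([0.0, 0.0, 0.0, 4.0]).reshape(2, 2)
        f = color_moments(ch[:, :, None])
        assert f[0] == pytest.approx(1.0)              # mean
        assert f[1] == pytest.approx(np.sqrt(3.0))     # sd
        assert f[2] == pytest.approx(6.0 ** (1 / 3))   # cube-root skewness

    def test_block_length_nine_for_rgb(self, rng):
        assert len(color_moments(rng.random((6, 6, 3)))) == 9

    def test_scale_equivariance(self, rng):
        arr = rng.random((8, 8, 3))
        f1, f2 = color_moments(arr), color_moments(3.0 * arr)
        assert np.allclose(f2, 3.0 * f1)

    def test_negative_skew_keeps_sign(self):
        ch = np.array([0.0, 4.0, 4.0, 4.0]).reshape(2, 2)
        f = color_moments(ch[:, :, None])
        assert f[2] == pytest.approx(-(6.0 ** (1 / 3)))


class TestAutocorrelogram:
    def test_constant_image(self):
        q = np.full((10, 10), 3, dtype=np.int64)
        f = autocorrelogram(q, n_colors=4, distances=(1, 2))
        f = f.reshape(4, 2)                 # (colour, distance)
        assert np.allclose(f[3], 1.0)
        assert np.allclose(f[:3], 0.0)

    def test_checkerboard_half(self):
        """Interior checkerboard pixels see 4 same-colour diagonals on the
        8-pixel L-inf ring; the exact value (border rings are clipped) is
        confirmed against an exhaustive ring-enumeration oracle."""
        yy, xx = np.mgrid[0:40, 0:40]
        q = ((yy + xx) % 2).astype(np.int64)
        f = autocorrelogram(q, n_colors=2, distances=(1,)).reshape(2, 1)
        num = np.zeros(2)
        den = np.zeros(2)
        for r in range(40):
            for c in range(40):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr, dc) == (0, 0):
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 40 and 0 <= cc < 40:
                            den[q[r, c]] += 1
                            num[q[r, c]] += q[rr, cc] == q[r, c]
        assert f[0, 0] == pytest.approx(num[0] / den[0], abs=1e-12)
        assert f[1, 0] == pytest.approx(num[1] / den[1], abs=1e-12)
        assert f[0, 0] == pytest.approx(0.5, abs=0.03)   # border clipping

    def test_block_length_contract(self, rng):
        q = rng.integers(0, 8, size=(20, 20))
        f = autocorrelogram(q, n_colors=8, distances=(1, 3, 5))
        assert len(f) == 8 * 3

    def test_values_in_unit_interval(self, rng):
        q = rng.integers(0, 16, size=(25, 25))
        f = autocorrelogram(q, n_colors=16, distances=(1, 3, 5, 7))
        assert (f >= 0).all() and (f <= 1).all()


class TestBuildFeatureVector:
    def test_default_hybrid_length(self, clean_roi, cfg_small):
        fv = build_feature_vector(clean_roi, ("lbp", "color_moments"),
                                  cfg_small)
        assert len(fv.values) == 10 + 9

    def test_deterministic(self, clean_roi, cfg_small):
        a = build_feature_vector(clean_roi, ("lbp", "color_moments"),
                                 cfg_small)
        b = build_feature_vector(clean_roi, ("lbp", "color_moments"),
                                 cfg_small)
        assert np.array_equal(a.values, b.values)

    def test_unknown_block_rejected(self, clean_roi, cfg_small):
        with pytest.raises(ValueError):
            build_feature_vector(clean_roi, ("lbp", "bogus"), cfg_small)

    def test_canonical_block_order(self, clean_roi, cfg_small):
        fv = build_feature_vector(clean_roi, ("color_moments", "lbp"),
                                  cfg_small)
        # order is canonical (lbp before color_moments), not request order
        assert np.array_equal(
            fv.values[:10], fv.blocks["lbp"])

    def test_feature_names_match_lengths(self, cfg_small):
        sel = ("lbp", "color_moments", "correlogram")
        names = feature_names(sel, cfg_small)
        assert len(names) == 10 + 9 + 64 * 4
        assert len(names) == len(set(names))

    def test_quantize_respects_levels(self, rng):
        q = quantize(rng.random((10, 10)), 16)
        assert q.min() >= 0 and q.max() <= 15
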