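"""Feature bank: morphology, density, run-length texture, wavelet subbands."""

import numpy as np
import pytest

from usradiomics import (
    ROIValidationError,
    TumorROI,
    build_glrlm,
    density_features,
    feature_names,
    feature_vector,
    glrlm_features,
    morphology_features,
    quantize,
    texture_features,
    wavelet_decompose,
    wavelet_features,
)
from usradiomics.features import (
    DENSITY_NAMES,
    DIRECTIONS,
    MORPHOLOGY_NAMES,
    TEXTURE_STATS,
)
from conftest import disk_mask
from oracles import brute_force_glrlm, brute_force_glrlm_stats


class TestMorphology:
    def test_disk_is_nearly_circular(self, disk_roi):
        m = morphology_features(disk_roi)
        assert m["Compactness"] == pytest.approx(1.0, rel=0.05)
        assert m["Convexity"] == pytest.approx(1.0, rel=0.05)
        assert m["Spherical_Disproportion"] == pytest.approx(1.0, rel=0.05)
        assert m["Spherical_Ratio"] == pytest.approx(1.0, rel=0.05)

    def test_square_exact_values(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True  # 10 x 10 square
        m = morphology_features(TumorROI(mask), pixel_spacing=1.0)
        assert m["Volume"] == 100.0
        assert m["Max_3D_Diameter"] == pytest.approx(9 * np.sqrt(2), abs=1e-12)

    def test_feret_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mask = disk_mask((40, 40), center=(20 + rng.uniform(-3, 3),) * 2,
                             radius=rng.uniform(6, 12))
            roi = TumorROI(mask)
            m = morphology_features(roi)
            from scipy import ndimage

            interior = ndimage.binary_erosion(
                mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
            )
            pts = np.argwhere(mask & ~interior).astype(float)
            best = max(
                np.hypot(a[0] - b[0], a[1] - b[1]) for a in pts for b in pts
            )
            assert m["Max_3D_Diameter"] == pytest.approx(best, abs=1e-9)

    def test_scaling_law(self):
        mask = disk_mask((40, 40), radius=10.0)
        big = np.kron(mask, np.ones((2, 2), bool))
        m1 = morphology_features(TumorROI(mask))
        m2 = morphology_features(TumorROI(big))
        assert m2["Volume"] == 4 * m1["Volume"]
        assert m2["Max_Radius"] == pytest.approx(2 * m1["Max_Radius"], rel=0.06)
        assert m2["Max_3D_Diameter"] == pytest.approx(2 * m1["Max_3D_Diameter"], rel=0.06)
        # pixel spacing scales lengths linearly and areas quadratically
        m3 = morphology_features(TumorROI(mask), pixel_spacing=2.0)
        assert m3["Volume"] == 4 * m1["Volume"]
        assert m3["Max_Radius"] == 2 * m1["Max_Radius"]

    def test_degenerate_roi_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[5:9, 5:9] = True
        roi = TumorROI(mask)  # 16 px: passes ROI validation
        roi.mask[5, 5] = False  # sneak below the morphology limit
        with pytest.raises(ROIValidationError):
            morphology_features(roi)


def _oracle_density(image, mask, n_bins=32, band_width=5):
    """All 21 first-order statistics from their definitions, coded naively."""
    v = image[mask]
    n = v.size
    mean = v.sum() / n
    std = np.sqrt(((v - mean) ** 2).sum() / n)

    pad = np.pad(image, 1, mode="reflect")
    h, w = image.shape
    gx = np.zeros_like(image)
    gy = np.zeros_like(image)
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    local = np.zeros_like(image)
    for r in range(h):
        for c in range(w):
            win = pad[r : r + 3, c : c + 3]
            gx[r, c] = (win * kx).sum()
            gy[r, c] = (win * ky).sum()
            local[r, c] = win.mean()
    grad = np.sqrt(gx**2 + gy**2)[mask]
    fluct = np.abs(image - local)[mask]

    # Chebyshev-distance band around the ROI
    band = np.zeros_like(mask)
    fg = np.argwhere(mask)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                continue
            d = np.max(np.abs(fg - [r, c]), axis=1).min()
            band[r, c] = d <= band_width
    bv = image[band]
    band_mean = bv.mean() if bv.size else 0.0
    band_std = np.sqrt(((bv - bv.mean()) ** 2).mean()) if bv.size else 0.0

    vmin, vmax = v.min(), v.max()
    counts, _ = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    q = counts / counts.sum()
    nz = q[q > 0]
    m3 = ((v - mean) ** 3).mean()
    m4 = ((v - mean) ** 4).mean()
    return {
        "Density": mean,
        "Density_STD": std,
        "Gradient_Mean": grad.mean(),
        "Gradient_STD": np.sqrt(((grad - grad.mean()) ** 2).mean()),
        "ISO_Intensity": np.mean(np.abs(v - mean) <= 0.1 * abs(mean)),
        "Fluctuation_Mean": fluct.mean(),
        "Fluctuation_STD": np.sqrt(((fluct - fluct.mean()) ** 2).mean()),
        "Mean_Contrast": (mean - band_mean) / (mean + band_mean),
        "Contrast": (vmax - vmin) / (vmax + vmin),
        "Skewness": m3 / std**3,
        "Kurtosis": m4 / std**4 - 3.0,
        "STD_Ratio": std / band_std,
        "Energy": (v**2).sum(),
        "Entropy": -(nz * np.log2(nz)).sum(),
        "Max_Intensity": vmax,
        "MAD": np.abs(v - mean).mean(),
        "Median": np.median(v),
        "Minimum": vmin,
        "Range": vmax - vmin,
        "RMS": np.sqrt((v**2).mean()),
        "Uniformity": (q**2).sum(),
    }


class TestDensity:
    def test_constant_roi_conventions(self, disk_roi):
        d = density_features(np.full((80, 80), 50.0), disk_roi)
        assert d["Density_STD"] == 0.0
        assert d["Entropy"] == 0.0
        assert d["Uniformity"] == 1.0
        assert d["Range"] == 0.0
        assert d["Skewness"] == 0.0 and d["Kurtosis"] == 0.0

    def test_fair_coin_histogram(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        img = np.zeros((16, 16))
        img[4:12, 4::2] = 255.0  # half the ROI at 255, half at 0
        d = density_features(img, mask)
        assert d["Entropy"] == pytest.approx(1.0)
        assert d["Uniformity"] == pytest.approx(0.5)

    def test_all_21_match_independent_formulas(self):
        rng = np.random.default_rng(9)
        image = np.round(rng.uniform(10, 240, size=(15, 15)), 1)
        mask = np.zeros((15, 15), bool)
        mask[5:10, 5:10] = True  # enumerated 5x5 patch
        got = density_features(image, mask)
        want = _oracle_density(image, mask)
        assert set(got) == set(DENSITY_NAMES)
        for name in DENSITY_NAMES:
            assert got[name] == pytest.approx(want[name], rel=1e-10), name


class TestGLRLM:
    LEVELS_4x4 = np.array(
        [[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 3, 3], [4, 4, 4, 4]], dtype=np.int64
    )

    def _qroi(self, levels, n_gray):
        from usradiomics import QuantizedROI

        return QuantizedROI(levels=levels, n_gray=n_gray, source_min=0, source_max=1)

    def test_four_by_four_example_horizontal(self):
        g = build_glrlm(self._qroi(self.LEVELS_4x4, 4), 0)
        assert g.n_runs == 6  # four runs of length 2, two of length 4
        assert g.p[0, 1] == 2 and g.p[1, 1] == 2  # levels 1, 2: runs of 2
        assert g.p[2, 3] == 1 and g.p[3, 3] == 1  # levels 3, 4: runs of 4
        assert glrlm_features(g)["RP"] == pytest.approx(6 / 16)

    def test_constant_roi_one_run_per_row(self):
        levels = np.ones((4, 4), dtype=np.int64)
        g = build_glrlm(self._qroi(levels, 1), 0)
        assert g.p[0, 3] == 4 and g.n_runs == 4

    def test_conservation_identity_random_rois(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            levels = rng.integers(0, 5, size=(9, 7))
            q = self._qroi(levels, 4)
            for theta in DIRECTIONS:
                g = build_glrlm(q, theta)
                j = np.arange(1, g.p.shape[1] + 1)
                assert (g.p * j).sum() == (levels > 0).sum()
                assert g.p.sum() == g.n_runs

    def test_matches_brute_force_enumerator(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            levels = rng.integers(0, 5, size=(8, 8))
            q = self._qroi(levels, 4)
            for theta in DIRECTIONS:
                np.testing.assert_array_equal(
                    build_glrlm(q, theta).p, brute_force_glrlm(levels, theta, 4), theta
                )

    def test_stats_match_brute_force(self):
        rng = np.random.default_rng(14)
        levels = rng.integers(1, 5, size=(8, 8))
        q = self._qroi(levels, 4)
        for theta in DIRECTIONS:
            g = build_glrlm(q, theta)
            want = brute_force_glrlm_stats(g.p, g.n_pixels)
            got = glrlm_features(g)
            for k in TEXTURE_STATS:
                assert got[k] == pytest.approx(want[k], rel=1e-12), (theta, k)

    def test_forced_identities(self):
        # all runs length 1 -> SRE = RP = 1; all level 1 -> LGRE = HGRE = 1
        alternating = np.indices((6, 6)).sum(axis=0) % 2 + 1
        f = glrlm_features(build_glrlm(self._qroi(alternating, 2), 0))
        assert f["SRE"] == 1.0 and f["RP"] == 1.0
        ones = np.ones((6, 6), dtype=np.int64)
        f1 = glrlm_features(build_glrlm(self._qroi(ones, 1), 90))
        assert f1["LGRE"] == 1.0 and f1["HGRE"] == 1.0

    def test_rotation_swaps_directions(self, speckle_roi):
        frame, roi = speckle_roi
        q = quantize(frame, roi, 16)
        q_rot = quantize(np.rot90(frame), TumorROI(np.rot90(roi.mask)), 16)
        f = {t: glrlm_features(build_glrlm(q, t)) for t in DIRECTIONS}
        fr = {t: glrlm_features(build_glrlm(q_rot, t)) for t in DIRECTIONS}
        for a, b in ((0, 90), (90, 0), (45, 135), (135, 45)):
            for k in TEXTURE_STATS:
                assert f[a][k] == pytest.approx(fr[b][k], rel=1e-12), (a, b, k)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            build_glrlm(self._qroi(np.ones((4, 4), np.int64), 1), 30)

    def test_empty_matrix_rejected(self):
        from usradiomics import GLRLMatrix

        with pytest.raises(ValueError):
            glrlm_features(GLRLMatrix(np.zeros((2, 2), np.int64), 0, 0, 0))


class TestWavelet:
    def test_constant_image_has_zero_details(self, disk_roi):
        sb = wavelet_decompose(np.full((80, 80), 9.0), disk_roi)
        for k in ("LH", "HL", "HH"):
            np.testing.assert_allclose(sb.subbands[k], 0.0, atol=1e-12)

    def test_haar_ll_is_block_sum_over_two(self, disk_roi):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 255, (80, 80))
        sb = wavelet_decompose(img, disk_roi)
        blocks = img.reshape(40, 2, 40, 2).sum(axis=(1, 3))
        np.testing.assert_allclose(sb.subbands["LL"], blocks / 2.0, atol=1e-9)

    def test_energy_conservation(self, disk_roi):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 255, (80, 80))
        sb = wavelet_decompose(img, disk_roi)
        assert sb.energy() == pytest.approx(np.sum(img**2), rel=1e-8)

    def test_subband_shapes_ceil_rule(self):
        mask = disk_mask((9, 9), radius=4.0)
        img = np.random.default_rng(8).uniform(0, 255, (9, 9))
        sb = wavelet_decompose(img, TumorROI(mask))
        for b in sb.subbands.values():
            assert b.shape == (5, 5)
        assert sb.masks["LL"].shape == (5, 5)

    def test_mask_downsample_any_rule(self):
        mask = np.zeros((8, 8), bool)
        mask[0, 0] = True  # one source pixel -> its 2x2 cell is in-ROI
        mask[4:6, 4:6] = True
        from usradiomics.features import _downsample_mask

        ds = _downsample_mask(mask)
        assert ds[0, 0] and ds[2, 2]
        assert ds.sum() == 2

    def test_too_small_image_rejected(self, disk_roi):
        with pytest.raises(ValueError):
            wavelet_decompose(np.zeros((4, 4)), disk_roi)

    def test_wavelet_feature_counts_by_profile(self, speckle_roi):
        frame, roi = speckle_roi
        sb = wavelet_decompose(frame, roi)
        assert len(wavelet_features(sb, profile="full_334")) == 260
        assert len(wavelet_features(sb, profile="paper_284")) == 210

    def test_constant_input_detail_stds_are_zero(self, disk_roi):
        sb = wavelet_decompose(np.full((80, 80), 77.0), disk_roi)
        w = wavelet_features(sb, profile="full_334")
        for k in ("Density_STD_LH", "Density_STD_HL", "Density_STD_HH"):
            assert w[k] == 0.0

    def test_subband_suffixed_names_present(self):
        names = feature_names("paper_284")
        for expected in ("GLN_HL_90", "Entropy_HH", "LGRE_LL_0", "Gradient_STD_LH"):
            assert expected in names


class TestFeatureVector:
    def test_length_and_group_sizes(self, speckle_roi):
        frame, roi = speckle_roi
        vec = feature_vector(frame, roi)
        assert len(vec) == 284
        names = list(vec.names)
        assert names[:9] == list(MORPHOLOGY_NAMES)
        assert names[9:30] == list(DENSITY_NAMES)
        assert len(names[30:74]) == 44
        assert len(names[74:]) == 210

    def test_full_profile_length(self, speckle_roi):
        frame, roi = speckle_roi
        assert len(feature_vector(frame, roi, profile="full_334")) == 334

    def test_recomputation_is_bit_identical(self, speckle_roi):
        frame, roi = speckle_roi
        a = feature_vector(frame, roi)
        b = feature_vector(frame, roi)
        np.testing.assert_array_equal(a.values, b.values)

    def test_intensity_shift_behavior(self, speckle_roi):
        # +c leaves quantized-texture features unchanged (bin edges follow
        # min/max) and shifts the density mean by exactly c
        frame, roi = speckle_roi
        frame = np.rint(frame)
        a = feature_vector(frame, roi, sigma=0.0)
        b = feature_vector(frame + 10.0, roi, sigma=0.0)
        sa, sb = a.to_series(), b.to_series()
        assert sb["Density"] == sa["Density"] + 10.0
        for stat in TEXTURE_STATS:
            for theta in (0, 45, 90, 135):
                assert sb[f"{stat}_{theta}"] == sa[f"{stat}_{theta}"]

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            feature_names("paper_285")
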