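import numpy as np
import pytest
from skimage.feature import graycomatrix

from mammotex.segment import ROI
from mammotex.texture import (
    ANGLES,
    FEATURE_NAMES,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    DegenerateROIError,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    quantize,
    roi_features,
)

from _oracles import (
    glcm_counts_brute,
    glcm_features_brute,
    glrlm_counts_brute,
    glrlm_features_brute,
)


def _roi(patch, mask=None):
    patch = np.asarray(patch, dtype=np.uint8)
    if mask is None:
        mask = np.ones_like(patch, dtype=bool)
    return ROI(source_id="t", patch=patch, mask=mask, provenance="lesion-centered",
               tissue_class="abnormal", severity="benign")


def _random_quantized(seed, max_side=12, levels=8, with_mask=True):
    rng = np.random.default_rng(seed)
    h, w = rng.integers(3, max_side + 1, 2)
    q = rng.integers(0, levels, (h, w))
    if with_mask and rng.random() < 0.5:
        drop = rng.random((h, w)) < 0.15
        q[drop] = -1
        if (q >= 0).sum() < 4:
            q[:2, :2] = rng.integers(0, levels, (2, 2))
    return q


class TestQuantize:
    def test_full_range_binning(self):
        patch = np.array([[0, 255], [128, 32]], dtype=np.uint8)
        q = quantize(patch, None, 8)
        assert q[0, 1] == 7 and q[0, 0] == 0
        assert q[1, 0] == int(128 / 255 * 8)

    def test_constant_patch_single_level(self):
        q = quantize(np.full((4, 4), 99, dtype=np.uint8), None, 8)
        assert set(np.unique(q)) == {0}

    def test_occupied_levels_bounded(self, rng):
        patch = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        q = quantize(patch, None, 5)
        assert len(np.unique(q[q >= 0])) <= 5

    def test_out_of_mask_sentinel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :] = True
        q = quantize(np.arange(9, dtype=np.uint8).reshape(3, 3), mask, 4)
        assert (q[~mask] == -1).all() and (q[mask] >= 0).all()

    def test_shift_invariance(self, rng):
        patch = rng.integers(10, 120, (8, 8), dtype=np.uint8)
        np.testing.assert_array_equal(
            quantize(patch, None, 8), quantize(patch + 100, None, 8)
        )


class TestGLCM:
    def test_constant_2x2_horizontal(self):
        q = np.zeros((2, 2), dtype=int)
        M = glcm(q, d=1, theta=0, levels=1)
        assert M.counts[0, 0] == 4  # two pairs, counted both directions
        assert M.p[0, 0] == 1.0

    def test_hand_countable_two_level_grid(self):
        q = np.array([[0, 0, 1, 1]] * 4)
        M = glcm(q, d=1, theta=0, levels=2)
        # per row: (0,0), (0,1), (1,1); symmetric doubling, 4 rows
        np.testing.assert_array_equal(M.counts, [[8, 4], [4, 8]])

    def test_transpose_swaps_0_and_90_degrees(self, rng):
        q = rng.integers(0, 4, (6, 8))
        a = glcm(q.T, d=1, theta=0, levels=4).counts
        b = glcm(q, d=1, theta=90, levels=4).counts
        np.testing.assert_array_equal(a, b)

    def test_symmetry_and_normalization(self, rng):
        q = rng.integers(0, 8, (10, 10))
        for theta in ANGLES:
            M = glcm(q, d=1, theta=theta, levels=8)
            np.testing.assert_array_equal(M.counts, M.counts.T)
            assert M.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_skimage_counts(self, rng):
        """Library oracle: symmetric graycomatrix equals ours on full masks."""
        q = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        ours = glcm(q, d=1, theta=0, levels=8).counts
        theirs = graycomatrix(q, [1], [0], levels=8, symmetric=True)[:, :, 0, 0]
        np.testing.assert_array_equal(ours, theirs)

    def test_degenerate_roi_raises(self):
        q = np.array([[0, -1], [-1, -1]])
        with pytest.raises(DegenerateROIError):
            glcm(q, d=1, theta=0, levels=2)

    def test_bad_angle_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            glcm(np.zeros((3, 3), dtype=int), theta=30)


class TestGLCMFeatures:
    def test_constant_image_closed_forms(self):
        M = glcm(np.zeros((4, 4), dtype=int), d=1, theta=0, levels=1)
        f = glcm_features(M)
        assert f["glcm_contrast"] == 0
        assert f["glcm_energy"] == 1
        assert f["glcm_entropy"] == 0
        assert f["glcm_max_probability"] == 1

    def test_checkerboard_closed_forms(self):
        q = np.indices((6, 6)).sum(axis=0) % 2
        f = glcm_features(glcm(q, d=1, theta=0, levels=2))
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(0.5)  # p = [[0,.5],[.5,0]]

    def test_all_22_names_present_and_finite(self, rng):
        q = rng.integers(0, 8, (9, 9))
        f = glcm_features(glcm(q, d=1, theta=45, levels=8))
        assert list(f) == GLCM_FEATURE_NAMES
        assert all(np.isfinite(v) for v in f.values())

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        q = _random_quantized(seed)
        for theta in ANGLES:
            P = glcm_counts_brute(q, 1, theta, 8)
            if P.sum() == 0:
                continue
            ours = glcm_features(glcm(q, d=1, theta=theta, levels=8))
            np.testing.assert_array_equal(glcm(q, d=1, theta=theta, levels=8).counts, P)
            expected = glcm_features_brute(P)
            for name in GLCM_FEATURE_NAMES:
                assert ours[name] == pytest.approx(expected[name], rel=1e-10, abs=1e-12), name


class TestGLRLM:
    def test_hand_counted_row(self):
        q = np.array([[5, 5, 5, 2]])
        R = glrlm(q, theta=0, levels=6)
        assert R.counts[5, 2] == 1 and R.counts[2, 0] == 1
        assert R.Nr == 2

    def test_constant_rows_single_runs(self):
        q = np.zeros((3, 7), dtype=int)
        R = glrlm(q, theta=0, levels=1)
        assert R.counts[0, 6] == 3 and R.Nr == 3
        j = np.arange(1, R.counts.shape[1] + 1)
        assert (R.counts * j).sum() == R.Np == 21

    @pytest.mark.parametrize("theta", ANGLES)
    def test_run_pixel_conservation(self, theta, rng):
        q = rng.integers(0, 8, (8, 8))
        q[rng.random((8, 8)) < 0.2] = -1
        R = glrlm(q, theta=theta, levels=8)
        j = np.arange(1, R.counts.shape[1] + 1)
        assert (R.counts * j).sum() == R.Np == (q >= 0).sum()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="mask"):
            glrlm(np.full((3, 3), -1), theta=0, levels=2)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        q = _random_quantized(seed + 500)
        for theta in ANGLES:
            R = glrlm(q, theta=theta, levels=8)
            Rb, Npb = glrlm_counts_brute(q, theta, 8)
            np.testing.assert_array_equal(R.counts, Rb)
            assert R.Np == Npb
            ours = glrlm_features(R)
            expected = glrlm_features_brute(Rb, Npb)
            for name in GLRLM_FEATURE_NAMES:
                assert ours[name] == pytest.approx(expected[name], rel=1e-10), name


class TestGLRLMFeatures:
    def test_single_short_run(self):
        q = np.array([[3]])
        f = glrlm_features(glrlm(q, theta=0, levels=4))
        assert f["glrlm_sre"] == 1 and f["glrlm_lre"] == 1 and f["glrlm_rp"] == 1

    def test_constant_4x4_closed_forms(self):
        f = glrlm_features(glrlm(np.zeros((4, 4), dtype=int), theta=0, levels=1))
        assert f["glrlm_sre"] == pytest.approx(1 / 16)
        assert f["glrlm_lre"] == pytest.approx(16)
        assert f["glrlm_rp"] == pytest.approx(4 / 16)


class TestROIFeatures:
    def test_exactly_33_features(self, rng):
        roi = _roi(rng.integers(0, 256, (32, 32), dtype=np.uint8))
        f = roi_features(roi)
        assert list(f) == FEATURE_NAMES
        assert len(f) == 33
        assert sum(n.startswith("glcm_") for n in f) == 22
        assert sum(n.startswith("glrlm_") for n in f) == 11
        assert all(np.isfinite(v) for v in f.values())

    def test_feature_range_contracts(self, rng):
        roi = _roi(rng.integers(0, 256, (24, 24), dtype=np.uint8))
        f = roi_features(roi)
        assert 0 < f["glcm_energy"] <= 1
        assert f["glcm_entropy"] >= 0
        assert 0 < f["glrlm_rp"] <= 1

    def test_isotropic_roi_average_equals_single_angle(self):
        roi = _roi(np.full((8, 8), 40, dtype=np.uint8))
        f = roi_features(roi)
        q = quantize(roi.patch, roi.mask, 8)
        single = glcm_features(glcm(q, d=1, theta=0, levels=8))
        assert f["glcm_energy"] == pytest.approx(single["glcm_energy"])
        assert f["glcm_contrast"] == pytest.approx(single["glcm_contrast"])

    def test_angle_average_invariant_under_90_degree_rotation(self, rng):
        """The angle set is closed under 90-degree rotation, so the
        angle-averaged features are exactly invariant."""
        patch = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        f1 = roi_features(_roi(patch))
        f2 = roi_features(_roi(np.rot90(patch)))
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-9), name

    def test_intensity_shift_invariance(self, rng):
        patch = rng.integers(10, 120, (16, 16), dtype=np.uint8)
        f1 = roi_features(_roi(patch))
        f2 = roi_features(_roi(patch + 60))
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-12), name

    def test_mean_over_four_angles(self, rng):
        patch = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        roi = _roi(patch)
        q = quantize(patch, roi.mask, 8)
        per_angle = [
            glcm_features(glcm(q, d=1, theta=t, levels=8))["glcm_contrast"]
            for t in ANGLES
        ]
        assert roi_features(roi)["glcm_contrast"] == pytest.approx(np.mean(per_angle))
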