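"""Slice-wise GLCM texture protocol against brute-force oracles.

The oracle builds the co-occurrence matrix by an explicit double loop over
every pixel pair and evaluates each statistic as a direct sum over the full
matrix — independent of the vectorised implementation.
"""

import math

import numpy as np
import pytest

from strokemark.errors import EmptyLesionError, UndefinedFeatureError
from strokemark.texture import (
    _ANGLE_OFFSETS,
    GLCMConfig,
    TextureFeatures,
    glcm_slice,
    haralick_features,
    lesion_texture,
    normalize_to_8bit,
    slice_entropy,
)
from strokemark.imaging import BinaryMask, ScalarVolume

from conftest import make_grid


# ------------------------------------------------------------------ oracles


def glcm_bruteforce(levels2d, mask2d, distance, angle_deg, levels=256):
    """Double-loop pair enumeration; symmetrised and normalised."""
    dr, dc = _ANGLE_OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    nr, nc = levels2d.shape
    counts = np.zeros((levels, levels))
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and mask2d[r, c] and mask2d[r2, c2]:
                counts[levels2d[r, c], levels2d[r2, c2]] += 1
    n_pairs = int(counts.sum())
    counts = counts + counts.T
    if counts.sum() > 0:
        counts /= counts.sum()
    return counts, n_pairs


def haralick_bruteforce(p):
    """Direct sums over the full matrix for all six statistics."""
    L = p.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    contrast = ((i - j) ** 2 * p).sum()
    dissimilarity = (np.abs(i - j) * p).sum()
    homogeneity = (p / (1 + np.abs(i - j))).sum()
    asm = (p**2).sum()
    energy = math.sqrt(asm)
    p_i, p_j = p.sum(1), p.sum(0)
    mu_i, mu_j = (np.arange(L) * p_i).sum(), (np.arange(L) * p_j).sum()
    s_i = math.sqrt((((np.arange(L) - mu_i) ** 2) * p_i).sum())
    s_j = math.sqrt((((np.arange(L) - mu_j) ** 2) * p_j).sum())
    if s_i * s_j < 1e-12:
        corr = 1.0
    else:
        corr = (((i - mu_i) * (j - mu_j) * p).sum()) / (s_i * s_j)
    return np.array([contrast, dissimilarity, homogeneity, asm, energy, corr])


def _impl_features(levels2d, mask2d, d, ang):
    return np.array(haralick_features(glcm_slice(levels2d, mask2d, d, ang)))


# -------------------------------------------------------------- discretising


class TestNormalize:
    def _vol_mask(self, values):
        arr = np.asarray(values, float).reshape(-1, 1, 1)
        grid = make_grid(arr.shape)
        mask = BinaryMask(grid, np.ones(arr.shape, np.uint8))
        return ScalarVolume(grid, arr), mask

    def test_endpoints_map_to_0_and_255(self):
        vol, mask = self._vol_mask([100.0, 300.0])
        assert list(normalize_to_8bit(vol, mask).ravel()) == [0, 255]

    def test_midpoint_floors(self):
        vol, mask = self._vol_mask([100.0, 200.0, 300.0])
        assert list(normalize_to_8bit(vol, mask).ravel()) == [0, 127, 255]

    def test_constant_lesion_maps_to_zero(self):
        vol, mask = self._vol_mask([7.0, 7.0, 7.0])
        assert list(normalize_to_8bit(vol, mask).ravel()) == [0, 0, 0]

    def test_empty_mask_raises(self):
        vol, mask = self._vol_mask([1.0, 2.0])
        empty = BinaryMask(mask.grid, np.zeros(mask.grid.shape, np.uint8))
        with pytest.raises(EmptyLesionError):
            normalize_to_8bit(vol, empty)


# -------------------------------------------------------------------- GLCMs


class TestGLCMSlice:
    def test_constant_patch_single_cell(self):
        lv = np.zeros((2, 2), np.int64)
        g = glcm_slice(lv, np.ones((2, 2), bool), 1, 0)
        assert g.p[0, 0] == pytest.approx(1.0)
        assert g.p.sum() == pytest.approx(1.0)
        assert g.valid_pair_count == 2

    def test_single_pixel_has_no_pairs(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        g = glcm_slice(np.zeros((3, 3), np.int64), m, 1, 0)
        assert g.valid_pair_count == 0
        with pytest.raises(UndefinedFeatureError):
            haralick_features(g)

    @pytest.mark.parametrize("d", [1, 2, 3])
    @pytest.mark.parametrize("ang", [0, 45, 90, 135])
    def test_matches_bruteforce_on_random_slices(self, rng, d, ang):
        for _ in range(5):
            n = int(rng.integers(6, 12))
            lv = rng.integers(0, 256, size=(n, n))
            m = rng.random((n, n)) < 0.7
            g = glcm_slice(lv, m, d, ang)
            p_oracle, n_oracle = glcm_bruteforce(lv, m, d, ang)
            np.testing.assert_allclose(g.p, p_oracle, atol=1e-12)
            assert g.valid_pair_count == n_oracle
            if n_oracle:
                np.testing.assert_allclose(
                    _impl_features(lv, m, d, ang), haralick_bruteforce(p_oracle), atol=1e-10
                )

    def test_symmetric_and_normalised(self, rng):
        lv = rng.integers(0, 256, size=(8, 8))
        g = glcm_slice(lv, np.ones((8, 8), bool), 2, 45)
        np.testing.assert_allclose(g.p, g.p.T, atol=0)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-9)


class TestHaralick:
    def test_constant_region_conventions(self):
        lv = np.zeros((4, 4), np.int64)
        feats = _impl_features(lv, np.ones((4, 4), bool), 1, 0)
        np.testing.assert_allclose(feats, [0, 0, 1, 1, 1, 1], atol=1e-12)

    def test_checkerboard_closed_forms(self):
        # alternating 0/255 columns: horizontal neighbours always differ by 255
        lv = np.zeros((8, 8), np.int64)
        lv[:, 1::2] = 255
        contrast, dissim, homog, asm, energy, _ = _impl_features(lv, np.ones((8, 8), bool), 1, 0)
        assert contrast == pytest.approx(255**2)
        assert dissim == pytest.approx(255.0)
        assert homog == pytest.approx(1 / 256)
        assert asm == pytest.approx(0.5)
        assert energy == pytest.approx(math.sqrt(0.5))

    def test_energy_squared_is_asm(self, rng):
        lv = rng.integers(0, 64, size=(10, 10))
        _, _, _, asm, energy, _ = _impl_features(lv, np.ones((10, 10), bool), 1, 90)
        assert energy**2 == pytest.approx(asm, abs=1e-12)


class TestEntropy:
    def test_constant_slice_zero_bits(self):
        assert slice_entropy(np.zeros((4, 4), np.int64), np.ones((4, 4), bool)) == 0.0

    def test_uniform_all_levels_eight_bits(self):
        lv = np.arange(256).reshape(16, 16)
        assert slice_entropy(lv, np.ones((16, 16), bool)) == pytest.approx(8.0)

    def test_three_quarter_one_quarter(self):
        lv = np.array([[0, 0], [0, 1]])
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert slice_entropy(lv, np.ones((2, 2), bool)) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.8113, abs=1e-4)


# ------------------------------------------------------------ subject level


def _lesion_volume(arr, mask_arr, spacing=(1.0, 1.0, 1.0)):
    grid = make_grid(arr.shape, spacing)
    return ScalarVolume(grid, arr), BinaryMask(grid, mask_arr.astype(np.uint8))


class TestLesionTexture:
    def test_returns_seven_features(self, rng):
        arr = rng.normal(500, 50, (8, 8, 3))
        mask = np.zeros((8, 8, 3), np.uint8)
        mask[2:7, 2:7, :] = 1
        vol, m = _lesion_volume(arr, mask)
        assert len(lesion_texture(vol, m).as_tuple()) == 7

    def test_single_slice_lesion_equals_slice_features(self, rng):
        arr = rng.normal(500, 80, (9, 9, 5))
        mask = np.zeros((9, 9, 5), np.uint8)
        mask[1:8, 1:8, 2] = 1
        vol, m = _lesion_volume(arr, mask)
        subject = lesion_texture(vol, m)

        # oracle: normalise over the lesion, average brute-force features
        # over all (d, angle) offsets of that one slice
        lv3 = normalize_to_8bit(vol, m)
        lv, msk = lv3[:, :, 2], mask[:, :, 2].astype(bool)
        per = []
        for d in (1, 2, 3):
            for ang in (0, 45, 90, 135):
                p, n = glcm_bruteforce(lv, msk, d, ang)
                if n:
                    per.append(haralick_bruteforce(p))
        expected = np.mean(per, axis=0)
        np.testing.assert_allclose(np.array(subject.as_tuple()[:6]), expected, atol=1e-10)
        assert subject.entropy == pytest.approx(slice_entropy(lv, msk), abs=1e-12)

    def test_constant_lesion_conventions(self):
        arr = np.full((6, 6, 4), 3.3)
        mask = np.zeros((6, 6, 4), np.uint8)
        mask[1:5, 1:5, 1:3] = 1
        vol, m = _lesion_volume(arr, mask)
        t = lesion_texture(vol, m)
        np.testing.assert_allclose(t.as_tuple(), [0, 0, 1, 1, 1, 1, 0], atol=1e-12)

    def test_multi_slice_matches_dense_route(self, rng):
        """Sparse fast path equals the dense GLCM route on a 3D lesion."""
        arr = rng.normal(600, 90, (10, 10, 4))
        mask = (rng.random((10, 10, 4)) < 0.6).astype(np.uint8)
        mask[4:7, 4:7, :] = 1
        vol, m = _lesion_volume(arr, mask)
        subject = lesion_texture(vol, m)

        lv3 = normalize_to_8bit(vol, m)
        slices = []
        entropies = []
        for z in range(4):
            msk = mask[:, :, z].astype(bool)
            if not msk.any():
                continue
            entropies.append(slice_entropy(lv3[:, :, z], msk))
            per = []
            for d in (1, 2, 3):
                for ang in (0, 45, 90, 135):
                    p, n = glcm_bruteforce(lv3[:, :, z], msk, d, ang)
                    if n:
                        per.append(haralick_bruteforce(p))
            if per:
                slices.append(np.mean(per, axis=0))
        expected = np.mean(slices, axis=0)
        np.testing.assert_allclose(np.array(subject.as_tuple()[:6]), expected, atol=1e-10)
        assert subject.entropy == pytest.approx(float(np.mean(entropies)), abs=1e-12)

    def test_intensity_affine_invariance(self, rng):
        """a*I + b leaves the normalised level map, hence all features, unchanged."""
        arr = rng.normal(500, 60, (8, 8, 3))
        mask = np.zeros((8, 8, 3), np.uint8)
        mask[1:7, 1:7, :] = 1
        vol, m = _lesion_volume(arr, mask)
        vol2 = ScalarVolume(vol.grid, 3.7 * arr + 123.0)
        t1, t2 = lesion_texture(vol, m), lesion_texture(vol2, m)
        np.testing.assert_allclose(t1.as_tuple(), t2.as_tuple(), atol=1e-9)

    def test_translation_within_slice_invariance(self, rng):
        arr = rng.normal(0, 1, (12, 12, 1))
        mask = np.zeros((12, 12, 1), np.uint8)
        mask[1:6, 1:6, 0] = 1
        vol, m = _lesion_volume(arr, mask)
        t1 = lesion_texture(vol, m)
        arr2 = np.roll(arr, (5, 4), axis=(0, 1))
        mask2 = np.roll(mask, (5, 4), axis=(0, 1))
        vol2, m2 = _lesion_volume(arr2, mask2)
        np.testing.assert_allclose(t1.as_tuple(), lesion_texture(vol2, m2).as_tuple(), atol=1e-10)

    def test_scattered_voxels_undefined(self):
        mask = np.zeros((9, 9, 2), np.uint8)
        mask[0, 0, 0] = mask[5, 5, 1] = 1  # no pair at any offset
        arr = np.random.default_rng(1).normal(size=(9, 9, 2))
        vol, m = _lesion_volume(arr, mask)
        with pytest.raises(UndefinedFeatureError):
            lesion_texture(vol, m)

    def test_per_slice_normalisation_switch(self, rng):
        arr = rng.normal(500, 60, (8, 8, 3))
        arr[:, :, 2] += 400.0  # strong slice-wise offset
        mask = np.zeros((8, 8, 3), np.uint8)
        mask[1:7, 1:7, :] = 1
        vol, m = _lesion_volume(arr, mask)
        global_t = lesion_texture(vol, m)
        per_slice_t = lesion_texture(vol, m, GLCMConfig(normalize_per_slice=True))
        assert global_t.as_tuple() != per_slice_t.as_tuple()
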