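"""Normalization algebra against independent direct-formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from im2im.core import AxisSpec, NDImage
from im2im.preprocess import (
    DegenerateIntensityError,
    apply_stain_norm,
    center_chunk_bounds,
    center_normalize_array,
    fit_stain_reference,
    pad_to_valid,
    percentile_normalize_array,
    standard_normalize_array,
    un_normalize_array,
)


def oracle_percentile(arr, lo, hi, a, b):
    """Direct formula on the sorted array with linear interpolation."""
    p_lo, p_hi = np.percentile(arr, [lo, hi])
    return np.clip(arr, p_lo, p_hi - 0.0) * 0 + (
        (np.clip(arr, p_lo, p_hi) - p_lo) / (p_hi - p_lo) * (b - a) + a
    )


class TestPercentile:
    def test_affine_endpoints_and_midpoint(self):
        img = np.arange(101, dtype=np.float32)[None]
        out = percentile_normalize_array(img, lo=0, hi=100, out_range=(-1, 1))[0]
        assert out[0] == -1.0 and out[100] == 1.0 and out[50] == 0.0

    def test_matches_direct_formula_with_interpolated_percentiles(self):
        img = np.arange(101, dtype=np.float32)[None]
        out = percentile_normalize_array(img, lo=0.5, hi=99.5)[0]
        p_lo, p_hi = np.percentile(img[0], [0.5, 99.5])
        expected = (np.clip(50.0, p_lo, p_hi) - p_lo) / (p_hi - p_lo) * 2 - 1
        assert out[50] == pytest.approx(expected, abs=1e-6)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateIntensityError):
            percentile_normalize_array(np.full((1, 8, 8), 3.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_arrays_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        arr = r.normal(0, 10, size=(1, 17, 13)).astype(np.float32)
        out = percentile_normalize_array(arr, lo=2, hi=98, out_range=(-1, 1))
        assert np.allclose(out, oracle_percentile(arr, 2, 98, -1, 1), atol=1e-5)
        assert out.min() >= -1 - 1e-6 and out.max() <= 1 + 1e-6

    def test_permutation_invariance_of_mapping(self, rng):
        arr = rng.normal(size=(1, 64)).astype(np.float32)
        perm = rng.permutation(64)
        out = percentile_normalize_array(arr)[0]
        out_perm = percentile_normalize_array(arr[:, perm])[0]
        assert np.allclose(out[perm], out_perm, atol=1e-6)


class TestStandard:
    def test_two_point_example(self):
        out = standard_normalize_array(np.array([[1.0, 3.0]], dtype=np.float32))
        assert np.allclose(out, [[-1.0, 1.0]])

    def test_output_moments(self, rng):
        arr = rng.normal(5, 3, size=(2, 32, 32)).astype(np.float32)
        out = standard_normalize_array(arr)
        for c in range(2):
            assert abs(out[c].mean()) < 1e-5
            assert abs(out[c].std() - 1) < 1e-5

    def test_idempotent_up_to_float(self, rng):
        arr = rng.normal(size=(1, 50)).astype(np.float32)
        once = standard_normalize_array(arr)
        twice = standard_normalize_array(once)
        assert np.allclose(once, twice, atol=1e-5)

    def test_zero_std_raises(self):
        with pytest.raises(DegenerateIntensityError):
            standard_normalize_array(np.ones((1, 4, 4), dtype=np.float32))


class TestCenter:
    def test_hand_computed_chunk_stats(self):
        # planes constant {0,2,4,0}; fraction .5 -> chunk planes {2,4}: mu=3, sd=1
        vol = np.zeros((1, 4, 2, 2), dtype=np.float32)
        for z, v in enumerate([0.0, 2.0, 4.0, 0.0]):
            vol[0, z] = v
        out = center_normalize_array(vol, center_fraction=0.5)
        assert np.allclose(out[0, :, 0, 0], [-3.0, -1.0, 1.0, -3.0])

    def test_fraction_one_equals_standard(self, rng):
        vol = rng.normal(size=(1, 6, 8, 8)).astype(np.float32)
        assert np.allclose(
            center_normalize_array(vol, 1.0),
            standard_normalize_array(vol),
            atol=1e-6,
        )

    def test_single_plane_rejected(self):
        with pytest.raises(ValueError):
            center_normalize_array(np.zeros((1, 1, 4, 4), dtype=np.float32))

    @pytest.mark.parametrize(
        "n_z,fraction,expected",
        [(4, 0.5, (1, 3)), (5, 0.5, (1, 4)), (8, 0.25, (3, 5)), (3, 1.0, (0, 3))],
    )
    def test_chunk_bounds(self, n_z, fraction, expected):
        assert center_chunk_bounds(n_z, fraction) == expected


class TestUnNormalize:
    def test_percentile_inversion_exact(self, rng):
        arr = rng.normal(10, 4, size=(1, 16, 16)).astype(np.float32)
        stats = {}
        out = percentile_normalize_array(arr, 0, 100, (-1, 1), stats_out=stats)
        back = un_normalize_array(out, stats)
        assert np.allclose(back, arr, atol=1e-4)

    def test_zscore_inversion_via_stats(self, rng):
        arr = rng.normal(10, 4, size=(1, 16, 16)).astype(np.float32)
        stats = {}
        out = standard_normalize_array(arr, stats_out=stats)
        assert np.allclose(un_normalize_array(out, stats), arr, atol=1e-4)


class TestStain:
    def _tile(self, rng, shift=0.0):
        base = rng.uniform(0.3, 0.9, size=(32, 32, 3)) + shift
        return np.clip(base, 0, 1).astype(np.float32)

    def test_self_normalization_identity(self, rng):
        tile = self._tile(rng)
        ref = fit_stain_reference(tile)
        out = apply_stain_norm(tile, ref)
        assert np.allclose(out, tile, atol=0.02)  # color-space round trip

    def test_stats_transferred(self, rng):
        from skimage.color import rgb2lab

        ref_tile = self._tile(rng)
        tile = np.clip(self._tile(rng) * 0.7 + 0.1, 0, 1)
        ref = fit_stain_reference(ref_tile)
        out = apply_stain_norm(tile, ref)
        lab = rgb2lab(out)
        for i in range(3):
            assert lab[..., i].mean() == pytest.approx(ref.means[i], abs=0.5)
            assert lab[..., i].std() == pytest.approx(ref.stds[i], abs=0.5)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            fit_stain_reference(np.zeros((4, 8, 8)))


class TestPadToValid:
    def test_ceiling_arithmetic(self, rng):
        arr = rng.normal(size=(1, 30, 30)).astype(np.float32)
        padded, crop = pad_to_valid(arr, (8, 8))
        assert padded.shape == (1, 32, 32)
        assert crop.crop(padded).shape == (1, 30, 30)
        assert np.array_equal(crop.crop(padded), arr)

    def test_valid_shape_is_identity(self, rng):
        arr = rng.normal(size=(1, 32, 32)).astype(np.float32)
        padded, crop = pad_to_valid(arr, (8, 8))
        assert padded is arr

    def test_anisotropic_factors_pad_only_xy(self, rng):
        arr = rng.normal(size=(1, 5, 30, 30)).astype(np.float32)
        padded, _ = pad_to_valid(arr, (1, 8, 8))
        assert padded.shape == (1, 5, 32, 32)
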