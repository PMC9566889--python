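import numpy as np
import pytest
from hypothesis import given, strategies as st

import petstratify as ps
from petstratify.preprocess import FWHM_TO_SIGMA, mask_voxel_index, scatter_to_volume


def _dense_gaussian_impulse(shape, center, sigma_vox):
    """Independent oracle: sampled separable Gaussian kernel over the full
    grid (no truncation), normalized per axis."""
    out = 1.0
    kernels = []
    for axis, s in enumerate(shape):
        x = np.arange(s, dtype=np.float64) - center[axis]
        k = np.exp(-0.5 * (x / sigma_vox[axis]) ** 2)
        kernels.append(k / k.sum())
    out = kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
    return out


class TestSmoothGaussian:
    def test_sigma_conversion(self):
        # FWHM 8 mm on 2 mm voxels -> sigma = 8 / (2*sqrt(2 ln2)) / 2 = 1.6986 voxels
        assert 8.0 * FWHM_TO_SIGMA / 2.0 == pytest.approx(1.69864, abs=1e-4)

    def test_constant_preserved_everywhere(self):
        vol = ps.Volume.from_voxel_size(np.full((10, 10, 10), 3.0), (2.0, 2.0, 2.0))
        out = ps.smooth_gaussian(vol, fwhm_mm=8.0)
        np.testing.assert_allclose(out.data, 3.0, rtol=1e-6)

    def test_impulse_matches_dense_convolution_oracle(self):
        shape = (33, 33, 33)
        center = (16, 16, 16)
        data = np.zeros(shape)
        data[center] = 1.0
        vol = ps.Volume.from_voxel_size(data, (2.0, 2.0, 2.0))
        out = ps.smooth_gaussian(vol, fwhm_mm=8.0)
        sigma = np.full(3, 8.0 * FWHM_TO_SIGMA / 2.0)
        oracle = _dense_gaussian_impulse(shape, center, sigma)
        # compare away from the boundary (renormalization only acts there)
        sl = tuple([slice(4, -4)] * 3)
        assert np.max(np.abs(out.data[sl] - oracle[sl])) < 1e-6

    def test_nonpositive_fwhm_rejected(self):
        vol = ps.Volume.from_voxel_size(np.ones((8, 8, 8)))
        with pytest.raises(ValueError):
            ps.smooth_gaussian(vol, 0.0)


class TestProportionalScale:
    def _mask(self, shape=(8, 8, 8)):
        return ps.BrainMask.from_voxel_size(np.ones(shape, dtype=bool))

    def test_constant_hits_target(self):
        mask = self._mask()
        vol = ps.Volume.from_voxel_size(np.full(mask.shape, 7.0))
        out = ps.proportional_scale(vol, mask, target=50.0)
        np.testing.assert_allclose(out.data, 50.0, rtol=1e-12)

    def test_mask_mean_equals_target(self, rng):
        mask = self._mask()
        vol = ps.Volume.from_voxel_size(rng.random(mask.shape) + 0.5)
        out = ps.proportional_scale(vol, mask, target=50.0)
        assert out.data[mask.data].mean() == pytest.approx(50.0, rel=1e-9)

    def test_halving_example(self):
        mask = self._mask()
        vol = ps.Volume.from_voxel_size(np.full(mask.shape, 2.0))
        out = ps.proportional_scale(vol, mask, target=1.0)
        np.testing.assert_allclose(out.data, 1.0, rtol=1e-12)

    @given(c=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    def test_scale_invariance_any_positive_factor(self, c):
        rng = np.random.default_rng(7)
        mask = ps.BrainMask.from_voxel_size(np.ones((6, 6, 6), dtype=bool))
        data = rng.random(mask.shape) + 0.5
        a = ps.proportional_scale(ps.Volume.from_voxel_size(data), mask)
        b = ps.proportional_scale(ps.Volume.from_voxel_size(data * c), mask)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_power_of_two_factor_is_bit_exact(self, rng):
        mask = ps.BrainMask.from_voxel_size(np.ones((6, 6, 6), dtype=bool))
        data = rng.random(mask.shape) + 0.5
        a = ps.proportional_scale(ps.Volume.from_voxel_size(data), mask)
        b = ps.proportional_scale(ps.Volume.from_voxel_size(data * 4.0), mask)
        assert np.array_equal(a.data, b.data)

    def test_nonpositive_mask_mean_rejected(self):
        mask = self._mask()
        vol = ps.Volume.from_voxel_size(np.zeros(mask.shape))
        with pytest.raises(ValueError, match="non-positive"):
            ps.proportional_scale(vol, mask)


class TestVectorize:
    def test_identical_volumes_identical_rows(self, tiny_config):
        cfg = ps.SimulationConfig(**{**tiny_config.__dict__, "noise_sd": 0.0,
                                     "global_scale_sd": 0.0, "effect_regions": [],
                                     "n_per_class": (3, 3)})
        fm = ps.vectorize(ps.simulate_cohort(cfg))
        assert np.array_equal(fm.values[0], fm.values[1])
        assert np.array_equal(fm.values[0], fm.values[5])

    def test_global_factor_removed(self, tiny_cohort):
        fm0 = ps.vectorize(tiny_cohort)
        sid, label, vol = tiny_cohort.subjects[2]
        scaled = ps.Volume(data=vol.data * 10.0, affine=vol.affine)
        subjects = list(tiny_cohort.subjects)
        subjects[2] = (sid, label, scaled)
        fm1 = ps.vectorize(ps.Cohort(subjects=subjects, mask=tiny_cohort.mask))
        np.testing.assert_allclose(fm1.values, fm0.values, rtol=1e-12)

    def test_row_means_equal_target(self, tiny_features):
        np.testing.assert_allclose(tiny_features.values.mean(axis=1), 50.0, rtol=1e-6)

    def test_voxel_index_round_trip(self, tiny_cohort, tiny_features):
        row = tiny_features.values[0]
        vol = scatter_to_volume(row, tiny_features.voxel_index, tiny_cohort.mask)
        # re-extract in the documented order
        idx = tiny_features.voxel_index
        assert np.array_equal(vol.data[idx[:, 0], idx[:, 1], idx[:, 2]], row)
        assert np.all(vol.data[~tiny_cohort.mask.data] == 0)

    def test_voxel_order_is_kji_ascending(self):
        mask = ps.BrainMask.from_voxel_size(np.ones((2, 2, 2), dtype=bool))
        idx = mask_voxel_index(mask)
        kji = [(k, j, i) for (i, j, k) in map(tuple, idx)]
        assert kji == sorted(kji)

    def test_pipeline_order_is_smooth_then_scale(self, tiny_cohort):
        """Scaling by the raw-volume mask mean (scale -> smooth) gives a
        different matrix than the implemented smooth -> scale order, because
        renormalized smoothing changes the mask mean."""
        mask = tiny_cohort.mask
        fm = ps.vectorize(tiny_cohort, fwhm_mm=8.0, target=50.0)
        idx = fm.voxel_index
        _, _, vol = tiny_cohort.subjects[0]
        manual = ps.proportional_scale(ps.smooth_gaussian(vol, 8.0), mask, 50.0)
        np.testing.assert_array_equal(
            manual.data[idx[:, 0], idx[:, 1], idx[:, 2]], fm.values[0])
        swapped = ps.smooth_gaussian(ps.proportional_scale(vol, mask, 50.0), 8.0)
        assert not np.allclose(
            swapped.data[idx[:, 0], idx[:, 1], idx[:, 2]], fm.values[0])

    def test_grid_mismatch_rejected(self, tiny_cohort):
        bad_mask = ps.BrainMask.from_voxel_size(np.ones((5, 5, 5), dtype=bool))
        with pytest.raises(ValueError, match="grid"):
            ps.vectorize(tiny_cohort, mask=bad_mask)

    def test_empty_cohort_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="empty"):
            ps.vectorize(ps.Cohort(subjects=[], mask=tiny_cohort.mask))
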