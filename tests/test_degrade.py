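"""Acquisition simulator: parameter draws, blur, slice sampling, artifacts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthosr.degrade import (AcquisitionParams, ArtifactConfig, add_noise,
                             augment_intensity, blur_along_axis,
                             extract_slices, inject_motion, normalize_window,
                             sample_acquisition_params, simulate_pair)
from orthosr.volumes import VolumeGrid


def _vol(values, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(values, dtype=float), spacing)


class TestAcquisitionParams:
    def test_bounds_enforced(self):
        AcquisitionParams(3.0, 8.0, 3.0, 12.0, "axial", "coronal")
        with pytest.raises(ValueError):
            AcquisitionParams(2.0, 5.0, 5.0, 5.0, "axial", "coronal")
        with pytest.raises(ValueError):
            AcquisitionParams(5.0, 5.0, 10.0, 5.0, "axial", "coronal")
        with pytest.raises(ValueError):
            AcquisitionParams(5.0, 5.0, 5.0, 5.0, "axial", "axial")

    def test_draw_bounds_and_moments(self):
        rng = np.random.default_rng(0)
        n = 10_000
        draws = [sample_acquisition_params(rng) for _ in range(n)]
        t = np.array([[p.t1, p.t2] for p in draws]).ravel()
        d = np.array([[p.d1, p.d2] for p in draws]).ravel()
        assert np.all((t >= 3.0) & (t <= 8.0))
        assert np.all((d >= t) & (d <= t + 4.0))
        # U(3,8): mean 5.5, sd 5/sqrt(12); d - t ~ U(0,4): mean 2, sd 4/sqrt(12)
        se_t = (5.0 / np.sqrt(12)) / np.sqrt(t.size)
        se_g = (4.0 / np.sqrt(12)) / np.sqrt(t.size)
        assert abs(t.mean() - 5.5) < 3 * se_t
        assert abs((d - t).mean() - 2.0) < 3 * se_g

    def test_axes_distinct_and_offsets_in_range(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = sample_acquisition_params(rng)
            assert p.axis1 != p.axis2
            assert 0.0 <= p.offset1 < p.d1
            assert 0.0 <= p.offset2 < p.d2


class TestBlur:
    def test_sigma_zero_identity(self, rng):
        vol = _vol(rng.random((8, 8, 8)))
        out = blur_along_axis(vol, "axial", 0.0)
        assert np.array_equal(out.values, vol.values)

    def test_constant_preserved(self):
        vol = _vol(np.full((10, 10, 10), 0.7))
        out = blur_along_axis(vol, "coronal", 5.0)
        assert np.allclose(out.values, 0.7, atol=1e-6)

    def test_impulse_matches_analytic_gaussian(self):
        n = 81
        vol = _vol(np.zeros((5, 5, n)))
        vol.values[2, 2, n // 2] = 1.0
        sigma = 4.0
        out = blur_along_axis(vol, "axial", sigma)
        x = np.arange(n) - n // 2
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        assert np.allclose(out.values[2, 2], kernel, atol=1e-4)
        # other positions untouched
        assert np.allclose(out.values[0, 0], 0.0)

    def test_total_intensity_preserved_interior(self, rng):
        vol = _vol(np.zeros((40, 8, 8)))
        vol.values[15:25] = rng.random((10, 8, 8))
        out = blur_along_axis(vol, "sagittal", 2.0)
        assert np.isclose(out.values.sum(), vol.values.sum(), rtol=1e-6)

    def test_sigma_in_mm_not_voxels(self):
        # same world-sigma on a 2 mm grid needs half the voxel sigma
        n = 41
        a = _vol(np.zeros((3, 3, n)), spacing=(1, 1, 2.0))
        a.values[1, 1, n // 2] = 1.0
        out = blur_along_axis(a, "axial", 4.0)
        x = 2.0 * (np.arange(n) - n // 2)
        kernel = np.exp(-0.5 * (x / 4.0) ** 2)
        kernel /= kernel.sum()
        assert np.allclose(out.values[1, 1], kernel, atol=1e-4)


class TestExtractSlices:
    def test_plane_count_arithmetic(self):
        vol = _vol(np.zeros((3, 3, 13)))  # 12 mm extent along axial
        out = extract_slices(vol, "axial", 3.0)
        assert out.shape == (3, 3, 5)
        assert out.spacing[2] == 3.0

    def test_distance_beyond_extent_single_plane(self):
        vol = _vol(np.zeros((3, 3, 5)))
        out = extract_slices(vol, "axial", 50.0)
        assert out.shape[2] == 1

    def test_ramp_sampled_exactly(self):
        n = 21
        vals = np.broadcast_to(0.3 * np.arange(n) + 1.0, (4, 4, n)).copy()
        vol = _vol(vals)
        out = extract_slices(vol, "axial", 2.5, offset_mm=0.5)
        pos = np.arange(0.5, 20.0 + 1e-9, 2.5)
        assert np.allclose(out.values[0, 0], 0.3 * pos + 1.0, atol=1e-12)
        assert out.origin[2] == 0.5

    def test_invalid_inputs(self):
        vol = _vol(np.zeros((3, 3, 5)))
        with pytest.raises(ValueError):
            extract_slices(vol, "axial", -1.0)
        with pytest.raises(ValueError):
            extract_slices(vol, "axial", 2.0, offset_mm=2.0)


class TestMotion:
    def test_sigma_zero_identity(self, rng):
        stack = _vol(rng.random((8, 8, 4)), spacing=(1, 1, 7.0))
        out = inject_motion(stack, "axial", rng, 0.0)
        assert np.array_equal(out.values, stack.values)

    def test_single_slice_pure_shift(self):
        stack = _vol(np.zeros((16, 16, 1)), spacing=(1, 1, 7.0))
        stack.values[8, 8, 0] = 1.0

        class FixedRng:
            def normal(self, loc, scale, size=None):
                return np.array([2.0, 0.0])

        out = inject_motion(stack, "axial", FixedRng(), 1.0)
        # content moves by +2 voxels along the first in-plane axis
        assert out.values[10, 8, 0] == pytest.approx(1.0)

    def test_empirical_shift_sd(self):
        rng = np.random.default_rng(3)
        n_slices = 150
        stack = _vol(np.zeros((31, 31, n_slices)), spacing=(1, 1, 5.0))
        stack.values[15, 15, :] = 1.0
        out = inject_motion(stack, "axial", rng, 1.0)
        # recover per-slice shift from the center of mass
        xs = []
        for s in range(n_slices):
            sl = out.values[:, :, s]
            cx = (sl * np.arange(31)[:, None]).sum() / sl.sum()
            cy = (sl * np.arange(31)[None, :]).sum() / sl.sum()
            xs += [cx - 15.0, cy - 15.0]
        xs = np.asarray(xs)
        se = 1.0 / np.sqrt(2 * xs.size)
        assert abs(xs.std() - 1.0) < 3 * se + 0.05  # + interpolation spread


class TestIntensity:
    def test_identity_augment(self, rng):
        vol = _vol(rng.random((6, 6, 6)))

        out = augment_intensity(vol, rng, (0.0, 0.0), (1.0, 1.0))
        assert np.allclose(out.values, vol.values, atol=1e-12)

    def test_gamma_on_constant(self, rng):
        vol = _vol(np.full((4, 4, 4), 0.5))
        out = augment_intensity(vol, rng, (0.0, 0.0), (2.0, 2.0))
        assert np.allclose(out.values, 0.25, atol=1e-12)

    def test_rejects_out_of_range(self, rng):
        vol = _vol(np.full((4, 4, 4), 2.0))
        with pytest.raises(ValueError):
            augment_intensity(vol, rng, (0.0, 0.0), (1.0, 1.0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(b=st.floats(-0.3, 0.3), g=st.floats(0.3, 3.0), seed=st.integers(0, 100))
    def test_monotone_in_intensity(self, b, g, seed):
        v = np.sort(np.random.default_rng(seed).random(64)).reshape(4, 4, 4)
        vol = _vol(v)
        out = augment_intensity(vol, np.random.default_rng(0), (b, b), (g, g))
        flat = out.values.ravel()
        assert np.all(np.diff(flat) >= -1e-12)


class TestNoise:
    def test_sigma_zero_identity(self, rng):
        vol = _vol(rng.random((6, 6, 6)))
        out = add_noise(vol, rng, 0.0)
        assert np.array_equal(out.values, vol.values)

    def test_rayleigh_mean_on_zero_volume(self):
        rng = np.random.default_rng(5)
        vol = _vol(np.zeros((40, 40, 40)))
        sigma = 0.05
        out = add_noise(vol, rng, sigma)
        expect = sigma * np.sqrt(np.pi / 2)
        sd = sigma * np.sqrt(2 - np.pi / 2)
        se = sd / np.sqrt(out.values.size)
        assert abs(out.values.mean() - expect) < 3 * se
        assert np.all(out.values >= 0)


class TestSimulatePair:
    def test_degenerate_config_reduces_to_blur_and_sampling(self, rng):
        hr = _vol(np.random.default_rng(0).random((32, 32, 32)))
        params = AcquisitionParams(4.0, 5.0, 6.0, 7.0, "axial", "coronal")
        pair = simulate_pair(hr, rng, ArtifactConfig.none(), params,
                             normalized=True)
        for t in pair.targets:
            assert np.array_equal(t.values, hr.values)
        expect = extract_slices(blur_along_axis(hr, "axial", 4.0), "axial", 6.0)
        assert np.allclose(pair.X1.values, np.clip(expect.values, 0, 1),
                           atol=1e-12)
        assert pair.masked_view is None

    def test_spacing_contract(self, rng):
        hr = _vol(np.random.default_rng(1).random((40, 40, 40)))
        pair = simulate_pair(hr, rng, ArtifactConfig())
        ax1 = pair.X1.axis_index(pair.params.axis1)
        ax2 = pair.X2.axis_index(pair.params.axis2)
        assert pair.X1.spacing[ax1] == pytest.approx(pair.params.d1)
        assert pair.X2.spacing[ax2] == pytest.approx(pair.params.d2)
        inplane = [s for i, s in enumerate(pair.X1.spacing) if i != ax1]
        assert inplane == [1.0, 1.0]

    def test_forced_masking(self):
        hr = _vol(np.random.default_rng(2).random((32, 32, 32)))
        cfg = ArtifactConfig(mask_view_prob=1.0)
        pair = simulate_pair(hr, np.random.default_rng(3), cfg)
        assert pair.masked_view in (1, 2)
        blanked = pair.X1 if pair.masked_view == 1 else pair.X2
        other = pair.X2 if pair.masked_view == 1 else pair.X1
        assert not blanked.values.any()
        assert other.values.any()

    def test_reproducible_given_seed(self):
        hr = _vol(np.random.default_rng(4).random((32, 32, 32)))
        pairs = [simulate_pair(hr, np.random.default_rng(99), ArtifactConfig())
                 for _ in range(2)]
        assert np.array_equal(pairs[0].X1.values, pairs[1].X1.values)
        assert np.array_equal(pairs[0].X2.values, pairs[1].X2.values)
        for a, b in zip(pairs[0].targets, pairs[1].targets):
            assert np.array_equal(a.values, b.values)
        assert pairs[0].params.to_dict() == pairs[1].params.to_dict()

    def test_rejects_anisotropic_input(self, rng):
        hr = VolumeGrid(np.zeros((10, 10, 10)), (1.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="isotropic"):
            simulate_pair(hr, rng)

    def test_artifacts_only_hurt(self):
        """Clean degradation reconstructs at least as well as artifacted."""
        from orthosr.baseline import fuse_interpolate
        from orthosr.metrics import psnr
        from orthosr.phantom import PhantomSpec, make_phantom

        vol, _ = make_phantom(PhantomSpec(seed=21, size=64))
        hr = normalize_window(vol)
        grid = (hr.shape, hr.spacing, hr.origin)
        params = AcquisitionParams(5.0, 5.0, 7.0, 7.0, "axial", "coronal")
        diffs = []
        for seed in range(10):
            clean = simulate_pair(hr, np.random.default_rng(seed),
                                  ArtifactConfig.none(), params, normalized=True)
            dirty = simulate_pair(hr, np.random.default_rng(seed),
                                  ArtifactConfig(mask_view_prob=0.0), params,
                                  normalized=True)
            p_clean = psnr(hr, fuse_interpolate(clean.X1, clean.X2, grid=grid,
                                                normalize=False))
            p_dirty = psnr(hr, fuse_interpolate(dirty.X1, dirty.X2, grid=grid,
                                                normalize=False))
            diffs.append(p_clean - p_dirty)
        assert np.median(diffs) >= 0
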