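import numpy as np
import pytest
from scipy import fft as sp_fft

from streakless.binning import bin2d, debin2d
from streakless.noise_estimation import StreakParams
from streakless.noise_model import (
    CorrelationKernel,
    PowerSpectralDensity,
    binning_residual_kernel,
    binning_residual_transfer,
    component_psd,
    compose_scale_psd,
    kernel_from_psd,
    make_streak_kernels,
    poisson_stage_psd,
    psd_from_kernel,
    streak_support_mask,
)

SHAPE = (16, 24, 20)


def synth_noise(kernel: CorrelationKernel, shape, rng):
    """Oracle: circular convolution of white noise with the kernel taps."""
    spec = sp_fft.fftn(np.pad(kernel.g, [(0, s - k) for s, k in zip(shape, kernel.g.shape)]))
    return sp_fft.ifftn(spec * sp_fft.fftn(rng.standard_normal(shape))).real


class TestPsdFromKernel:
    def test_unit_impulse_gives_flat_unit_variance_psd(self):
        g = np.zeros((1, 1, 1))
        g[0] = 1.0
        psd = psd_from_kernel(CorrelationKernel(g=g), (8, 8, 8))
        np.testing.assert_allclose(psd.psd, 512.0)
        assert psd.pixel_variance == pytest.approx(1.0)

    def test_angle_constant_kernel_supported_on_dc_plane(self):
        set_ = make_streak_kernels(0, SHAPE)
        psd = psd_from_kernel(set_.kernels["w"], SHAPE)
        off_plane = psd.psd[1:, :, :]
        assert np.abs(off_plane).max() < 1e-8 * psd.psd.max()
        assert psd.psd[0].max() > 0

    def test_variance_bookkeeping_monte_carlo(self, rng):
        g = rng.standard_normal((3, 3, 3)) * 0.3
        k = CorrelationKernel(g=g)
        psd = psd_from_kernel(k, SHAPE)
        # oracle: sample variance of synthesized realizations
        samples = np.stack([synth_noise(k, SHAPE, rng) for _ in range(30)])
        mc_var = samples.var()
        assert psd.pixel_variance == pytest.approx(np.sum(g**2), rel=1e-10)
        assert mc_var == pytest.approx(psd.pixel_variance, rel=0.1)

    def test_kernel_larger_than_shape_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            psd_from_kernel(CorrelationKernel(g=np.ones((9, 9, 9))), (8, 8, 8))


class TestKernelFromPsd:
    def test_flat_psd_gives_impulse(self):
        psd = PowerSpectralDensity(np.full((8, 8, 8), 512.0))
        k = kernel_from_psd(psd)
        flat = np.abs(k.g).ravel()
        assert flat.max() == pytest.approx(1.0, rel=1e-10)
        assert np.sort(flat)[-2] < 1e-10

    def test_round_trip_identity(self, rng):
        # a valid (even-symmetric) random PSD: the PSD of a random kernel
        g0 = rng.standard_normal((5, 5, 5))
        psd0 = psd_from_kernel(CorrelationKernel(g=g0), SHAPE)
        psd1 = psd_from_kernel(kernel_from_psd(psd0), SHAPE)
        np.testing.assert_allclose(psd1.psd, psd0.psd, rtol=1e-10, atol=1e-10 * psd0.psd.max())

    def test_negative_psd_raises(self):
        with pytest.raises(ValueError, match="nonnegative"):
            PowerSpectralDensity(-np.ones((4, 4, 4)))

    def test_u_component_kernel_constant_along_angle_and_horizontal(self):
        set_ = make_streak_kernels(0, SHAPE)
        psd = psd_from_kernel(set_.kernels["u"], SHAPE)
        k = kernel_from_psd(psd)
        assert np.ptp(k.g, axis=0).max() < 1e-12  # constant along angle
        assert np.ptp(k.g, axis=1).max() < 1e-12  # constant along horizontal


class TestStreakKernels:
    def test_unit_norm_at_scale_zero(self):
        set_ = make_streak_kernels(0, SHAPE)
        for p in "wuv":
            assert set_.kernels[p].norm == pytest.approx(1.0)

    def test_scale_law(self):
        s0 = make_streak_kernels(0, SHAPE)
        s2 = make_streak_kernels(2, SHAPE)
        for p in "wuv":
            assert s2.kernels[p].norm / s0.kernels[p].norm == pytest.approx(4.0)

    def test_realization_statistics(self, rng):
        set_ = make_streak_kernels(0, (16, 32, 32))
        eta = synth_noise(set_.kernels["w"], (16, 32, 32), rng)
        # constant along the angle, near-unit variance across displacement
        assert np.ptp(eta, axis=0).max() < 1e-10
        assert eta.var() == pytest.approx(1.0, rel=0.25)

    def test_negative_scale_raises(self):
        with pytest.raises(ValueError):
            make_streak_kernels(-1, SHAPE)


class TestBinningResidual:
    def test_variance_matches_residual_field_monte_carlo(self, rng):
        # oracle: residual of white noise under one bin/debin round trip
        shape = (4, 32, 32)
        res_vars = []
        for _ in range(50):
            eta = rng.standard_normal(shape)
            res = eta - debin2d(bin2d(eta), shape)
            res_vars.append(res.var())
        mc = np.mean(res_vars)
        transfer = binning_residual_transfer(shape)
        model = transfer.mean()  # variance of unit white noise through q
        assert mc == pytest.approx(model, rel=0.02)

    def test_residual_orthogonal_to_coarse_part(self, rng):
        shape = (2, 16, 16)
        dots = []
        for _ in range(200):
            eta = rng.standard_normal(shape)
            coarse = debin2d(bin2d(eta), shape)
            dots.append(np.sum((eta - coarse) * coarse))
        assert abs(np.mean(dots)) < 3 * np.std(dots) / np.sqrt(len(dots))

    def test_constant_field_has_zero_residual(self):
        shape = (2, 8, 8)
        eta = np.full(shape, 3.7)
        res = eta - debin2d(bin2d(eta), shape)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_kernel_is_real_and_matches_transfer(self):
        q = binning_residual_kernel((16, 16))
        spec = np.abs(sp_fft.fft2(q)) ** 2
        transfer = binning_residual_transfer((1, 16, 16))[0]
        np.testing.assert_allclose(spec, transfer, atol=1e-10)


class TestComposeScalePsd:
    def test_all_zero_strengths_give_zero_psd(self):
        set_ = make_streak_kernels(0, SHAPE)
        psd = compose_scale_psd(StreakParams(0, 0, 0), set_)
        np.testing.assert_array_equal(psd.psd, 0.0)

    def test_single_component_equals_component_psd(self):
        set_ = make_streak_kernels(0, SHAPE)
        psd = compose_scale_psd(StreakParams(1.0, 0.0, 0.0), set_)
        np.testing.assert_allclose(psd.psd, psd_from_kernel(set_.kernels["w"], SHAPE).psd)

    def test_mixed_variance_bookkeeping(self, rng):
        set_ = make_streak_kernels(0, SHAPE)
        params = StreakParams(0.5, 0.3, 0.2)
        psd = compose_scale_psd(params, set_)
        expected = 0.25 + 0.09 + 0.04  # sum of sigma^2 * unit kernel norms
        assert psd.pixel_variance == pytest.approx(expected, rel=1e-10)
        # Monte-Carlo cross-check through synthesized realizations
        k = kernel_from_psd(psd)
        samples = np.stack([synth_noise(k, SHAPE, rng) for _ in range(40)])
        assert samples.var() == pytest.approx(expected, rel=0.2)

    def test_negative_strength_raises(self):
        with pytest.raises(ValueError):
            StreakParams(-0.1, 0, 0)

    def test_residual_set_is_attenuated_at_low_displacement_frequency(self):
        plain = component_psd("w", make_streak_kernels(0, SHAPE))
        resid = component_psd("w", make_streak_kernels(0, SHAPE, residual=True))
        assert resid[0, 0, 0] == pytest.approx(0.0, abs=1e-10)
        assert resid.sum() < plain.sum()

    def test_dc_plane_support(self):
        set_ = make_streak_kernels(1, SHAPE, residual=True)
        psd = compose_scale_psd(StreakParams(0.2, 0.1, 0.05), set_)
        assert np.abs(psd.psd[1:]).max() < 1e-8 * max(psd.psd.max(), 1e-30)


class TestPoissonStagePsd:
    def test_empty_support_gives_flat_white_psd(self):
        psd = poisson_stage_psd(SHAPE, 2.0, None)
        np.testing.assert_allclose(psd.psd, 2.0 * np.prod(SHAPE))
        assert psd.pixel_variance == pytest.approx(2.0)

    def test_zero_c_gives_zero_psd(self):
        psd = poisson_stage_psd(SHAPE, 0.0, streak_support_mask(SHAPE))
        np.testing.assert_array_equal(psd.psd, 0.0)

    def test_zeroed_fraction_matches_support_mask(self):
        mask = streak_support_mask(SHAPE)
        psd = poisson_stage_psd(SHAPE, 1.0, mask)
        zeroed = np.count_nonzero(psd.psd == 0)
        assert zeroed == np.count_nonzero(mask)
        assert zeroed / psd.domain_size == pytest.approx(1.0 / SHAPE[0])

    def test_negative_c_raises(self):
        with pytest.raises(ValueError):
            poisson_stage_psd(SHAPE, -1.0, None)
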