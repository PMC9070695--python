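import numpy as np
import pytest

from streakless.noise_estimation import (
    DB3_HIGHPASS,
    MAD_SCALE,
    StreakParams,
    build_probe_bank,
    convolved_norm,
    estimate_segment_params,
    mad_std,
    response_matrix,
    scale_from_std,
    unmix_components,
)
from streakless.noise_model import make_streak_kernels
from streakless.synthetic import SyntheticConfig, streak_field

SHAPE = (64, 96, 64)


def make_streak_noise(sigma_w, sigma_u, sigma_v, seed, shape=SHAPE):
    cfg = SyntheticConfig(shape=shape, sigma_w=sigma_w, sigma_u=sigma_u, sigma_v=sigma_v, seed=seed)
    return streak_field(cfg, np.random.default_rng(seed))


class TestDb3:
    def test_exactly_six_taps(self):
        assert len(DB3_HIGHPASS) == 6

    def test_unit_norm_and_zero_dc(self):
        assert np.sum(DB3_HIGHPASS**2) == pytest.approx(1.0, abs=1e-12)
        assert np.sum(DB3_HIGHPASS) == pytest.approx(0.0, abs=1e-12)


class TestMadStd:
    def test_white_normal_noise_calibration(self, rng):
        z = rng.standard_normal((100, 100, 100))
        impulse = (np.ones(1), np.ones(1), np.ones(1))
        assert mad_std(z, impulse) == pytest.approx(1.0, rel=0.01)

    def test_constant_volume_gives_zero(self):
        assert mad_std(np.full((8, 8, 8), 3.0), (np.ones(1), np.ones(1), np.ones(1))) == 0.0

    def test_scale_equivariance(self, rng):
        z = rng.standard_normal((20, 20, 20))
        probe = (DB3_HIGHPASS, DB3_HIGHPASS, DB3_HIGHPASS)
        assert mad_std(5.0 * z, probe) == pytest.approx(5.0 * mad_std(z, probe), rel=1e-10)

    def test_volume_smaller_than_kernel_raises(self):
        with pytest.raises(ValueError, match="smaller"):
            mad_std(np.zeros((4, 4, 4)), (DB3_HIGHPASS, DB3_HIGHPASS, DB3_HIGHPASS))

    def test_full_3d_kernel_accepted(self, rng):
        z = rng.standard_normal((12, 12, 12))
        g = np.zeros((3, 3, 3))
        g[1, 1, 1] = 1.0
        assert mad_std(z, g) == pytest.approx(1.0, rel=0.2)


class TestScaleFromStd:
    def test_precomputed_norm_form(self):
        assert scale_from_std(2.0, 2.0) == pytest.approx(1.0)

    def test_zero_norm_raises(self):
        with pytest.raises(ValueError, match="response"):
            scale_from_std(1.0, 0.0)

    def test_matched_probe_recovers_strength(self):
        shape = (32, 64, 64)
        set_ = make_streak_kernels(0, shape)
        bank = build_probe_bank(shape)
        norm = convolved_norm(set_.kernels["w"], bank.factors["w"], shape)
        estimates = []
        for seed in range(10):
            eta = make_streak_noise(0.02, 0.0, 0.0, seed, shape)
            estimates.append(scale_from_std(mad_std(eta, bank.factors["w"]), norm))
        assert 0.018 <= np.median(estimates) <= 0.022

    def test_white_noise_yields_small_streak_reading(self, rng):
        shape = (32, 64, 64)
        bank = build_probe_bank(shape)
        white = 0.02 * rng.standard_normal(shape)
        streaky = make_streak_noise(0.02, 0.0, 0.0, 0, shape)
        # the angularly low-pass probe suppresses white noise but not streaks
        assert mad_std(white, bank.factors["w"]) < 0.3 * mad_std(streaky, bank.factors["w"])


class TestProbeBank:
    def test_constant_volume_gives_zero_response(self):
        bank = build_probe_bank((16, 24, 24))
        const = np.full((16, 24, 24), 7.0)
        for q in "wuv":
            assert mad_std(const, bank.factors[q]) == pytest.approx(0.0, abs=1e-10)

    def test_w_probe_separates_components(self):
        shape = (32, 64, 64)
        bank = build_probe_bank(shape)
        eta_w = make_streak_noise(0.02, 0.0, 0.0, 1, shape)
        eta_u = make_streak_noise(0.0, 0.02, 0.0, 1, shape)
        r_w = mad_std(eta_w, bank.factors["w"]) ** 2
        r_u = mad_std(eta_u, bank.factors["w"]) ** 2
        assert r_w / max(r_u, 1e-30) > 10.0

    def test_probes_are_separable_unit_factors(self):
        bank = build_probe_bank((32, 48, 48))
        for q in "wuv":
            for f in bank.factors[q]:
                assert np.sum(f**2) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_dimensions_raise(self):
        with pytest.raises(ValueError):
            build_probe_bank((4, 48, 48))


class TestUnmix:
    def test_zero_readings_give_zero_params(self):
        set_ = make_streak_kernels(0, (32, 64, 64))
        bank = build_probe_bank((32, 64, 64))
        M = response_matrix(set_, bank)
        params = unmix_components([0.0, 0.0, 0.0], M)
        assert params.as_tuple() == (0.0, 0.0, 0.0)

    def test_recovery_of_mixed_components(self):
        shape = (64, 96, 64)
        set_ = make_streak_kernels(0, shape)
        bank = build_probe_bank(shape)
        M = response_matrix(set_, bank)
        recovered = []
        for seed in range(5):
            eta = make_streak_noise(0.02, 0.005, 0.0, seed, shape)
            p = estimate_segment_params(eta, set_, bank, M)
            recovered.append(p.as_tuple())
        med = np.median(recovered, axis=0)
        assert med[0] == pytest.approx(0.02, rel=0.2)
        assert med[1] == pytest.approx(0.005, rel=0.2)
        assert med[2] < 0.002

    def test_pure_white_streaks_do_not_leak_into_uv(self):
        shape = (64, 96, 64)
        set_ = make_streak_kernels(0, shape)
        bank = build_probe_bank(shape)
        M = response_matrix(set_, bank)
        vals = []
        for seed in range(5):
            eta = make_streak_noise(0.02, 0.0, 0.0, seed, shape)
            sigma_hats = [mad_std(eta, bank.factors[q]) for q in "wuv"]
            # low-frequency probes do read energy from the white component...
            assert sigma_hats[1] > 0 and sigma_hats[2] > 0
            # ...but unmixing attributes it back to the white component
            vals.append(unmix_components(sigma_hats, M).as_tuple())
        med = np.median(vals, axis=0)
        assert med[0] == pytest.approx(0.02, rel=0.2)
        assert med[1] < 0.004 and med[2] < 0.004

    def test_nonnegativity(self, rng):
        set_ = make_streak_kernels(0, (32, 48, 48))
        bank = build_probe_bank((32, 48, 48))
        M = response_matrix(set_, bank)
        for _ in range(20):
            params = unmix_components(rng.uniform(0, 0.1, 3), M)
            assert min(params.as_tuple()) >= 0.0


class TestSegmentParams:
    def test_disjoint_segments_agree_on_homogeneous_noise(self):
        shape = (32, 128, 64)
        eta = make_streak_noise(0.02, 0.0, 0.0, 3, shape)
        seg_shape = (32, 64, 64)
        set_ = make_streak_kernels(0, seg_shape)
        bank = build_probe_bank(seg_shape)
        M = response_matrix(set_, bank)
        p1 = estimate_segment_params(eta[:, :64], set_, bank, M)
        p2 = estimate_segment_params(eta[:, 64:], set_, bank, M)
        assert p1.sigma_w == pytest.approx(p2.sigma_w, rel=0.3)

    def test_doubled_noise_in_one_half(self):
        shape = (32, 128, 64)
        eta = make_streak_noise(0.02, 0.0, 0.0, 4, shape)
        eta[:, 64:] *= 2.0
        seg_shape = (32, 64, 64)
        set_ = make_streak_kernels(0, seg_shape)
        bank = build_probe_bank(seg_shape)
        M = response_matrix(set_, bank)
        p1 = estimate_segment_params(eta[:, :64], set_, bank, M)
        p2 = estimate_segment_params(eta[:, 64:], set_, bank, M)
        assert p2.sigma_w / p1.sigma_w == pytest.approx(2.0, rel=0.3)

    def test_zero_noise_segment_gives_zero_params(self):
        seg = np.zeros((32, 64, 64))
        set_ = make_streak_kernels(0, seg.shape)
        params = estimate_segment_params(seg, set_)
        assert params.as_tuple() == (0.0, 0.0, 0.0)

    def test_smooth_signal_robustness(self):
        # a strong smooth blob changes the noise estimate by < 15%
        shape = (48, 64, 64)
        eta = make_streak_noise(0.02, 0.0, 0.0, 5, shape)
        g0, g1, g2 = np.meshgrid(
            np.linspace(-2, 2, shape[0]), np.linspace(-2, 2, shape[1]), np.linspace(-2, 2, shape[2]),
            indexing="ij",
        )
        blob = 10 * 0.02 * np.exp(-(g0**2 + g1**2 + g2**2))
        set_ = make_streak_kernels(0, shape)
        bank = build_probe_bank(shape)
        M = response_matrix(set_, bank)
        clean = estimate_segment_params(eta, set_, bank, M)
        dirty = estimate_segment_params(eta + blob, set_, bank, M)
        assert dirty.sigma_w == pytest.approx(clean.sigma_w, rel=0.15)


def test_estimator_consistency_with_segment_size():
    # median estimate converges toward the truth as the segment grows
    true = 0.02
    errs = []
    for shape in [(32, 48, 48), (64, 96, 96)]:
        set_ = make_streak_kernels(0, shape)
        bank = build_probe_bank(shape)
        M = response_matrix(set_, bank)
        ests = [
            estimate_segment_params(make_streak_noise(true, 0, 0, s, shape), set_, bank, M).sigma_w
            for s in range(5)
        ]
        errs.append(abs(np.median(ests) - true))
    assert errs[1] <= errs[0] + 0.1 * true
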