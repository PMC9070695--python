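"""Stage 1: extreme-streak pre-attenuation and coarse-to-fine multiscale
streak removal with per-segment adaptive PSDs.

The stack is first binned along the angle (streaks are angle-constant, so
all their energy survives), then a 2-D displacement binning pyramid is
processed coarse to fine: at each level the already-denoised coarser
content is substituted back before denoising, so the level PSD models only
the fine displacement frequencies plus the binning residual.  Finally only
the coarse angular components of the original stack are replaced, leaving
the high-frequency angular residual bit-identical to the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import binning
from .collab_filter import FilterProfile, denoise_volume
from .noise_estimation import (
    MAD_SCALE,
    StreakParams,
    build_probe_bank,
    estimate_segment_params,
    response_matrix,
)
from .noise_model import compose_scale_psd, make_streak_kernels
from .normalization import ProjectionStack

logger = logging.getLogger(__name__)

__all__ = [
    "StreakConfig",
    "SegmentGrid",
    "attenuate_extreme_streaks",
    "segment_denoise",
    "multiscale_streak_denoise",
]


@dataclass
class StreakConfig:
    """Configuration of the multiscale streak stage."""

    n_scales: int | None = None  # K; None -> PyramidSpec.default_n_scales
    angular_target: int = 32
    segment_size: int = 256  # displacement extent of one segment
    segment_overlap: float = 0.5
    extreme_tau: float = 4.0
    # cap on coarse-level strengths relative to the finest-level estimate;
    # for stationary streaks the per-scale strengths are equal by design
    # (the 2^k kernel norms carry the scale factor), so a coarse estimate
    # far above the finest-level one indicates signal leakage into the
    # probes, not stronger noise
    coarse_cap_factor: float = 2.0
    profile: FilterProfile = field(default_factory=FilterProfile)
    denoiser: object = None  # injectable; None -> collaborative filter


@dataclass
class SegmentGrid:
    """Overlapping displacement segments with partition-of-unity windows."""

    shape: tuple
    segment_size: int = 256
    overlap: float = 0.5

    def segments(self):
        """Yield ``(slices, window)`` covering the displacement plane.

        Segments span the full angular extent; the raised-cosine windows
        are renormalized during recombination so they sum to one
        everywhere.
        """
        _, m1, m2 = self.shape
        step = max(1, int(self.segment_size * (1.0 - self.overlap)))
        for s1, w1 in self._axis_segments(m1, step):
            for s2, w2 in self._axis_segments(m2, step):
                window = w1[:, None] * w2[None, :]
                yield (slice(None), s1, s2), window

    def _axis_segments(self, m, step):
        size = min(self.segment_size, m)
        starts = list(range(0, max(m - size, 0) + 1, step))
        if starts[-1] != m - size:
            starts.append(m - size)
        out = []
        for s in starts:
            window = np.hanning(size + 2)[1:-1] if len(starts) > 1 else np.ones(size)
            out.append((slice(s, s + size), window))
        return out


def _quadratic_fit_kernel(window: int = 15) -> np.ndarray:
    """Moving 2-D quadratic least-squares fit as a convolution kernel.

    Returns the 15x15 kernel whose correlation with an image gives the
    value at the window center of the best-fit quadratic surface.
    """
    half = window // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    basis = np.stack([np.ones_like(x), x, y, x * x, x * y, y * y], axis=-1).reshape(-1, 6)
    pinv = np.linalg.pinv(basis.astype(np.float64))
    return pinv[0].reshape(window, window)


def attenuate_extreme_streaks(Z: ProjectionStack, tau: float = 4.0) -> ProjectionStack:
    """Median-replace detector columns whose angular median is an outlier.

    The image of per-pixel angular medians is compared against a moving
    local quadratic fit; pixels deviating by more than ``tau`` robust
    standard deviations are replaced, per angle, by the median over their
    3x3 displacement neighborhood.
    """
    z = Z.data
    med_img = np.median(z, axis=0)
    window = 15
    kern = _quadratic_fit_kernel(window)
    fitted = ndimage.correlate(med_img, kern, mode="nearest")
    resid = med_img - fitted
    # the moving fit is unreliable within half a window of the border
    margin = window // 2
    interior = resid[margin:-margin, margin:-margin]
    scale = MAD_SCALE * np.median(np.abs(interior - np.median(interior)))
    flagged = np.abs(resid) > tau * max(scale, 1e-30)
    flagged[:margin, :] = flagged[-margin:, :] = False
    flagged[:, :margin] = flagged[:, -margin:] = False
    if not np.any(flagged):
        return ProjectionStack(data=z.copy())
    out = z.copy()
    for i in range(z.shape[0]):
        repl = ndimage.median_filter(z[i], size=3, mode="nearest")
        out[i][flagged] = repl[flagged]
    n = int(np.count_nonzero(flagged))
    logger.info("extreme-streak attenuation: %d detector pixels replaced", n)
    return ProjectionStack(data=out)


def segment_denoise(volume: np.ndarray, psd_builder, grid: SegmentGrid, profile: FilterProfile, denoiser=None) -> np.ndarray:
    """Per-segment parameter estimation, PSD construction and denoising.

    ``psd_builder(segment_volume)`` must return the PSD object for one
    segment; segment estimates are recombined with windows normalized to a
    partition of unity.
    """
    denoise = denoiser or denoise_volume
    num = np.zeros_like(volume, dtype=np.float64)
    den = np.zeros(volume.shape[1:], dtype=np.float64)
    for slices, window in grid.segments():
        seg = volume[slices]
        psd = psd_builder(seg)
        est = denoise(seg, psd, profile)
        num[slices] += est * window[None, :, :]
        den[slices[1], slices[2]] += window
    if np.any(den <= 0):
        raise RuntimeError("segment windows do not cover the volume")
    return num / den[None, :, :]


def _scale_psd_builder(k: int, residual: bool, estimated: list, cap: StreakParams | None = None):
    """Build the per-segment PSD closure for pyramid level ``k``."""

    def build(segment: np.ndarray):
        set_ = make_streak_kernels(k, segment.shape, residual=residual)
        bank = build_probe_bank(segment.shape)
        M = response_matrix(set_, bank)
        params = estimate_segment_params(segment, set_, bank, M)
        if cap is not None:
            params = StreakParams(
                sigma_w=min(params.sigma_w, cap.sigma_w),
                sigma_u=min(params.sigma_u, cap.sigma_u),
                sigma_v=min(params.sigma_v, cap.sigma_v),
            )
        estimated.append((k, params))
        return compose_scale_psd(params, set_)

    return build


def _reference_params(z_alpha: np.ndarray, cfg: StreakConfig):
    """Finest-level strengths (max over segments) used to cap coarse levels."""
    grid = SegmentGrid(z_alpha.shape, cfg.segment_size, cfg.segment_overlap)
    set_ = None
    best = StreakParams(0.0, 0.0, 0.0)
    for slices, _ in grid.segments():
        seg = z_alpha[slices]
        if set_ is None or set_.shape != seg.shape:
            set_ = make_streak_kernels(0, seg.shape)
            bank = build_probe_bank(seg.shape)
            M = response_matrix(set_, bank)
        p = estimate_segment_params(seg, set_, bank, M)
        best = StreakParams(
            sigma_w=max(best.sigma_w, p.sigma_w),
            sigma_u=max(best.sigma_u, p.sigma_u),
            sigma_v=max(best.sigma_v, p.sigma_v),
        )
    return best


def multiscale_streak_denoise(Z: ProjectionStack, cfg: StreakConfig | None = None) -> ProjectionStack:
    """Remove streak noise from a log-domain projection stack.

    Only the angularly binned subspace of the input is modified: the
    angular high-frequency residual passes through bit-identical.
    """
    cfg = cfg or StreakConfig()
    z = Z.data
    K = cfg.n_scales
    if K is None:
        K = binning.PyramidSpec.default_n_scales(z.shape)

    z_alpha = binning.bin_angular(z, cfg.angular_target)

    # displacement pyramid Z_0 .. Z_K (Z_0 is the angularly binned stack)
    levels = [z_alpha]
    for _ in range(K):
        levels.append(binning.bin2d(levels[-1]))

    estimated: list = []

    # reference strengths from the finest level, where the probes see the
    # least signal contrast; coarse-level estimates are capped against them
    ref = _reference_params(levels[0], cfg)
    cap = StreakParams(
        sigma_w=cfg.coarse_cap_factor * ref.sigma_w,
        sigma_u=cfg.coarse_cap_factor * ref.sigma_u,
        sigma_v=cfg.coarse_cap_factor * ref.sigma_v,
    )

    def denoise_level(vol, k, residual):
        # halve the segment size with the scale so segments keep tracking
        # the same detector regions through the displacement pyramid
        seg_size = max(32, cfg.segment_size >> k)
        grid = SegmentGrid(vol.shape, seg_size, cfg.segment_overlap)
        builder = _scale_psd_builder(k, residual, estimated, cap=cap if k > 0 else None)
        return segment_denoise(vol, builder, grid, cfg.profile, denoiser=cfg.denoiser)

    est = denoise_level(levels[K], K, residual=False)
    for k in range(K - 1, -1, -1):
        z_tilde = binning.replace_coarse(levels[k], est, binning.bin2d, binning.debin2d)
        est = denoise_level(z_tilde, k, residual=True)

    for k, params in estimated:
        logger.info(
            "scale %d: sigma_w=%.4g sigma_u=%.4g sigma_v=%.4g",
            k, params.sigma_w, params.sigma_u, params.sigma_v,
        )

    out = binning.replace_coarse(
        z,
        est,
        lambda x: binning.bin_angular(x, cfg.angular_target),
        lambda c, shape: binning.debin_angular(c, shape[0]),
    )
    return ProjectionStack(data=out)
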