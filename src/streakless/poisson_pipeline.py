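"""Stage 2: Poissonian noise attenuation via adaptive variance stabilization.

The bright-field-induced variance scaling is undone by adding the smoothed
log-field back, a data-driven polynomial variance model is fitted and turned
into a variance-stabilizing transform with an exact-unbiased inverse, and
the stabilized stack is denoised at multiple 3-D binning scales with a
streak-notched flat PSD before inversion and field removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import interp1d

from . import binning
from .collab_filter import FilterProfile, denoise_volume
from .noise_estimation import DB3_HIGHPASS, mad_std
from .noise_model import poisson_stage_psd, streak_support_mask
from .normalization import ProjectionStack

logger = logging.getLogger(__name__)

__all__ = [
    "PoissonConfig",
    "FieldModel",
    "VSTModel",
    "build_field",
    "field_correct",
    "fit_vst",
    "multiscale_poisson_denoise",
    "poisson_only_mode",
]


@dataclass
class PoissonConfig:
    """Configuration of the Poisson stage."""

    n_scales: int = 1  # K_poi; 0 means single-scale
    vst_degree: int = 2
    notch_streaks: bool = True
    recombine_sigma: float = 1.2  # 3-D Gaussian selecting coarse low frequencies
    segments: tuple = (2, 2)  # displacement segment grid, full angular extent
    profile: FilterProfile = field(default_factory=FilterProfile)
    denoiser: object = None


@dataclass
class FieldModel:
    """Log-domain bright/dark field and its outlier-free smoothed version."""

    i_l: np.ndarray
    i_l_smooth: np.ndarray


def build_field(I_B: np.ndarray, I_D: np.ndarray, med_window: int = 5, gauss_sigma: float = 3.0) -> FieldModel:
    """Smooth log-field ``g_I * medfilt(ln(I_B - I_D))``.

    The median filter removes extreme outliers (broken pixels); the
    Gaussian ensures a smooth result so no field structure survives into
    the denoised output.
    """
    diff = np.asarray(I_B, dtype=np.float64) - np.asarray(I_D, dtype=np.float64)
    floor = 1e-6 * max(float(np.median(np.abs(diff))), 1e-30)
    if np.all(diff <= 0):
        raise ValueError("bright - dark field is nonpositive everywhere")
    i_l = np.log(np.maximum(diff, floor))
    smooth = ndimage.gaussian_filter(
        ndimage.median_filter(i_l, size=med_window, mode="nearest"),
        gauss_sigma,
        mode="nearest",
    )
    return FieldModel(i_l=i_l, i_l_smooth=smooth)


def field_correct(Y: ProjectionStack | np.ndarray, field_model: FieldModel) -> np.ndarray:
    """``S = Y + smoothed log-field`` (broadcast over the angular axis)."""
    y = Y.data if isinstance(Y, ProjectionStack) else np.asarray(Y, dtype=np.float64)
    if y.shape[1:] != field_model.i_l_smooth.shape:
        raise ValueError("field shape does not match projections")
    return y + field_model.i_l_smooth[None, :, :]


@dataclass
class VSTModel:
    """Fitted variance polynomial with forward and exact-unbiased inverse maps.

    ``coeffs`` are highest-power-first polynomial coefficients of the
    variance function ``F``; the forward stabilizer is
    ``f(s) = integral of F^(-1/2)`` tabulated over the fit range, and the
    inverse maps a denoised stabilized value back through the table of
    ``E[f(S) | E[S]]`` under a Gaussian surrogate of variance ``F``.
    """

    coeffs: np.ndarray
    s_range: tuple
    _fwd: object = None
    _inv: object = None

    def variance(self, s):
        return np.maximum(np.polyval(self.coeffs, s), 1e-12)

    def forward(self, s):
        return self._fwd(np.asarray(s, dtype=np.float64))

    def inverse(self, t):
        return self._inv(np.asarray(t, dtype=np.float64))


def _local_mean_var(S: np.ndarray, block: int = 8):
    """Robust per-block (mean, variance) pairs from pseudo-residuals.

    Vertical pairwise differences cancel the locally smooth signal; the
    variance inside each (angle-slice, block x block) cell is estimated by
    a scaled median of absolute differences.
    """
    m0, m1, m2 = S.shape
    d = (S[:, :, 1:] - S[:, :, :-1]) / np.sqrt(2.0)
    # shrink the block on small volumes so enough pairs are collected
    while block > 4 and m0 * (m1 // block) * ((m2 - 1) // block) < 200:
        block -= 2
    n1, n2 = m1 // block, (m2 - 1) // block
    if n1 == 0 or n2 == 0:
        raise ValueError("volume too small for VST block statistics")
    Sc = S[:, : n1 * block, : n2 * block]
    dc = d[:, : n1 * block, : n2 * block]
    Sb = Sc.reshape(m0, n1, block, n2, block)
    db = dc.reshape(m0, n1, block, n2, block)
    means = Sb.mean(axis=(2, 4)).ravel()
    mad = np.median(np.abs(db), axis=(2, 4)).ravel()
    variances = (1.4826 * mad) ** 2
    return means, variances


def fit_vst(S: np.ndarray, degree: int = 2, n_table: int = 1000) -> VSTModel:
    """Fit the variance polynomial and tabulate the VST and its inverse.

    Block (mean, variance) pairs are pooled into intensity bins (median
    variance per bin, weighted by bin population) and fitted by weighted
    least squares; the stabilizer is obtained by numerical quadrature of
    ``F^(-1/2)`` and the exact-unbiased inverse by Gauss-Hermite evaluation
    of ``E[f(S) | E[S]]`` with a Gaussian surrogate of variance ``F``.
    """
    S = np.asarray(S, dtype=np.float64)
    means, variances = _local_mean_var(S)
    n_bins = max(10, min(60, means.size // 200))
    if means.size < 200:
        raise ValueError("not enough samples to fit the variance model")
    order = np.argsort(means)
    means, variances = means[order], variances[order]
    edges = np.linspace(0, means.size, n_bins + 1).astype(int)
    bm, bv, bw = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 20:
            continue
        bm.append(np.mean(means[a:b]))
        bv.append(np.median(variances[a:b]))
        bw.append(b - a)
    bm, bv, bw = map(np.asarray, (bm, bv, bw))
    lo, hi = float(means.min()), float(means.max())
    span = max(hi - lo, 1e-6)
    grid = np.linspace(lo - 0.05 * span, hi + 0.05 * span, n_table)
    level = float(np.median(bv))
    if level <= 1e-12 * span * span:
        # essentially noiseless data: a constant, tiny variance model keeps
        # the stabilizer affine and downstream filtering a near-identity
        coeffs = np.array([max(level, 1e-12 * span * span)])
        F = np.full_like(grid, coeffs[-1])
    else:
        coeffs = np.polyfit(bm, bv, deg=degree, w=np.sqrt(bw))
        F = np.polyval(coeffs, grid)
        core = (grid >= np.quantile(means, 0.01)) & (grid <= np.quantile(means, 0.99))
        if np.mean(F[core] <= 0) > 0.05:
            raise ValueError(
                "fitted variance model is nonpositive on the data range; "
                "reduce the polynomial degree"
            )
        # extrapolation may dip negative outside the core range; clamp
        F = np.maximum(F, 1e-3 * abs(np.median(F[core])))
    f_tab = cumulative_trapezoid(F ** (-0.5), grid, initial=0.0)
    fwd = interp1d(grid, f_tab, bounds_error=False, fill_value="extrapolate")

    # exact-unbiased inverse: E[f(mu + sqrt(F(mu)) xi)] over Gauss-Hermite nodes
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()
    samples = grid[:, None] + np.sqrt(F)[:, None] * nodes[None, :]
    ef = (fwd(samples) * weights[None, :]).sum(axis=1)
    if np.any(np.diff(ef) <= 0):  # enforce monotonicity for inversion
        ef = np.maximum.accumulate(ef)
        keep = np.concatenate([[True], np.diff(ef) > 0])
        ef, ginv = ef[keep], grid[keep]
    else:
        ginv = grid
    inv = interp1d(ef, ginv, bounds_error=False, fill_value="extrapolate")

    model = VSTModel(coeffs=coeffs, s_range=(lo, hi), _fwd=fwd, _inv=inv)
    logger.info("VST fitted: degree %d, range [%.3g, %.3g]", degree, lo, hi)
    return model


def _poisson_probe():
    psi = DB3_HIGHPASS
    return (psi, psi, psi)


def _denoise_stabilized(vol: np.ndarray, cfg: PoissonConfig) -> np.ndarray:
    """Segment-wise flat-PSD denoising of one stabilized pyramid level."""
    probe = _poisson_probe()
    denoise = cfg.denoiser or denoise_volume
    n1, n2 = cfg.segments
    m0, m1, m2 = vol.shape
    # enough room for the probe and the filter cube in every segment
    n1 = max(1, min(n1, m1 // 16))
    n2 = max(1, min(n2, m2 // 16))
    out = np.zeros_like(vol)
    weight = np.zeros(vol.shape[1:])
    e1 = np.linspace(0, m1, n1 + 1).astype(int)
    e2 = np.linspace(0, m2, n2 + 1).astype(int)
    for a, b in zip(e1[:-1], e1[1:]):
        for c, d in zip(e2[:-1], e2[1:]):
            seg = vol[:, a:b, c:d]
            c_var = mad_std(seg, probe) ** 2
            mask = streak_support_mask(seg.shape) if cfg.notch_streaks else None
            psd = poisson_stage_psd(seg.shape, c_var, mask)
            out[:, a:b, c:d] += denoise(seg, psd, cfg.profile)
            weight[a:b, c:d] += 1.0
    return out / weight[None, :, :]


def multiscale_poisson_denoise(
    Y: ProjectionStack,
    field_model: FieldModel,
    vst: VSTModel | None = None,
    cfg: PoissonConfig | None = None,
) -> ProjectionStack:
    """Attenuate the Poissonian component of a (streak-free) log stack.

    Each 3-D binning scale is denoised independently and the estimates are
    recombined coarse to fine, taking only Gaussian-low-passed content from
    the coarser scale (its high frequencies are estimated worse than the
    finer scale's own).
    """
    cfg = cfg or PoissonConfig()
    S = field_correct(Y, field_model)
    if vst is None:
        vst = fit_vst(S, degree=cfg.vst_degree)
    fS = vst.forward(S)

    levels = [fS]
    for _ in range(cfg.n_scales):
        levels.append(binning.bin3d(levels[-1]))
    estimates = [_denoise_stabilized(v, cfg) for v in levels]

    combined = estimates[-1]
    for k in range(len(levels) - 2, -1, -1):
        fine = estimates[k]
        coarse_up = binning.debin3d(combined, fine.shape)
        own_coarse_up = binning.debin3d(binning.bin3d(fine), fine.shape)
        lowpass = ndimage.gaussian_filter(coarse_up - own_coarse_up, cfg.recombine_sigma, mode="nearest")
        combined = fine + lowpass
    denoised = vst.inverse(combined)
    out = denoised - field_model.i_l_smooth[None, :, :]
    return ProjectionStack(data=out)


def poisson_only_mode(
    Z: ProjectionStack,
    field_model: FieldModel,
    cfg: PoissonConfig | None = None,
) -> ProjectionStack:
    """Poisson denoising without prior streak removal (flat, un-notched PSD)."""
    cfg = cfg or PoissonConfig()
    cfg = PoissonConfig(
        n_scales=cfg.n_scales,
        vst_degree=cfg.vst_degree,
        notch_streaks=False,
        recombine_sigma=cfg.recombine_sigma,
        segments=cfg.segments,
        profile=cfg.profile,
        denoiser=cfg.denoiser,
    )
    return multiscale_poisson_denoise(Z, field_model, cfg=cfg)
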