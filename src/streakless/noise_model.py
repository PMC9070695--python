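"""Stationary correlated-noise representations: kernels, PSDs and the
angle-constant streak components at every pyramid scale.

Conventions
-----------
The Fourier transform is the unnormalized forward FFT with ``1/|X|`` inverse,
frequencies in unshifted order (DC at index 0).  For noise ``eta = g * nu``
(circular 3-D convolution with white unit-variance ``nu``) the PSD is

    Psi = E |F(eta)|^2 = |X| * |F(g)|^2,

so ``mean(Psi) / |X|`` equals the per-pixel noise variance (Parseval) and a
zero-phase kernel is recovered as ``ifft(sqrt(Psi / |X|))``.

Streak noise is constant along the angular axis, so every streak PSD is
supported only on the angular-DC plane.  Three components are distinguished
by their displacement structure: white across both displacements (``w``),
constant across horizontal (``u``), and constant across vertical (``v``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "CorrelationKernel",
    "PowerSpectralDensity",
    "StreakComponentSet",
    "psd_from_kernel",
    "kernel_from_psd",
    "make_streak_kernels",
    "binning_residual_kernel",
    "binning_residual_transfer",
    "compose_scale_psd",
    "component_psd",
    "poisson_stage_psd",
    "streak_support_mask",
]

STREAK_COMPONENTS = ("w", "u", "v")


@dataclass
class CorrelationKernel:
    """Centered convolution kernel taps plus their Euclidean norm."""

    g: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.sqrt(np.sum(self.g.astype(np.float64) ** 2)))


@dataclass
class PowerSpectralDensity:
    """Nonnegative PSD on the full volume grid (unshifted FFT order)."""

    psd: np.ndarray

    def __post_init__(self):
        self.psd = np.asarray(self.psd, dtype=np.float64)
        if np.any(self.psd < -1e-12 * max(1.0, self.psd.max(initial=0.0))):
            raise ValueError("PSD must be nonnegative")
        self.psd = np.maximum(self.psd, 0.0)

    @property
    def domain_size(self) -> int:
        return int(self.psd.size)

    @property
    def pixel_variance(self) -> float:
        """Per-pixel variance of the noise this PSD describes."""
        return float(self.psd.mean() / self.psd.size)


@dataclass
class StreakComponentSet:
    """Unit-strength streak component kernels for one pyramid scale.

    ``kernels[p]`` is the full-volume-shaped kernel of component ``p`` with
    Euclidean norm ``2**scale``; ``residual`` indicates whether the PSDs
    built from this set should carry the 2-D binning-residual transfer
    (true at every scale finer than the coarsest, where the coarse content
    has been replaced by an already-denoised estimate).
    """

    scale: int
    shape: tuple
    kernels: dict
    residual: bool = False


def _centered_embed(g: np.ndarray, shape) -> np.ndarray:
    """Zero-pad kernel taps into a volume-sized array, center at index 0."""
    g = np.asarray(g, dtype=np.float64)
    if any(gs > s for gs, s in zip(g.shape, shape)):
        raise ValueError(f"kernel shape {g.shape} exceeds volume shape {tuple(shape)}")
    out = np.zeros(shape, dtype=np.float64)
    out[tuple(slice(0, s) for s in g.shape)] = g
    # circular shift so the kernel center sits at the origin
    return np.roll(out, [-(s // 2) for s in g.shape], axis=tuple(range(len(shape))))


def psd_from_kernel(k: CorrelationKernel, shape) -> PowerSpectralDensity:
    """PSD of noise obtained by circular convolution of ``k`` with white noise."""
    padded = _centered_embed(k.g, shape)
    spec = sp_fft.fftn(padded)
    psd = np.abs(spec) ** 2 * float(np.prod(shape))
    return PowerSpectralDensity(psd)


def kernel_from_psd(psd: PowerSpectralDensity) -> CorrelationKernel:
    """Zero-phase kernel whose PSD (on the same grid) equals ``psd``."""
    root = np.sqrt(psd.psd / psd.domain_size)
    g = sp_fft.ifftn(root).real
    return CorrelationKernel(g=g)


def _component_kernel(p: str, shape) -> np.ndarray:
    """Unit-norm angle-constant kernel of component ``p`` on ``shape``."""
    m0, m1, m2 = shape
    if p == "w":
        g = np.zeros(shape)
        g[:, m1 // 2, m2 // 2] = 1.0 / np.sqrt(m0)
    elif p == "u":  # constant across angle and horizontal
        g = np.zeros(shape)
        g[:, :, m2 // 2] = 1.0 / np.sqrt(m0 * m1)
    elif p == "v":  # constant across angle and vertical
        g = np.zeros(shape)
        g[:, m1 // 2, :] = 1.0 / np.sqrt(m0 * m2)
    else:
        raise ValueError(f"unknown streak component {p!r}")
    return g


def make_streak_kernels(scale: int, shape, residual: bool = False) -> StreakComponentSet:
    """Streak component kernels at pyramid scale ``k`` (norm ``2**k``)."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    kernels = {
        p: CorrelationKernel(g=(2.0**scale) * _component_kernel(p, shape))
        for p in STREAK_COMPONENTS
    }
    return StreakComponentSet(scale=scale, shape=tuple(shape), kernels=kernels, residual=residual)


def binning_residual_transfer(shape) -> np.ndarray:
    """Squared frequency response of ``eta - debin(bin(eta))`` residuals.

    The equivalent low-pass of one sum-and-replicate 2-D binning round trip
    is the 2x2 box average ``h``; the residual transfer is
    ``max(0, 1 - |F h|^2)`` evaluated on the displacement frequency grid of
    ``shape`` and broadcast over the angular axis.  Components constant
    along one displacement axis automatically see only the residual of the
    other axis, since their spectra live at DC of the constant axis where
    the corresponding box-filter factor is 1.
    """
    _, m1, m2 = shape
    w1 = 2.0 * np.pi * sp_fft.fftfreq(m1)
    w2 = 2.0 * np.pi * sp_fft.fftfreq(m2)
    h1 = np.cos(w1 / 2.0) ** 2
    h2 = np.cos(w2 / 2.0) ** 2
    transfer = np.maximum(0.0, 1.0 - h1[:, None] * h2[None, :])
    return transfer[None, :, :]


def binning_residual_kernel(shape_2d) -> np.ndarray:
    """Zero-phase 2-D kernel ``q`` of the white-noise 2-D binning residual.

    Defined through its root transfer ``F q = sqrt(max(0, 1 - |F h|^2))``
    with ``h`` the 2x2 box average; validated against the Monte-Carlo
    residual-field statistics in the test suite.
    """
    m1, m2 = shape_2d
    w1 = 2.0 * np.pi * sp_fft.fftfreq(m1)
    w2 = 2.0 * np.pi * sp_fft.fftfreq(m2)
    h1 = np.cos(w1 / 2.0) ** 2
    h2 = np.cos(w2 / 2.0) ** 2
    root = np.sqrt(np.maximum(0.0, 1.0 - h1[:, None] * h2[None, :]))
    return sp_fft.ifft2(root).real


def component_psd(p: str, set_: StreakComponentSet) -> np.ndarray:
    """Unit-strength PSD of component ``p`` at the set's scale (raw array)."""
    psd = psd_from_kernel(set_.kernels[p], set_.shape).psd
    if set_.residual:
        psd = psd * binning_residual_transfer(set_.shape)
    return psd


def compose_scale_psd(params, set_: StreakComponentSet, shape=None) -> PowerSpectralDensity:
    """Combine per-component strengths into the full streak PSD of a scale.

    ``Psi_k = sum_p sigma_{k,p}^2 * Psi(g_{k,p})`` with the binning-residual
    transfer applied when ``set_.residual`` is set.  The result is nonzero
    only on the angular-DC plane.
    """
    shape = set_.shape if shape is None else tuple(shape)
    if shape != set_.shape:
        raise ValueError("shape must match the component set")
    total = np.zeros(shape, dtype=np.float64)
    for p in STREAK_COMPONENTS:
        s = float(getattr(params, f"sigma_{p}"))
        if s < 0:
            raise ValueError(f"negative streak strength sigma_{p}")
        if s > 0:
            total += s * s * component_psd(p, set_)
    return PowerSpectralDensity(total)


def streak_support_mask(shape) -> np.ndarray:
    """Boolean mask of frequencies removed by the streak stage.

    Every streak PSD is supported on the angular-DC plane, and the white
    streak component covers all displacement frequencies of that plane, so
    the union of the per-scale streak supports is the full angular-DC plane
    (a fraction ``1/m0`` of all frequency bins).
    """
    mask = np.zeros(shape, dtype=bool)
    mask[0, :, :] = True
    return mask


def poisson_stage_psd(shape, c: float, streak_support: np.ndarray | None = None) -> PowerSpectralDensity:
    """Flat white PSD of pixel variance ``c``, notched on streak frequencies.

    ``streak_support`` is a boolean mask of frequencies already removed by
    the streak stage (``None`` or all-False for no notch, e.g. when Poisson
    denoising runs without prior ring reduction).
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    size = float(np.prod(shape))
    psd = np.full(shape, c * size, dtype=np.float64)
    if streak_support is not None:
        psd[np.asarray(streak_support, dtype=bool)] = 0.0
    return PowerSpectralDensity(psd)
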