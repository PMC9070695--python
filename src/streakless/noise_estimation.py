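"""Self-calibration of noise strength.

Robust (MAD-based) standard-deviation probes are taken through anisotropic
separable kernels that pass the noise component of interest while attenuating
signal contrast, and the three probe readings are unmixed into per-component
streak strengths by non-negative least squares on the variance scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal
from scipy.optimize import nnls

from .noise_model import STREAK_COMPONENTS, StreakComponentSet, component_psd

__all__ = [
    "MAD_SCALE",
    "DB3_HIGHPASS",
    "StreakParams",
    "ProbeKernelBank",
    "mad_std",
    "scale_from_std",
    "build_probe_bank",
    "response_matrix",
    "unmix_components",
    "estimate_segment_params",
]

#: Normal-consistency factor 1 / Phi^{-1}(3/4) for the MAD scale estimator.
MAD_SCALE = 1.4826

def _db3_highpass() -> np.ndarray:
    """Daubechies 'db3' decomposition high-pass filter (6 taps, closed form).

    Unit l2 norm and zero DC; built from the scaling filter by the usual
    quadrature-mirror relation (no wavelet library is assumed present).
    """
    sq10 = np.sqrt(10.0)
    s = np.sqrt(5.0 + 2.0 * sq10)
    h = np.array(
        [
            1.0 + sq10 + s,
            5.0 + sq10 + 3.0 * s,
            10.0 - 2.0 * sq10 + 2.0 * s,
            10.0 - 2.0 * sq10 - 2.0 * s,
            5.0 + sq10 - 3.0 * s,
            1.0 + sq10 - s,
        ]
    ) / (16.0 * np.sqrt(2.0))
    return np.array([(-1.0) ** k * h[5 - k] for k in range(6)])


DB3_HIGHPASS = _db3_highpass()


@dataclass
class StreakParams:
    """Per-scale (optionally per-segment) streak component strengths."""

    sigma_w: float = 0.0
    sigma_u: float = 0.0
    sigma_v: float = 0.0

    def __post_init__(self):
        for p in STREAK_COMPONENTS:
            if getattr(self, f"sigma_{p}") < 0:
                raise ValueError("streak strengths must be nonnegative")

    def as_tuple(self):
        return (self.sigma_w, self.sigma_u, self.sigma_v)


@dataclass
class ProbeKernelBank:
    """Separable 3-D probe kernels, one per streak component.

    Each probe is stored as its three 1-D factors (angle, horizontal,
    vertical); every factor has unit Euclidean norm.
    """

    factors: dict  # component -> (f0, f1, f2)

    def kernel(self, q: str) -> np.ndarray:
        f0, f1, f2 = self.factors[q]
        return f0[:, None, None] * f1[None, :, None] * f2[None, None, :]


def _gaussian_factor(std: float) -> np.ndarray:
    """1-D Gaussian truncated at +-3 std, unit l2 norm."""
    half = max(1, int(np.ceil(3.0 * std)))
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / std) ** 2)
    return g / np.sqrt(np.sum(g**2))


def build_probe_bank(shape) -> ProbeKernelBank:
    """Probe kernels for a volume of shape ``(m0, m1, m2)``.

    * ``w`` probe: angular low-pass x high-pass on both displacements
      (responds to streaks white across displacement);
    * ``u`` probe: angular low-pass x horizontal low-pass x vertical
      high-pass (responds to horizontally constant streaks);
    * ``v`` probe: angular low-pass x horizontal high-pass x vertical
      low-pass.
    """
    m0, m1, m2 = shape
    if min(m0, m1, m2) < 8:
        raise ValueError(f"volume shape {tuple(shape)} too small for probes")
    phi0 = _gaussian_factor(m0 / 8.0)
    phi1 = _gaussian_factor(m1 / 12.0)
    phi2 = _gaussian_factor(m2 / 12.0)
    psi = DB3_HIGHPASS
    if len(phi0) > m0 or len(phi1) > m1 or len(phi2) > m2:
        raise ValueError("probe factors exceed volume extents")
    return ProbeKernelBank(
        factors={
            "w": (phi0, psi, psi),
            "u": (phi0, phi1, psi),
            "v": (phi0, psi, phi2),
        }
    )


def _separable_valid_convolve(z: np.ndarray, factors) -> np.ndarray:
    out = np.asarray(z, dtype=np.float64)
    for axis, f in enumerate(factors):
        if len(f) > out.shape[axis]:
            raise ValueError("volume smaller than probe kernel")
        shape = [1, 1, 1]
        shape[axis] = len(f)
        out = signal.fftconvolve(out, np.asarray(f).reshape(shape), mode="valid")
    return out


def mad_std(z: np.ndarray, g_d) -> float:
    """Robust std of ``z`` convolved with ``g_d`` (valid region only).

    ``g_d`` is either a tuple/list of three 1-D factors or a full 3-D
    kernel.  The sample median is subtracted before taking the median
    absolute deviation so that a nonzero-mean filtered signal does not bias
    the estimate.
    """
    if isinstance(g_d, (tuple, list)):
        r = _separable_valid_convolve(z, g_d)
    else:
        g_d = np.asarray(g_d, dtype=np.float64)
        if any(k > s for k, s in zip(g_d.shape, np.shape(z))):
            raise ValueError("volume smaller than probe kernel")
        r = signal.fftconvolve(np.asarray(z, dtype=np.float64), g_d, mode="valid")
    r = r.ravel()
    med = np.median(r)
    return float(MAD_SCALE * np.median(np.abs(r - med)))


def convolved_norm(g_s, g_d, shape) -> float:
    """Euclidean norm of ``g_s * g_d`` (circular convolution on ``shape``).

    ``g_s`` is a component kernel (:class:`CorrelationKernel` or array on the
    full grid); ``g_d`` is a probe kernel given as a 3-D array or as three
    separable 1-D factors.
    """
    from .noise_model import CorrelationKernel, psd_from_kernel

    if not isinstance(g_s, CorrelationKernel):
        g_s = CorrelationKernel(g=np.asarray(g_s, dtype=np.float64))
    psd = psd_from_kernel(g_s, shape).psd
    if isinstance(g_d, (tuple, list)):
        parts = [np.abs(np.fft.fft(f, n=shape[ax])) ** 2 for ax, f in enumerate(g_d)]
        transfer = (
            parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]
        )
    else:
        transfer = np.abs(sp_fft.fftn(np.asarray(g_d, dtype=np.float64), s=shape)) ** 2
    size = float(np.prod(shape))
    return float(np.sqrt(np.sum(psd * transfer) / size**2))


def scale_from_std(sigma_hat: float, g_s, g_d=None, shape=None) -> float:
    """Component strength from a probe reading: ``sigma_hat / ||g_s * g_d||``.

    ``g_s`` may also be the precomputed response norm itself (scalar), in
    which case ``g_d`` is ignored.
    """
    if np.isscalar(g_s):
        norm = float(g_s)
    else:
        if shape is None:
            shape = np.asarray(getattr(g_s, "g", g_s)).shape
        norm = convolved_norm(g_s, g_d, shape)
    if norm <= 0:
        raise ValueError("probe has no response to this noise component")
    return float(sigma_hat) / norm


def _probe_transfer(bank: ProbeKernelBank, q: str, shape) -> np.ndarray:
    """Squared frequency response |F g_q|^2 on the full grid (separable)."""
    parts = []
    for axis, f in enumerate(bank.factors[q]):
        spec = np.abs(np.fft.fft(f, n=shape[axis])) ** 2
        parts.append(spec)
    return (
        parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]
    )


def response_matrix(
    set_: StreakComponentSet, bank: ProbeKernelBank, include_white: bool = True
) -> np.ndarray:
    """Response energies ``M[q, p] = ||g_p * g_q||^2``.

    Row ``q`` is a probe, column ``p`` a unit-strength streak component of
    the given scale (residual transfer included when the set carries it);
    the probe reading satisfies ``sigma_q^2 ~= sum_p sigma_p^2 M[q, p]``.

    With ``include_white`` a fourth, nuisance column models angularly
    non-constant white noise (unit response for every unit-norm probe), so
    that e.g. Poissonian noise in the data is not misattributed to the
    streak components; its solved strength is discarded by the unmixer.
    """
    shape = set_.shape
    size = float(np.prod(shape))
    comp_psds = {p: component_psd(p, set_) for p in STREAK_COMPONENTS}
    M = np.empty((3, 4 if include_white else 3))
    for qi, q in enumerate(STREAK_COMPONENTS):
        transfer = _probe_transfer(bank, q, shape)
        for pi, p in enumerate(STREAK_COMPONENTS):
            M[qi, pi] = float(np.sum(comp_psds[p] * transfer)) / size**2
        if include_white:
            M[qi, 3] = float(transfer.sum()) / size  # flat unit-variance PSD
    return M


def unmix_components(sigma_hats, M: np.ndarray) -> StreakParams:
    """Solve ``min_{s >= 0} ||M s - sigma_hats^2||`` on the variance scale.

    Probe readings overlap (the white component leaks into the low-frequency
    probes), which the full response matrix accounts for; the returned
    strengths are the nonnegative roots of the solved variances.
    """
    b = np.asarray(sigma_hats, dtype=np.float64) ** 2
    s, _ = nnls(np.asarray(M, dtype=np.float64), b)
    s = np.sqrt(np.maximum(s, 0.0))
    # any trailing nuisance components (white noise) are discarded
    return StreakParams(sigma_w=s[0], sigma_u=s[1], sigma_v=s[2])


def estimate_segment_params(
    segment: np.ndarray,
    set_: StreakComponentSet,
    bank: ProbeKernelBank | None = None,
    M: np.ndarray | None = None,
) -> StreakParams:
    """MAD probes -> NNLS unmixing on a single (segment) volume."""
    if bank is None:
        bank = build_probe_bank(segment.shape)
    if M is None:
        M = response_matrix(set_, bank)
    sigma_hats = [mad_std(segment, bank.factors[q]) for q in STREAK_COMPONENTS]
    return unmix_components(sigma_hats, M)
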