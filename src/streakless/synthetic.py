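"""Synthetic projection fixtures: a procedural phantom, the streak/Poisson
corruption model, and the sample-statistics SNR metric.

The corruption follows the count-domain composition
``noisy = Poisson(A) * exp(eta)`` with an angle-constant streak field
``eta`` built from the three displacement-structure components; the
"streak-free yet noisy" reference ``Y`` uses the same Poisson draw with the
streak field set to zero (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["SyntheticConfig", "make_phantom_projections", "streak_field", "corrupt", "snr"]


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic experiment."""

    shape: tuple = (64, 96, 64)  # (angle, horizontal, vertical)
    peak: float = np.inf  # scale of A; np.inf disables Poisson noise
    sigma_w: float = 0.02
    sigma_u: float = 0.0
    sigma_v: float = 0.0
    n_ellipsoids: int = 8  # 0 yields an empty phantom (constant projections)
    ellipsoids: tuple | None = None  # explicit (center, radii, amplitude) triples
    seed: int = 0

    def __post_init__(self):
        if not (self.peak > 0):
            raise ValueError("peak must be positive (or inf)")
        if min(self.sigma_w, self.sigma_u, self.sigma_v) < 0:
            raise ValueError("streak stds must be nonnegative")


def _ellipsoid_volume(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Random-ellipsoid attenuation volume of shape (h, h, v)."""
    _, m1, m2 = cfg.shape
    vol = np.zeros((m1, m1, m2))
    yy, xx, zz = np.meshgrid(
        np.linspace(-1, 1, m1), np.linspace(-1, 1, m1), np.linspace(-1, 1, m2), indexing="ij"
    )
    if cfg.ellipsoids is not None:
        shapes = cfg.ellipsoids
    elif cfg.n_ellipsoids <= 0:
        shapes = []
    else:
        n = max(5, min(10, cfg.n_ellipsoids))
        shapes = [
            (rng.uniform(-0.5, 0.5, size=3), rng.uniform(0.08, 0.35, size=3), rng.uniform(0.2, 1.0))
            for _ in range(n)
        ]
    for c, r, a in shapes:
        vol += a * (
            ((yy - c[0]) / r[0]) ** 2 + ((xx - c[1]) / r[1]) ** 2 + ((zz - c[2]) / r[2]) ** 2
            <= 1.0
        )
    return vol


def make_phantom_projections(cfg: SyntheticConfig) -> np.ndarray:
    """Noise-free positive projection stack ``A`` scaled to [peak/2, peak].

    A volume of random ellipsoids is parallel-beam projected (rotation about
    the vertical axis followed by axial summation), and the line integrals
    are exponentiated so that the weakest transmission equals half the peak.
    Deterministic for a given config (seeded internally).
    """
    m0, m1, m2 = cfg.shape
    rng = np.random.default_rng(cfg.seed)
    vol = _ellipsoid_volume(cfg, rng)
    angles = np.linspace(0.0, 180.0, m0, endpoint=False)
    proj = np.empty(cfg.shape)
    for i, ang in enumerate(angles):
        rot = ndimage.rotate(vol, ang, axes=(0, 1), reshape=False, order=1, mode="constant")
        proj[i] = rot.sum(axis=0)
    peak = cfg.peak if np.isfinite(cfg.peak) else 1.0
    pmax = proj.max()
    if pmax > 0:
        proj = proj * (np.log(2.0) / pmax)  # exp(-proj) in [1/2, 1]
    return peak * np.exp(-proj)


def streak_field(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Angle-constant streak noise field with the configured component mix."""
    m0, m1, m2 = cfg.shape
    eta = np.zeros((m1, m2))
    if cfg.sigma_w > 0:
        eta += cfg.sigma_w * rng.standard_normal((m1, m2))
    if cfg.sigma_u > 0:  # constant across horizontal
        eta += cfg.sigma_u * rng.standard_normal((1, m2))
    if cfg.sigma_v > 0:  # constant across vertical
        eta += cfg.sigma_v * rng.standard_normal((m1, 1))
    return np.broadcast_to(eta[None, :, :], cfg.shape).copy()


def corrupt(A: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Corrupt noise-free projections ``A`` with streaks and Poisson noise.

    Returns ``(Z, Y, lnA)``: the noisy log stack, the streak-free yet noisy
    log stack (same Poisson draw), and the clean log stack.  Counts are
    clamped at 0.5 before the logarithm to guard against zero variates.
    """
    A = np.asarray(A, dtype=np.float64)
    if np.any(A <= 0):
        raise ValueError("A must be strictly positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    eta = streak_field(cfg, rng)
    if np.isfinite(cfg.peak):
        counts = rng.poisson(A).astype(np.float64)
    else:
        counts = A.copy()
    counts = np.maximum(counts, 0.5)
    Z = np.log(counts * np.exp(eta))
    Y = np.log(counts)
    return Z, Y, np.log(A)


def snr(reference: np.ndarray, estimate: np.ndarray) -> float:
    """``10 log10( svar(reference) / smean((estimate - reference)^2) )``.

    Returns ``inf`` when the estimate matches the reference exactly.
    """
    reference = np.asarray(reference, dtype=np.float64)
    estimate = np.asarray(estimate, dtype=np.float64)
    if reference.shape != estimate.shape:
        raise ValueError("shape mismatch")
    err = np.mean((estimate - reference) ** 2)
    if err == 0:
        return np.inf
    return float(10.0 * np.log10(np.var(reference) / err))
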