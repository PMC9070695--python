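"""Summation binning / debinning operators for the multiscale pyramids.

All operators act on 3-D arrays with axis order ``(angle, horizontal,
vertical)``.  Binning is *summation* over adjacent pixels (so white-noise
variance multiplies by the block size), and the default debinning replicates
each coarse value over its block divided by the block size, which makes
``bin(debin(x)) == x`` hold exactly.  That exactness is what makes the
coarse-replacement recursion lossless when every denoiser is the identity.

Odd extents are padded by edge replication before binning and cropped back
after debinning; the original extents are simply passed to the debinning
calls as ``target_shape``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PyramidSpec",
    "bin2d",
    "debin2d",
    "bin_angular",
    "debin_angular",
    "bin3d",
    "debin3d",
    "replace_coarse",
]


@dataclass
class PyramidSpec:
    """Bookkeeping for a binning pyramid.

    Attributes
    ----------
    n_scales:
        Number of 2-D displacement binning steps ``K``.
    angular_target:
        Target angular size for the initial angular binning.
    n_poisson_scales:
        Number of 3-D binning steps used by the Poisson stage.
    shapes:
        Recorded (pre-padding) shape per displacement level, finest first.
    """

    n_scales: int
    angular_target: int = 32
    n_poisson_scales: int = 1
    shapes: list = field(default_factory=list)

    @staticmethod
    def default_n_scales(shape) -> int:
        """Number of displacement scales for a volume shape (overridable)."""
        m = min(shape[1], shape[2])
        return max(1, int(np.floor(np.log2(m / 64.0))) if m >= 128 else 1)


def _pad_even(x: np.ndarray, axes) -> np.ndarray:
    pad = [(0, 0)] * x.ndim
    needs = False
    for ax in axes:
        if x.shape[ax] % 2:
            pad[ax] = (0, 1)
            needs = True
    return np.pad(x, pad, mode="edge") if needs else x


def _sum_pairs(x: np.ndarray, axis: int) -> np.ndarray:
    n = x.shape[axis] // 2
    sl0 = [slice(None)] * x.ndim
    sl1 = [slice(None)] * x.ndim
    sl0[axis] = slice(0, 2 * n, 2)
    sl1[axis] = slice(1, 2 * n, 2)
    return x[tuple(sl0)] + x[tuple(sl1)]


def _replicate(x: np.ndarray, axis: int, target: int) -> np.ndarray:
    y = np.repeat(x, 2, axis=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, target)
    return y[tuple(sl)]


def bin2d(x: np.ndarray) -> np.ndarray:
    """Sum 2x2 displacement blocks; output displacement extents halve.

    White unit-variance noise comes out with variance 4.
    """
    x = np.asarray(x, dtype=np.float64)
    x = _pad_even(x, (1, 2))
    return _sum_pairs(_sum_pairs(x, 1), 2)


def debin2d(x: np.ndarray, target_shape) -> np.ndarray:
    """Replicate each coarse value over its 2x2 block divided by 4.

    ``bin2d(debin2d(x, s)) == x`` exactly for any coarse ``x`` whose binned
    shape is consistent with ``s``.
    """
    x = np.asarray(x, dtype=np.float64)
    if target_shape[0] != x.shape[0]:
        raise ValueError("debin2d does not act along the angular axis")
    for ax in (1, 2):
        if (target_shape[ax] + 1) // 2 != x.shape[ax]:
            raise ValueError(
                f"target shape {tuple(target_shape)} inconsistent with one "
                f"2-D binning step of {x.shape}"
            )
    y = _replicate(x / 4.0, 1, target_shape[1])
    return _replicate(y, 2, target_shape[2])


def bin_angular(x: np.ndarray, m_alpha: int = 32) -> np.ndarray:
    """Repeated pairwise angular summation until the angular size <= m_alpha."""
    if m_alpha < 1:
        raise ValueError("angular target must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    while x.shape[0] > m_alpha:
        x = _sum_pairs(_pad_even(x, (0,)), 0)
    return x


def debin_angular(x: np.ndarray, m0: int) -> np.ndarray:
    """Invert :func:`bin_angular` on coarse data (replication / 2 per step)."""
    x = np.asarray(x, dtype=np.float64)
    # reconstruct the ladder of sizes produced by bin_angular
    sizes = [m0]
    while sizes[-1] > x.shape[0]:
        sizes.append((sizes[-1] + 1) // 2)
    if sizes[-1] != x.shape[0]:
        raise ValueError(f"angular size {x.shape[0]} unreachable from {m0}")
    for target in sizes[-2::-1]:
        x = _replicate(x / 2.0, 0, target)
    return x


def bin3d(x: np.ndarray) -> np.ndarray:
    """Sum 2x2x2 blocks over all three axes (white-noise variance x8)."""
    x = np.asarray(x, dtype=np.float64)
    x = _pad_even(x, (0, 1, 2))
    for ax in (0, 1, 2):
        x = _sum_pairs(x, ax)
    return x


def debin3d(x: np.ndarray, target_shape) -> np.ndarray:
    """Replicate each coarse value over its 2x2x2 block divided by 8."""
    x = np.asarray(x, dtype=np.float64)
    for ax in (0, 1, 2):
        if (target_shape[ax] + 1) // 2 != x.shape[ax]:
            raise ValueError(
                f"target shape {tuple(target_shape)} inconsistent with one "
                f"3-D binning step of {x.shape}"
            )
    y = x / 8.0
    for ax in (0, 1, 2):
        y = _replicate(y, ax, target_shape[ax])
    return y


def debin2d_smooth(x: np.ndarray, target_shape) -> np.ndarray:
    """Cubic-interpolating debinning (no exact bin-debin identity)."""
    x = np.asarray(x, dtype=np.float64) / 4.0
    zoom = [1.0] + [target_shape[ax] / x.shape[ax] for ax in (1, 2)]
    y = ndimage.zoom(x, zoom, order=3, mode="nearest", grid_mode=True)
    return y


def replace_coarse(x_fine: np.ndarray, coarse_est: np.ndarray, bin_op, debin_op) -> np.ndarray:
    """Swap the coarse-scale content of ``x_fine`` for ``coarse_est``.

    Computes ``x_fine - debin(bin(x_fine)) + debin(coarse_est)``.  With the
    exact default debinning, passing ``coarse_est = bin(x_fine)`` returns
    ``x_fine`` unchanged (telescoping identity).
    """
    x_fine = np.asarray(x_fine, dtype=np.float64)
    binned = bin_op(x_fine)
    if binned.shape != np.asarray(coarse_est).shape:
        raise ValueError(
            f"coarse estimate shape {np.asarray(coarse_est).shape} does not "
            f"match binned shape {binned.shape}"
        )
    return x_fine - debin_op(binned, x_fine.shape) + debin_op(coarse_est, x_fine.shape)
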