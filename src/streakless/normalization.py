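"""Bright/dark-field normalization and the logarithmic transform.

Raw detector counts are turned into the additive-noise log domain in which
both denoising stages operate.  The sign convention keeps the logarithm of
the transmission (nonpositive for absorbing samples); any sign change for
reconstruction is downstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RawAcquisition",
    "ProjectionStack",
    "average_fields",
    "bright_field_normalize",
    "log_transform",
    "normalize_stack",
]

#: Internal axis order of every projection stack.
AXES = ("angle", "horizontal", "vertical")


@dataclass
class RawAcquisition:
    """Raw counts plus the calibration fields.

    ``p_raw`` has axes (angle, horizontal, vertical); the fields are 2-D
    arrays matching the detector (horizontal, vertical).
    """

    p_raw: np.ndarray
    bright: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.p_raw = np.asarray(self.p_raw, dtype=np.float64)
        self.bright = np.asarray(self.bright, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.p_raw.ndim != 3 or self.bright.ndim != 2 or self.dark.ndim != 2:
            raise ValueError("p_raw must be 3-D and the fields 2-D")
        if self.p_raw.shape[1:] != self.bright.shape or self.bright.shape != self.dark.shape:
            raise ValueError(
                f"field shape {self.bright.shape} does not match projections "
                f"{self.p_raw.shape[1:]}"
            )


@dataclass
class ProjectionStack:
    """Log-domain 3-D volume with fixed (angle, horizontal, vertical) axes."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("projection stack must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("projection stack contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


def average_fields(field_samples) -> np.ndarray:
    """Elementwise mean of repeated calibration-field acquisitions."""
    samples = [np.asarray(f, dtype=np.float64) for f in field_samples]
    if not samples:
        raise ValueError("no calibration field samples provided")
    shape = samples[0].shape
    if any(s.shape != shape for s in samples):
        raise ValueError("calibration field samples have differing shapes")
    return np.mean(samples, axis=0)


def bright_field_normalize(
    acq: RawAcquisition,
    floor_quantile: float = 1e-5,
    max_bad_fraction: float = 0.05,
) -> np.ndarray:
    """Normalize raw counts: ``(P_raw - I_D) / (I_B - I_D)``.

    Nonpositive values of numerator or denominator are clamped to a small
    positive floor (the ``floor_quantile`` quantile of the positive values,
    but at least 1e-6 of the bright-field median) before the division, so
    the subsequent logarithm is well defined.
    """
    denom = acq.bright - acq.dark
    bad = np.count_nonzero(denom <= 0)
    if bad > max_bad_fraction * denom.size:
        raise ValueError(
            f"bright - dark is nonpositive on {bad}/{denom.size} pixels; "
            "calibration data unusable"
        )
    numer = acq.p_raw - acq.dark[None, :, :]

    def _clamp(x: np.ndarray) -> np.ndarray:
        pos = x[x > 0]
        base = float(np.quantile(pos, floor_quantile)) if pos.size else 0.0
        floor = max(base, 1e-6 * max(float(np.median(acq.bright)), 1e-30))
        return np.where(x <= 0, floor, x)  # only nonpositive values are clamped

    return _clamp(numer) / _clamp(denom)[None, :, :]


def log_transform(p_norm: np.ndarray) -> ProjectionStack:
    """Elementwise natural logarithm of the normalized projections."""
    p_norm = np.asarray(p_norm, dtype=np.float64)
    if np.any(p_norm <= 0):
        raise ValueError("log transform requires strictly positive input; clamp upstream")
    return ProjectionStack(data=np.log(p_norm))


def normalize_stack(acq: RawAcquisition, floor_quantile: float = 1e-5) -> ProjectionStack:
    """Convenience: bright-field normalization followed by the log transform."""
    return log_transform(bright_field_normalize(acq, floor_quantile=floor_quantile))
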