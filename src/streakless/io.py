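"""Projection stack I/O: multi-page TIFF (one page per angle) and HDF5.

Axis order on disk is configurable at read time; the internal order is
always (angle, horizontal, vertical).  Data are written as 32-bit floats,
all internal computation is 64-bit.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import tifffile

from .normalization import ProjectionStack

__all__ = ["read_stack", "write_stack", "read_field", "write_field"]

_CANONICAL = ("angle", "h", "v")


def _permutation(axis_order) -> tuple:
    order = tuple(axis_order)
    if sorted(order) != sorted(_CANONICAL):
        raise ValueError(f"axis order must be a permutation of {_CANONICAL}, got {order}")
    return tuple(order.index(ax) for ax in _CANONICAL)


def read_stack(path, axis_order=("angle", "h", "v"), dataset: str = "data") -> ProjectionStack:
    """Read a 3-D stack from TIFF or HDF5 and put axes in internal order."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such stack: {path}")
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            arr = np.asarray(f[dataset])
    else:
        arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D stack in {path}, got shape {arr.shape}")
    arr = np.transpose(arr, _permutation(axis_order))
    return ProjectionStack(data=arr.astype(np.float64))


def write_stack(stack: ProjectionStack, path, dataset: str = "data") -> None:
    """Write a stack (32-bit float) as multi-page TIFF or HDF5."""
    path = os.fspath(path)
    data = stack.data.astype(np.float32)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=data)
    else:
        tifffile.imwrite(path, data)


def read_field(path, dataset: str = "data") -> np.ndarray:
    """Read a 2-D calibration field (or a stack of samples to be averaged)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such field image: {path}")
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            arr = np.asarray(f[dataset])
    else:
        arr = tifffile.imread(path)
    return arr.astype(np.float64)


def write_field(field: np.ndarray, path, dataset: str = "data") -> None:
    path = os.fspath(path)
    data = np.asarray(field, dtype=np.float32)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=data)
    else:
        tifffile.imwrite(path, data)
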