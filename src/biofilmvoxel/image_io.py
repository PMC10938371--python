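"""Voxel lattices with physical geometry, and multi-page TIFF I/O.

The substrate of every spatial operation in this package is a 3D lattice of
voxels with anisotropic physical edge lengths: confocal z-stacks have a slice
thickness (dz, typically 0.5 μm) that differs from the in-plane pixel pitch
(dy = dx, set by field of view / pixel count). Axis order is (z, y, x),
0-based, everywhere. Spacing is declared by the caller — TIFF metadata
dialects for voxel size are too inconsistent to rely on.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "MultiChannelStack",
    "read_stack",
    "write_stack",
    "split_channels",
    "read_mask",
    "write_mask",
]


def _check_geometry(values: np.ndarray, spacing_um: tuple) -> tuple:
    if values.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) array, got ndim={values.ndim}")
    if any(s < 1 for s in values.shape):
        raise ValueError(f"every dimension must be >= 1, got shape {values.shape}")
    spacing = tuple(float(s) for s in spacing_um)
    if len(spacing) != 3:
        raise ValueError("spacing_um must have three components (dz, dy, dx)")
    if any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing components must be positive finite, got {spacing}")
    return spacing


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """A 3D intensity lattice with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Nonnegative finite intensities.
    spacing_um : (dz, dy, dx)
        Physical voxel edge lengths in μm.
    name : str
        Channel / species label.
    """

    values: np.ndarray
    spacing_um: tuple
    name: str = ""

    def __post_init__(self):
        spacing = _check_geometry(self.values, self.spacing_um)
        object.__setattr__(self, "spacing_um", spacing)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if np.any(self.values < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean lattice with physical voxel spacing (foreground = True)."""

    values: np.ndarray
    spacing_um: tuple
    name: str = ""

    def __post_init__(self):
        spacing = _check_geometry(self.values, self.spacing_um)
        object.__setattr__(self, "spacing_um", spacing)
        if self.values.dtype != bool:
            raise ValueError(f"mask values must be boolean, got dtype {self.values.dtype}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx


@dataclasses.dataclass(frozen=True)
class MultiChannelStack:
    """An ordered collection of congruent channels (one VoxelGrid per fluorochrome).

    All channels must share shape and spacing; channel names must be unique.
    ``metadata`` carries acquisition context (treatment, day, replicate).
    """

    channels: tuple
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        channels = tuple(self.channels)
        object.__setattr__(self, "channels", channels)
        if not channels:
            raise ValueError("a stack needs at least one channel")
        ref = channels[0]
        names = []
        for ch in channels:
            if ch.shape != ref.shape or ch.spacing_um != ref.spacing_um:
                raise ValueError("all channels must be congruent in shape and spacing")
            names.append(ch.name)
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")

    @property
    def channel_names(self) -> list:
        return [ch.name for ch in self.channels]

    @property
    def shape(self) -> tuple:
        return self.channels[0].shape

    @property
    def spacing_um(self) -> tuple:
        return self.channels[0].spacing_um

    def channel(self, name: str) -> VoxelGrid:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel named {name!r}; have {self.channel_names}")


def split_channels(stack: MultiChannelStack) -> list:
    """Return the stack's channels as a list of grids, order preserved."""
    return list(stack.channels)


def read_stack(
    path,
    spacing_um: Sequence[float],
    channel_names: Sequence[str],
    interleave: str = "channels_fastest",
) -> MultiChannelStack:
    """Read a multi-page grayscale TIFF as a multi-channel stack.

    The page count must be divisible by ``len(channel_names)``. Two page
    orderings occur in exported CLSM data: ``channels_fastest`` (page index =
    z * C + c, the default) and ``z_fastest`` (page = c * Z + z).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pages = np.asarray(tifffile.imread(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2D grayscale pages, got shape {pages.shape}")
    n_channels = len(channel_names)
    if n_channels < 1:
        raise ValueError("need at least one channel name")
    n_pages = pages.shape[0]
    if n_pages % n_channels != 0:
        raise ValueError(
            f"page count {n_pages} is not divisible by channel count {n_channels}"
        )
    nz = n_pages // n_channels
    if interleave == "channels_fastest":
        per_channel = pages.reshape(nz, n_channels, *pages.shape[1:]).transpose(1, 0, 2, 3)
    elif interleave == "z_fastest":
        per_channel = pages.reshape(n_channels, nz, *pages.shape[1:])
    else:
        raise ValueError(f"unknown interleave mode {interleave!r}")
    grids = [
        VoxelGrid(np.ascontiguousarray(per_channel[c]), tuple(spacing_um), name)
        for c, name in enumerate(channel_names)
    ]
    return MultiChannelStack(tuple(grids))


def write_stack(stack: MultiChannelStack, path, interleave: str = "channels_fastest") -> None:
    """Write a stack as a multi-page grayscale TIFF (inverse of :func:`read_stack`)."""
    arrays = np.stack([ch.values for ch in stack.channels])  # (C, Z, Y, X)
    if interleave == "channels_fastest":
        pages = arrays.transpose(1, 0, 2, 3).reshape(-1, *arrays.shape[2:])
    elif interleave == "z_fastest":
        pages = arrays.reshape(-1, *arrays.shape[2:])
    else:
        raise ValueError(f"unknown interleave mode {interleave!r}")
    tifffile.imwrite(Path(path), pages)


def write_mask(mask: BinaryMask, path) -> None:
    """Store a binary mask as an 8-bit TIFF with foreground = 255."""
    tifffile.imwrite(Path(path), mask.values.astype(np.uint8) * 255)


def read_mask(path, spacing_um: Sequence[float], name: str = "") -> BinaryMask:
    """Read an 8-bit 0/255 TIFF as a binary mask; any other value is an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    values = np.asarray(tifffile.imread(path))
    if values.ndim == 2:
        values = values[None]
    distinct = np.unique(values)
    if not np.all(np.isin(distinct, (0, 255))):
        bad = [int(v) for v in distinct if v not in (0, 255)]
        raise ValueError(f"mask file contains non-binary values {bad}; expected only 0 and 255")
    return BinaryMask(values == 255, tuple(spacing_um), name)
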