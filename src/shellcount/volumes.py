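"""Core in-memory containers: physical voxel calibration and 3D volumes.

All arrays are ordered ``(z, y, x)`` — z is the page axis of a multi-page
TIFF and the optical (depth) axis of a confocal stack.  Coordinates are
0-based voxel centers; the physical depth of a voxel at index ``z`` is
``z * dz`` micrometres measured from the first (shallowest) imaged plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoxelGeometry",
    "IntensityVolume",
    "LabelVolume",
    "BinaryMask",
    "um3_to_voxels",
    "bin_volume_50pct",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical calibration binding voxel indices to micrometres.

    Parameters
    ----------
    dx, dy, dz : float
        Voxel spacing in µm along x, y and z.  A typical confocal stack of
        (1024 × 1024) pixels covering (211 × 211) µm at 400 planes over
        100 µm has ``dx = dy = 211/1024 ≈ 0.206`` and ``dz = 100/400 = 0.25``.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(
                f"voxel spacings must be positive, got "
                f"(dx={self.dx}, dy={self.dy}, dz={self.dz})"
            )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³ (= dx · dy · dz)."""
        return self.dx * self.dy * self.dz

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Spacing in array axis order (z, y, x)."""
        return (self.dz, self.dy, self.dx)

    def scaled(self, factor: float) -> "VoxelGeometry":
        """Geometry with every spacing multiplied by ``factor``."""
        return VoxelGeometry(self.dx * factor, self.dy * factor, self.dz * factor)


def _check_3d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) array, got shape {data.shape}")
    return data


@dataclass
class IntensityVolume:
    """One fluorescence channel of a 3D stack, with physical calibration."""

    data: np.ndarray
    geometry: VoxelGeometry
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3D instance segmentation: 0 = background, k > 0 = instance k.

    Label ids need not be contiguous and per-instance connectivity is not
    enforced (upstream segmenters make no such guarantee).
    """

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("label ids must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def ids(self) -> np.ndarray:
        """Sorted array of instance ids present (background excluded)."""
        ids = np.unique(self.data)
        return ids[ids > 0]


@dataclass
class BinaryMask:
    """3D boolean mask paired with the geometry of its source volume."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data).astype(bool, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def um3_to_voxels(threshold_um3: float, geometry: VoxelGeometry) -> int:
    """Convert a physical volume threshold to a voxel count.

    Returns ``ceil(threshold_um3 / voxel_volume)``: an object "larger than
    T µm³" is kept iff its voxel count × voxel_volume exceeds T, so the
    smallest surviving voxel count is ``ceil(T / v) (+1 when T/v is integral)``
    under the strict ``>`` comparison applied by the size filters.
    """
    if threshold_um3 < 0:
        raise ValueError("threshold must be non-negative")
    return int(math.ceil(threshold_um3 / geometry.voxel_volume))


def bin_volume_50pct(vol: IntensityVolume) -> IntensityVolume:
    """Downsample a volume to 50% per axis by 2×2×2 block averaging.

    Block-mean binning (rather than decimation) reduces shot noise before
    segmentation.  Odd trailing planes/rows/columns are dropped; the voxel
    spacing doubles along every axis.
    """
    data = vol.data
    if any(s < 2 for s in data.shape):
        raise ValueError(f"every axis must have length >= 2, got shape {data.shape}")
    nz, ny, nx = (s - s % 2 for s in data.shape)
    trimmed = data[:nz, :ny, :nx].astype(np.float64)
    binned = trimmed.reshape(nz // 2, 2, ny // 2, 2, nx // 2, 2).mean(axis=(1, 3, 5))
    return IntensityVolume(
        data=binned,
        geometry=vol.geometry.scaled(2.0),
        channel_name=vol.channel_name,
    )
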