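"""Stack I/O (TIFF / OME-TIFF), experiment manifests and run configuration.

Stacks are read page-major: the TIFF page axis becomes the z (depth) axis.
Voxel sizes are taken from OME-XML ``PhysicalSizeX/Y/Z`` attributes when
present, otherwise from a user-supplied override geometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .volumes import BinaryMask, IntensityVolume, LabelVolume, VoxelGeometry

__all__ = [
    "read_stack",
    "read_labels",
    "read_mask",
    "write_stack",
    "write_labels",
    "write_mask",
    "ManifestRecord",
    "ExperimentManifest",
    "read_manifest",
    "load_config",
]

_MANIFEST_COLUMNS = [
    "stack_id",
    "organoid_id",
    "condition",
    "timepoint",
    "area_index",
    "include",
    "reason",
]


def _geometry_from_ome(xml: str) -> VoxelGeometry | None:
    """Pull PhysicalSizeX/Y/Z (assumed µm) out of an OME-XML blob."""
    sizes = {}
    for axis in ("X", "Y", "Z"):
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', xml)
        if m:
            sizes[axis] = float(m.group(1))
    if set(sizes) == {"X", "Y", "Z"}:
        return VoxelGeometry(dx=sizes["X"], dy=sizes["Y"], dz=sizes["Z"])
    return None


def _read_array_and_geometry(
    path: str | Path, override_geometry: VoxelGeometry | None
) -> tuple[np.ndarray, VoxelGeometry]:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            geometry = None
            if tif.ome_metadata:
                geometry = _geometry_from_ome(tif.ome_metadata)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise IOError(f"could not read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {data.shape}")
    if geometry is None:
        geometry = override_geometry
    if geometry is None:
        raise ValueError(
            f"{path}: no PhysicalSizeX/Y/Z metadata found and no override geometry "
            "given; supply VoxelGeometry(dx, dy, dz) in µm"
        )
    return data, geometry


def read_stack(
    path: str | Path,
    override_geometry: VoxelGeometry | None = None,
    channel_name: str = "",
) -> IntensityVolume:
    """Read an intensity stack; z is the page axis, metadata beats override."""
    data, geometry = _read_array_and_geometry(path, override_geometry)
    return IntensityVolume(data=data, geometry=geometry, channel_name=channel_name)


def read_labels(
    path: str | Path, override_geometry: VoxelGeometry | None = None
) -> LabelVolume:
    """Read an instance-label stack (0 = background) from uint TIFF."""
    data, geometry = _read_array_and_geometry(path, override_geometry)
    return LabelVolume(data=data.astype(np.uint32, copy=False), geometry=geometry)


def read_mask(
    path: str | Path, override_geometry: VoxelGeometry | None = None
) -> BinaryMask:
    """Read a binary mask stack (nonzero = foreground)."""
    data, geometry = _read_array_and_geometry(path, override_geometry)
    return BinaryMask(data=data > 0, geometry=geometry)


def _ome_kwargs(geometry: VoxelGeometry) -> dict:
    return {
        "photometric": "minisblack",  # never let a size-3/4 x axis look like RGB
        "metadata": {
            "axes": "ZYX",
            "PhysicalSizeX": geometry.dx,
            "PhysicalSizeY": geometry.dy,
            "PhysicalSizeZ": geometry.dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        }
    }


def write_stack(path: str | Path, vol: IntensityVolume) -> None:
    """Write an intensity volume as OME-TIFF with physical voxel sizes."""
    tifffile.imwrite(str(path), vol.data, ome=True, **_ome_kwargs(vol.geometry))


def write_labels(path: str | Path, labels: LabelVolume) -> None:
    tifffile.imwrite(
        str(path), labels.data.astype(np.uint32), ome=True, **_ome_kwargs(labels.geometry)
    )


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(
        str(path), mask.data.astype(np.uint8), ome=True, **_ome_kwargs(mask.geometry)
    )


@dataclass(frozen=True)
class ManifestRecord:
    """One imaged area: which organoid, condition and timepoint it belongs to."""

    stack_id: str
    organoid_id: str
    condition: str
    timepoint: str
    area_index: int
    include: bool = True
    reason: str = ""


class ExperimentManifest:
    """Maps stacks → area → organoid → condition → timepoint.

    Excluded records (``include == False``) must carry a reason, mirroring the
    practice of documenting every stack dropped from evaluation.
    """

    def __init__(self, records: list[ManifestRecord]):
        seen: set[tuple[str, int, str]] = set()
        for rec in records:
            key = (rec.organoid_id, rec.area_index, rec.timepoint)
            if key in seen:
                raise ValueError(
                    f"duplicate (organoid_id, area_index, timepoint) = {key} in manifest"
                )
            seen.add(key)
            if not rec.include and not rec.reason:
                raise ValueError(
                    f"excluded stack {rec.stack_id!r} has no exclusion reason"
                )
        self.records = list(records)

    def included(self) -> list[ManifestRecord]:
        return [r for r in self.records if r.include]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=_MANIFEST_COLUMNS)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_manifest(path: str | Path) -> ExperimentManifest:
    """Read a manifest CSV (stack_id,organoid_id,condition,timepoint,area_index,include,reason)."""
    df = pd.read_csv(path, dtype={"stack_id": str, "organoid_id": str}, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        include = str(row["include"]).strip().lower() in {"1", "true", "yes", "y"}
        records.append(
            ManifestRecord(
                stack_id=str(row["stack_id"]),
                organoid_id=str(row["organoid_id"]),
                condition=str(row["condition"]),
                timepoint=str(row["timepoint"]),
                area_index=int(row["area_index"]),
                include=include,
                reason=str(row.get("reason", "")),
            )
        )
    return ExperimentManifest(records)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration {path} must be a YAML mapping")
    return cfg
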