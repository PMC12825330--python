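"""Per-nucleus records from a 3D instance segmentation.

A nuclei instance-label volume (from Cellpose or any other segmenter) is
filtered by physical volume and reduced to per-nucleus records: voxel count,
volume, centroid, and a moment-based minimal ellipsoidal representation.
The ellipsoids are QC/visualization artifacts; transduction classification
never uses them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import IntensityVolume, LabelVolume, VoxelGeometry

__all__ = [
    "NucleusRecord",
    "Ellipsoid",
    "CellposeSettings",
    "CapabilityError",
    "cellpose_adapter",
    "apply_volume_band",
    "filter_nuclei",
    "fit_ellipsoid",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


class CapabilityError(RuntimeError):
    """An optional external capability (e.g. Cellpose) is unavailable."""


@dataclass
class Ellipsoid:
    """Moment-fitted solid ellipsoid: center (µm), semi-axes (µm), orientation.

    Semi-axes follow the uniform-solid-ellipsoid moment relation
    ``a_i = sqrt(5 * eigenvalue_i)`` of the voxel-coordinate covariance.
    ``axes`` rows are the orthonormal principal directions in (x, y, z).
    """

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    axes: np.ndarray  # (3, 3) orthonormal, rows = principal directions
    degenerate: bool = False


@dataclass
class NucleusRecord:
    """One segmented nucleus."""

    label_id: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, float, float]  # (x, y, z) from the stack origin
    ellipsoid: Ellipsoid | None = None

    @property
    def depth_um(self) -> float:
        """Centroid depth below the first (shallowest) imaged plane."""
        return self.centroid_um[2]


@dataclass
class CellposeSettings:
    """Pass-through settings for the external Cellpose segmenter."""

    diameter_um: float = 5.0
    flow_threshold: float = 1.0
    cellprob_threshold: float = -6.0
    model: str = "CPx"
    max_tile_px: int = 4096
    min_volume_um3: float = 10.0
    max_volume_um3: float = math.inf  # nominally "1 m^3" upstream, i.e. unbounded


def cellpose_adapter(vol: IntensityVolume, settings: CellposeSettings | None = None) -> LabelVolume:
    """Segment nuclei with Cellpose, if installed, and band-filter by volume.

    This pipeline does not ship a segmenter: precomputed label volumes are a
    first-class input and fully bypass this adapter.  When Cellpose is not
    importable a :class:`CapabilityError` explains how to proceed.
    """
    settings = settings or CellposeSettings()
    try:
        from cellpose import models  # type: ignore
    except ImportError as exc:
        raise CapabilityError(
            "Cellpose is not installed; segment the nuclei channel externally and "
            "supply the label volume directly (read_labels), or install cellpose"
        ) from exc
    model = models.CellposeModel(model_type=settings.model, gpu=False)
    diam_px = settings.diameter_um / vol.geometry.dx
    masks = model.eval(
        vol.data,
        diameter=diam_px,
        flow_threshold=settings.flow_threshold,
        cellprob_threshold=settings.cellprob_threshold,
        do_3D=True,
    )[0]
    labels = LabelVolume(data=np.asarray(masks, dtype=np.uint32), geometry=vol.geometry)
    return apply_volume_band(labels, settings.min_volume_um3, settings.max_volume_um3)


def _compact(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary label ids to 0..n; returns (ids present incl. 0, inverse image)."""
    ids, inverse = np.unique(labels, return_inverse=True)
    return ids, inverse.reshape(labels.shape)

def _label_counts(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids, inv = _compact(labels)
    counts = np.bincount(inv.ravel(), minlength=len(ids))
    return ids, counts


def apply_volume_band(
    labels: LabelVolume,
    min_volume_um3: float = 10.0,
    max_volume_um3: float = math.inf,
) -> LabelVolume:
    """Remove instances outside the physical-volume band (min, max].

    The lower bound is strict ("larger than"), matching every size filter in
    the pipeline; the upper bound is effectively unbounded by default.
    """
    ids, counts = _label_counts(labels.data)
    volumes = counts * labels.geometry.voxel_volume
    keep = (volumes > min_volume_um3) & (volumes <= max_volume_um3)
    keep[ids == 0] = False
    drop_ids = ids[(ids > 0) & ~keep]
    out = labels.data.copy()
    if drop_ids.size:
        out[np.isin(out, drop_ids)] = 0
    return LabelVolume(data=out, geometry=labels.geometry)


def fit_ellipsoid(voxels_zyx: np.ndarray, geometry: VoxelGeometry) -> Ellipsoid:
    """Fit a minimal ellipsoidal representation to one nucleus's voxel set.

    Center is the voxel centroid; the principal directions are eigenvectors
    of the covariance of the voxel coordinates (in µm); each semi-axis is
    ``sqrt(5 λ_i)``, the relation that holds exactly for a uniform solid
    ellipsoid.  Degenerate (coplanar or near-coplanar) sets fall back to a
    minimum semi-axis of one voxel spacing and are flagged.
    """
    voxels_zyx = np.atleast_2d(np.asarray(voxels_zyx, dtype=np.float64))
    if voxels_zyx.shape[0] < 1:
        raise ValueError("empty voxel set")
    dz, dy, dx = geometry.spacing_zyx
    coords_xyz = voxels_zyx[:, ::-1] * np.array([dx, dy, dz])
    center = coords_xyz.mean(axis=0)
    degenerate = False
    min_spacing = min(dx, dy, dz)
    if voxels_zyx.shape[0] < 4:
        degenerate = True
        semi = np.full(3, min_spacing)
        axes = np.eye(3)
    else:
        cov = np.cov(coords_xyz, rowvar=False, bias=True)
        eigvals, eigvecs = np.linalg.eigh(cov)
        semi = np.sqrt(5.0 * np.clip(eigvals, 0.0, None))
        if np.any(semi < 1e-9):  # coplanar set: at least one vanishing moment
            degenerate = True
            semi = np.maximum(semi, min_spacing)
        axes = eigvecs.T
    return Ellipsoid(
        center_um=tuple(center),
        semi_axes_um=tuple(semi),
        axes=axes,
        degenerate=degenerate,
    )


def _records_from_labels(
    labels: LabelVolume, fit_ellipsoids: bool
) -> list[NucleusRecord]:
    data = labels.data
    geometry = labels.geometry
    ids, inv = _compact(data)
    n = len(ids)
    counts = np.bincount(inv.ravel(), minlength=n)
    zz, yy, xx = np.indices(data.shape, sparse=True)
    flat = inv.ravel()
    sums = {}
    for name, coord in (("z", zz), ("y", yy), ("x", xx)):
        sums[name] = np.bincount(
            flat, weights=np.broadcast_to(coord, data.shape).ravel(), minlength=n
        )
    dz, dy, dx = geometry.spacing_zyx
    records: list[NucleusRecord] = []
    if fit_ellipsoids:
        # voxel coordinate lists per compact label, via one argsort of the volume
        order = np.argsort(flat, kind="stable")
        bounds = np.searchsorted(flat[order], np.arange(n + 1))
        coords_all = np.column_stack(np.unravel_index(order, data.shape))
    for k in range(n):
        label_id = int(ids[k])
        if label_id == 0:
            continue
        cnt = int(counts[k])
        cz = sums["z"][k] / cnt * dz
        cy = sums["y"][k] / cnt * dy
        cx = sums["x"][k] / cnt * dx
        ellipsoid = None
        if fit_ellipsoids:
            vox = coords_all[bounds[k] : bounds[k + 1]]
            ellipsoid = fit_ellipsoid(vox, geometry)
        records.append(
            NucleusRecord(
                label_id=label_id,
                voxel_count=cnt,
                volume_um3=cnt * geometry.voxel_volume,
                centroid_um=(cx, cy, cz),
                ellipsoid=ellipsoid,
            )
        )
    return records


def filter_nuclei(
    labels: LabelVolume,
    min_volume_um3: float = 100.0,
    fit_ellipsoids: bool = False,
) -> tuple[LabelVolume, list[NucleusRecord]]:
    """Drop nuclei not strictly larger than ``min_volume_um3``; build records.

    Returns the cleaned label volume together with one record per surviving
    nucleus.  The final denominator of the transduction efficiency is the
    count of these nuclei that additionally pass the shell-size filter (see
    :mod:`shellcount.shells`).
    """
    ids, counts = _label_counts(labels.data)
    volumes = counts * labels.geometry.voxel_volume
    drop_ids = ids[(ids > 0) & ~(volumes > min_volume_um3)]
    out = labels.data.copy()
    if drop_ids.size:
        out[np.isin(out, drop_ids)] = 0
    cleaned = LabelVolume(data=out, geometry=labels.geometry)
    records = _records_from_labels(cleaned, fit_ellipsoids=fit_ellipsoids)
    logger.info(
        "nuclei volume filter (> %.1f µm³): %d -> %d instances",
        min_volume_um3,
        int(np.sum(ids > 0)),
        len(records),
    )
    return cleaned, records


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Tabulate records (one row per nucleus) for CSV export."""
    rows = []
    for r in records:
        row = {
            "label_id": r.label_id,
            "voxel_count": r.voxel_count,
            "volume_um3": r.volume_um3,
            "cx_um": r.centroid_um[0],
            "cy_um": r.centroid_um[1],
            "cz_um": r.centroid_um[2],
        }
        if r.ellipsoid is not None:
            e = r.ellipsoid
            row.update(
                {
                    "semi_a_um": e.semi_axes_um[0],
                    "semi_b_um": e.semi_axes_um[1],
                    "semi_c_um": e.semi_axes_um[2],
                    "degenerate": e.degenerate,
                }
            )
            for i in range(3):
                for j, ax in enumerate("xyz"):
                    row[f"axis{i}_{ax}"] = e.axes[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
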