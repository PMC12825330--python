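"""Virtual-shell construction and per-cell transduction classification.

The reporter protein is cytoplasmic while the segmentation is nuclear, so a
cell cannot be classified by looking inside its nucleus.  Instead a thin
*virtual shell* — the rind obtained by dilating each nucleus and subtracting
all nuclei — samples the perinuclear cytoplasm.  A cell is called transduced
when the fraction of its shell voxels covered by the segmented transduced
volume reaches a threshold (default 0.4, calibrated against manual counts).

In dense tissue the dilations of neighbouring nuclei collide; contested
voxels are assigned to the nucleus whose surface is nearest (Euclidean
distance in voxel units), ties going to the smaller label id.  Shells are
therefore pairwise disjoint and disjoint from every nucleus, which keeps the
transduced/total counts well-defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import BinaryMask, LabelVolume, VoxelGeometry

__all__ = [
    "ShellRecord",
    "build_shells",
    "filter_shells",
    "overlap_fractions",
    "classify",
    "shell_records_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class ShellRecord:
    """One nucleus's shell and its overlap with the transduced volume."""

    label_id: int
    shell_voxel_count: int
    shell_volume_um3: float
    overlap_voxels: int = 0
    overlap_fraction: float = 0.0
    transduced: bool | None = None


def _ball_offsets(
    radius: float, spacing: tuple[float, float, float]
) -> list[tuple[tuple[int, int, int], float]]:
    """Integer offsets within a (possibly anisotropic) ball, with squared distances."""
    sz, sy, sx = spacing
    mz = int(radius // sz)
    my = int(radius // sy)
    mx = int(radius // sx)
    out = []
    r2 = radius * radius
    for oz in range(-mz, mz + 1):
        for oy in range(-my, my + 1):
            for ox in range(-mx, mx + 1):
                d2 = (oz * sz) ** 2 + (oy * sy) ** 2 + (ox * sx) ** 2
                if d2 <= r2 + 1e-9 and (oz, oy, ox) != (0, 0, 0):
                    out.append(((oz, oy, ox), d2))
    out.sort(key=lambda t: t[1])
    return out


def _shifted(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Array shifted by ``offset`` with zero fill (out[v] = arr[v - offset])."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for ax, o in enumerate(offset):
        n = arr.shape[ax]
        src.append(slice(max(-o, 0), n - max(o, 0)))
        dst.append(slice(max(o, 0), n + min(o, 0)))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def build_shells(
    nuclei: LabelVolume,
    dilation_voxels: int = 2,
    dilation_um: float | None = None,
) -> LabelVolume:
    """Build per-nucleus shells: dilation by a discrete ball minus all nuclei.

    Parameters
    ----------
    dilation_voxels : int
        Ball radius in voxel units (default 2, i.e. a nominal lateral shell
        thickness of 0.824 µm on a 0.412 µm grid).  Anisotropy is *not*
        corrected in this mode: the dilation is an isotropic voxel ball,
        mirroring pixel-based dilation in common image-analysis software.
    dilation_um : float, optional
        If given, dilate by a physical radius instead (anisotropy-aware
        extension mode); ``dilation_voxels`` is then ignored.

    Contested voxels (within reach of several nuclei) go to the nucleus with
    the nearest surface voxel; exact ties go to the smaller label id.
    """
    labels = nuclei.data
    if dilation_um is not None:
        if dilation_um <= 0:
            raise ValueError("dilation_um must be positive")
        offsets = _ball_offsets(dilation_um, nuclei.geometry.spacing_zyx)
    else:
        if dilation_voxels < 1:
            raise ValueError("dilation_voxels must be >= 1")
        offsets = _ball_offsets(float(dilation_voxels), (1.0, 1.0, 1.0))

    best_d2 = np.full(labels.shape, np.inf, dtype=np.float64)
    best_label = np.zeros(labels.shape, dtype=labels.dtype)
    for offset, d2 in offsets:
        cand = _shifted(labels, offset)
        has = cand > 0
        closer = has & (d2 < best_d2)
        tie = has & (d2 == best_d2) & (cand < best_label)
        upd = closer | tie
        best_d2[upd] = d2
        best_label[upd] = cand[upd]
    shell = np.where(labels == 0, best_label, 0).astype(labels.dtype)
    return LabelVolume(data=shell, geometry=nuclei.geometry)


def _shell_counts(shells: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
    ids, inv = np.unique(shells.data, return_inverse=True)
    counts = np.bincount(inv.ravel(), minlength=len(ids))
    fg = ids > 0
    return ids[fg], counts[fg]


def filter_shells(
    shells: LabelVolume,
    geometry: VoxelGeometry | None = None,
    min_shell_um3: float = 50.0,
    n_nuclei: int | None = None,
) -> tuple[LabelVolume, np.ndarray]:
    """Remove artifact shells below the minimal physical volume.

    Shells with volume < ``min_shell_um3`` (default 50 µm³ for human tissue,
    30 µm³ for mouse) are removed; their nuclei drop out of the efficiency
    denominator.  When ``n_nuclei`` is given, the nuclei-to-shells count
    ratio is logged as a diagnostic — it should be ≈ 1.
    """
    if min_shell_um3 < 0:
        raise ValueError("min_shell_um3 must be non-negative")
    geometry = geometry or shells.geometry
    ids, counts = _shell_counts(shells)
    volumes = counts * geometry.voxel_volume
    keep = volumes >= min_shell_um3
    surviving = ids[keep]
    out = shells.data.copy()
    drop = ids[~keep]
    if drop.size:
        out[np.isin(out, drop)] = 0
    if surviving.size == 0:
        warnings.warn("no shells survive the size filter", stacklevel=2)
    if n_nuclei is not None and surviving.size:
        ratio = n_nuclei / surviving.size
        logger.info(
            "shell size filter (>= %.1f µm³): %d -> %d shells; nuclei/shells = %.3f",
            min_shell_um3,
            len(ids),
            surviving.size,
            ratio,
        )
    return LabelVolume(data=out, geometry=shells.geometry), surviving


def overlap_fractions(shells: LabelVolume, transduced: BinaryMask) -> list[ShellRecord]:
    """Exact integer overlap of every shell with the transduced mask."""
    if shells.shape != transduced.shape:
        raise ValueError(
            f"shape mismatch: shells {shells.shape} vs mask {transduced.shape}"
        )
    ids, inv = np.unique(shells.data, return_inverse=True)
    inv = inv.ravel()
    total = np.bincount(inv, minlength=len(ids))
    inside = np.bincount(inv[transduced.data.ravel()], minlength=len(ids))
    vv = shells.geometry.voxel_volume
    records = []
    for k, label_id in enumerate(ids):
        if label_id == 0:
            continue
        cnt = int(total[k])
        ov = int(inside[k])
        records.append(
            ShellRecord(
                label_id=int(label_id),
                shell_voxel_count=cnt,
                shell_volume_um3=cnt * vv,
                overlap_voxels=ov,
                overlap_fraction=ov / cnt,
            )
        )
    return records


def classify(
    records: list[ShellRecord], threshold: float = 0.4
) -> tuple[list[ShellRecord], int, int]:
    """Flag each cell as transduced iff overlap_fraction >= threshold.

    Returns ``(records, N_Td, N_Tot)`` where N_Tot counts all size-filtered
    shells and N_Td those flagged transduced.  The comparator is inclusive:
    a fraction exactly at the threshold counts as transduced.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    n_td = 0
    for rec in records:
        rec.transduced = rec.overlap_fraction >= threshold
        n_td += int(rec.transduced)
    return records, n_td, len(records)


def shell_records_to_frame(records: list[ShellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label_id": r.label_id,
                "shell_voxel_count": r.shell_voxel_count,
                "shell_volume_um3": r.shell_volume_um3,
                "overlap_voxels": r.overlap_voxels,
                "overlap_fraction": r.overlap_fraction,
                "transduced": r.transduced,
            }
            for r in records
        ]
    )
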