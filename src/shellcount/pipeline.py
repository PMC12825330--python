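"""End-to-end orchestration: nuclei labels + transduced mask → efficiency tables.

One :class:`RunConfig` carries every threshold of the analysis with the
standard defaults (probability 0.5, transduced-object minimum 10 µm³, nuclei
band (10 µm³, ∞), nuclei minimum 100 µm³, shell minimum 50 µm³ for human /
30 µm³ for mouse tissue, 2-voxel dilation, overlap threshold 0.4, 10 µm depth
bins, α = 0.05).  Every run can emit its fully-resolved configuration next to
its outputs, and the per-stage filter counts are logged so segmentation
problems surface as a broken nuclei-to-shells ratio rather than a silently
wrong efficiency.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantify
from .io import ExperimentManifest
from .nuclei import apply_volume_band, filter_nuclei
from .shells import build_shells, classify, filter_shells, overlap_fractions, shell_records_to_frame
from .volumes import BinaryMask, LabelVolume

__all__ = ["RunConfig", "StackResult", "PipelineResult", "process_stack", "run_pipeline"]

logger = logging.getLogger(__name__)

_SHELL_MIN_BY_TISSUE = {"human": 50.0, "mouse": 30.0}


@dataclass
class RunConfig:
    """All analysis parameters; defaults are the standard pipeline values."""

    tissue_preset: str = "human"
    prob_threshold: float = 0.5
    min_object_um3: float = 10.0
    nuclei_band_um3: tuple[float, float] = (10.0, math.inf)
    nuclei_min_um3: float = 100.0
    shell_min_um3: float | None = None  # resolved from tissue_preset when None
    dilation_voxels: int = 2
    overlap_threshold: float = 0.4
    bin_um: float = 10.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_preset not in _SHELL_MIN_BY_TISSUE:
            raise ValueError(
                f"tissue_preset must be one of {sorted(_SHELL_MIN_BY_TISSUE)}"
            )

    @property
    def shell_min_resolved_um3(self) -> float:
        if self.shell_min_um3 is not None:
            return self.shell_min_um3
        return _SHELL_MIN_BY_TISSUE[self.tissue_preset]

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["shell_min_um3"] = self.shell_min_resolved_um3
        out["nuclei_band_um3"] = [
            self.nuclei_band_um3[0],
            None if math.isinf(self.nuclei_band_um3[1]) else self.nuclei_band_um3[1],
        ]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "nuclei_band_um3" in d:
            lo, hi = d["nuclei_band_um3"]
            d["nuclei_band_um3"] = (lo, math.inf if hi is None else hi)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class StackResult:
    """Per-stack outcome: cell table, counts and the filter cascade."""

    cells: pd.DataFrame  # label_id, depth_um, volume_um3, overlap_fraction, transduced
    n_td: int
    n_tot: int
    stage_counts: dict

    @property
    def efficiency(self) -> float:
        return quantify.efficiency(self.n_td, self.n_tot)


def process_stack(labels: LabelVolume, mask: BinaryMask, config: RunConfig | None = None) -> StackResult:
    """Run the per-stack classification cascade on one area.

    Steps: nuclei volume band → nuclei minimum-volume filter → shell
    construction (dilation minus all nuclei) → shell size filter → overlap
    with the transduced mask → threshold classification.
    """
    config = config or RunConfig()
    if labels.shape != mask.shape:
        raise ValueError(f"labels {labels.shape} and mask {mask.shape} shapes differ")
    stage_counts = {"input_nuclei": int(labels.ids().size)}

    banded = apply_volume_band(labels, *config.nuclei_band_um3)
    stage_counts["band_filtered"] = int(banded.ids().size)

    cleaned, records = filter_nuclei(banded, min_volume_um3=config.nuclei_min_um3)
    stage_counts["volume_filtered"] = len(records)
    by_id = {r.label_id: r for r in records}

    shells = build_shells(cleaned, dilation_voxels=config.dilation_voxels)
    shells, surviving = filter_shells(
        shells,
        cleaned.geometry,
        min_shell_um3=config.shell_min_resolved_um3,
        n_nuclei=len(records),
    )
    stage_counts["shell_filtered"] = int(surviving.size)

    shell_recs = overlap_fractions(shells, mask)
    shell_recs, n_td, n_tot = classify(shell_recs, threshold=config.overlap_threshold)
    stage_counts["transduced"] = n_td

    frame = shell_records_to_frame(shell_recs)
    if frame.empty:
        cells = pd.DataFrame(
            columns=["label_id", "depth_um", "volume_um3", "overlap_fraction", "transduced"]
        )
    else:
        frame["depth_um"] = [by_id[i].depth_um for i in frame["label_id"]]
        frame["volume_um3"] = [by_id[i].volume_um3 for i in frame["label_id"]]
        cells = frame[
            ["label_id", "depth_um", "volume_um3", "overlap_fraction", "transduced"]
        ].copy()
    return StackResult(cells=cells, n_td=n_td, n_tot=n_tot, stage_counts=stage_counts)


@dataclass
class PipelineResult:
    area_results: pd.DataFrame
    organoid_results: pd.DataFrame
    condition_results: pd.DataFrame
    depth_profiles: pd.DataFrame
    cells: pd.DataFrame
    stage_counts: pd.DataFrame


def run_pipeline(
    config: RunConfig,
    manifest: ExperimentManifest,
    stacks: dict[str, tuple[LabelVolume, BinaryMask]],
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full quantification over every included stack of a manifest.

    ``stacks`` maps stack_id → (nuclei LabelVolume, transduced BinaryMask).
    Per-condition/timepoint efficiencies follow the hierarchical average
    (areas → organoid → condition).  When ``out_dir`` is given, the tables,
    depth profiles and the fully-resolved config are written there.
    """
    area_rows = []
    cell_rows = []
    count_rows = []
    for rec in manifest.included():
        if rec.stack_id not in stacks:
            raise KeyError(f"manifest stack {rec.stack_id!r} not provided")
        labels, mask = stacks[rec.stack_id]
        try:
            res = process_stack(labels, mask, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for stack {rec.stack_id!r}: {exc}"
            ) from exc
        if res.n_tot == 0:
            logger.warning("stack %s has no surviving cells; skipped", rec.stack_id)
            continue
        area_rows.append(
            {
                "stack_id": rec.stack_id,
                "condition": rec.condition,
                "timepoint": rec.timepoint,
                "organoid_id": rec.organoid_id,
                "area_index": rec.area_index,
                "n_td": res.n_td,
                "n_tot": res.n_tot,
                "efficiency": res.efficiency,
            }
        )
        cells = res.cells.copy()
        for col in ("stack_id", "condition", "timepoint", "organoid_id", "area_index"):
            cells[col] = getattr(rec, col)
        cell_rows.append(cells)
        count_rows.append({"stack_id": rec.stack_id, **res.stage_counts})
    if not area_rows:
        raise ValueError("no stack produced any surviving cells")

    area_df = pd.DataFrame(area_rows)
    cells_df = pd.concat(cell_rows, ignore_index=True)
    counts_df = pd.DataFrame(count_rows)
    organoid_df, condition_df = quantify.aggregate(area_df)

    profiles = []
    for (cond, tp), grp in cells_df.groupby(["condition", "timepoint"], sort=True):
        prof = quantify.depth_profile_hierarchy(grp, bin_width_um=config.bin_um)
        prof.insert(0, "condition", cond)
        prof.insert(1, "timepoint", tp)
        profiles.append(prof)
    depth_df = pd.concat(profiles, ignore_index=True)

    result = PipelineResult(
        area_results=area_df,
        organoid_results=organoid_df,
        condition_results=condition_df,
        depth_profiles=depth_df,
        cells=cells_df,
        stage_counts=counts_df,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        area_df.to_csv(out / "efficiency_by_area.csv", index=False)
        organoid_df.to_csv(out / "efficiency_by_organoid.csv", index=False)
        condition_df.to_csv(out / "efficiency_by_condition.csv", index=False)
        depth_df.to_csv(out / "depth_profile.csv", index=False)
        cells_df.to_csv(out / "cells.csv", index=False)
        counts_df.to_csv(out / "filter_cascade.csv", index=False)
        with open(out / "run_config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)
    return result
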