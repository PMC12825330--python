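"""Transduction-efficiency statistics: aggregation hierarchy, depth profiles,
inference, and threshold calibration against manual counts.

Efficiency is E = N_Td / N_Tot at the level of one imaged area.  Aggregation
is strictly hierarchical: the mean of the per-area efficiencies is treated as
a single measurement of the organoid, and the condition/timepoint mean is the
unweighted mean over organoids.  This is *not* the pooled ratio of summed
counts — organoids with many cells must not dominate the condition mean.
Dispersion uses the unbiased (N−1) standard deviation; SEM = SD / √N over
organoids, undefined (reported missing) for N = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .shells import ShellRecord
from .volumes import LabelVolume

__all__ = [
    "EfficiencyResult",
    "UndefinedEfficiencyError",
    "efficiency",
    "aggregate",
    "depth_profile",
    "depth_profile_hierarchy",
    "normalize_profile",
    "levene_median_test",
    "unpaired_t_test",
    "significance_stars",
    "read_manual_counts",
    "manual_reference",
    "plane_efficiency",
    "threshold_sweep",
    "calibrate_threshold",
]


class UndefinedEfficiencyError(ValueError):
    """Raised when N_Tot = 0; the caller must exclude the unit (empty-bin rule)."""


@dataclass
class EfficiencyResult:
    """Efficiency at one aggregation level.

    ``dispersion`` is an SD or SEM depending on ``dispersion_kind``;
    ``n_units`` is the number of lower-level units (areas or organoids)
    averaged, or the cell count N_Tot at area level.
    """

    level: str  # "area" | "organoid" | "condition-day" | "depth-bin"
    N_Td: int
    N_Tot: int
    E: float
    n_units: int = 1
    dispersion: float = float("nan")
    dispersion_kind: str = ""


def efficiency(n_td: int, n_tot: int) -> float:
    """E = N_Td / N_Tot, the fraction of cells classified as transduced."""
    if n_tot < 1:
        raise UndefinedEfficiencyError(
            "efficiency undefined for N_Tot = 0; exclude this unit from averaging"
        )
    if not (0 <= n_td <= n_tot):
        raise ValueError(f"need 0 <= N_Td <= N_Tot, got ({n_td}, {n_tot})")
    return n_td / n_tot


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan")


def aggregate(area_results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll per-area efficiencies up to organoid and condition/timepoint level.

    Parameters
    ----------
    area_results : DataFrame
        One row per included area with columns ``organoid_id``, ``condition``,
        ``timepoint``, ``area_index``, ``efficiency`` (and optionally
        ``n_td``/``n_tot``, carried along as sums for bookkeeping only).

    Returns
    -------
    (organoid_df, condition_df)
        Organoid rows carry the unweighted mean over areas; condition rows
        the unweighted mean over organoids with SD (N−1) and SEM = SD/√N.
        SEM is NaN for a single organoid, not zero.
    """
    required = {"organoid_id", "condition", "timepoint", "efficiency"}
    missing = required - set(area_results.columns)
    if missing:
        raise ValueError(f"area_results missing columns: {sorted(missing)}")
    if area_results.empty:
        raise ValueError("no included areas to aggregate")

    org_rows = []
    for (cond, tp, org), grp in area_results.groupby(
        ["condition", "timepoint", "organoid_id"], sort=True
    ):
        row = {
            "condition": cond,
            "timepoint": tp,
            "organoid_id": org,
            "n_areas": len(grp),
            "efficiency": float(grp["efficiency"].mean()),
            "sd_areas": _sd(grp["efficiency"].to_numpy()),
        }
        for col in ("n_td", "n_tot"):
            if col in grp:
                row[col] = int(grp[col].sum())
        org_rows.append(row)
    organoid_df = pd.DataFrame(org_rows)

    cond_rows = []
    for (cond, tp), grp in organoid_df.groupby(["condition", "timepoint"], sort=True):
        e = grp["efficiency"].to_numpy()
        sd = _sd(e)
        cond_rows.append(
            {
                "condition": cond,
                "timepoint": tp,
                "n_organoids": len(e),
                "efficiency": float(e.mean()),
                "sd": sd,
                "sem": sd / math.sqrt(len(e)) if len(e) >= 2 else float("nan"),
            }
        )
    condition_df = pd.DataFrame(cond_rows)
    return organoid_df, condition_df


def depth_profile(cells: pd.DataFrame, bin_width_um: float = 10.0) -> pd.DataFrame:
    """Depth-binned efficiency for one area.

    ``cells`` needs columns ``depth_um`` (nucleus centroid depth below the
    first imaged plane) and ``transduced`` (bool).  Bins are half-open
    ``[k·w, (k+1)·w)`` and labelled by their centre (5, 15, 25, … µm for the
    default 10 µm width).  Bins without cells are flagged ``included=False``
    and must be left out of any cross-organoid averaging.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    if cells.empty:
        return pd.DataFrame(
            columns=["bin_center_um", "bin_lo_um", "bin_hi_um", "n_td", "n_tot",
                     "efficiency", "included"]
        )
    depth = cells["depth_um"].to_numpy(dtype=float)
    flags = cells["transduced"].to_numpy(dtype=bool)
    idx = np.floor(depth / bin_width_um).astype(int)
    n_bins = int(idx.max()) + 1
    n_tot = np.bincount(idx, minlength=n_bins)
    n_td = np.bincount(idx, weights=flags.astype(float), minlength=n_bins).astype(int)
    rows = []
    for k in range(n_bins):
        populated = n_tot[k] > 0
        rows.append(
            {
                "bin_center_um": (k + 0.5) * bin_width_um,
                "bin_lo_um": k * bin_width_um,
                "bin_hi_um": (k + 1) * bin_width_um,
                "n_td": int(n_td[k]),
                "n_tot": int(n_tot[k]),
                "efficiency": n_td[k] / n_tot[k] if populated else float("nan"),
                "included": bool(populated),
            }
        )
    return pd.DataFrame(rows)


def depth_profile_hierarchy(
    cells: pd.DataFrame, bin_width_um: float = 10.0
) -> pd.DataFrame:
    """Depth profile averaged area → organoid → overall, per bin.

    ``cells`` needs ``organoid_id``, ``area_index``, ``depth_um``,
    ``transduced``.  Within each bin, per-area efficiencies are averaged into
    an organoid value, then averaged (unweighted) over organoids with SEM;
    empty bins simply drop out of the means at every level.
    """
    per_area = []
    for (org, area), grp in cells.groupby(["organoid_id", "area_index"], sort=True):
        prof = depth_profile(grp, bin_width_um)
        prof = prof[prof["included"]].copy()
        prof["organoid_id"] = org
        prof["area_index"] = area
        per_area.append(prof)
    if not per_area:
        raise ValueError("no cells to profile")
    all_bins = pd.concat(per_area, ignore_index=True)
    per_org = (
        all_bins.groupby(["organoid_id", "bin_center_um"], sort=True)["efficiency"]
        .mean()
        .reset_index()
    )
    rows = []
    for center, grp in per_org.groupby("bin_center_um", sort=True):
        e = grp["efficiency"].to_numpy()
        sd = _sd(e)
        rows.append(
            {
                "bin_center_um": float(center),
                "efficiency": float(e.mean()),
                "n_organoids": len(e),
                "sd": sd,
                "sem": sd / math.sqrt(len(e)) if len(e) >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def normalize_profile(
    profile: pd.DataFrame, mode: str = "whole-stack", reference: float | None = None
) -> pd.DataFrame:
    """Divide per-bin efficiencies by a reference value.

    Modes: ``"whole-stack"`` (pooled E over all binned cells, so that
    count-weighted bin values recompose to 1), ``"max-bin"`` (peak bin = 1),
    ``"reference"`` (explicit value), ``"none"`` (identity).  The applied
    mode and reference are recorded in ``DataFrame.attrs['normalization']``.
    """
    out = profile.copy()
    if mode == "none":
        ref = 1.0
    elif mode == "whole-stack":
        if not {"n_td", "n_tot"} <= set(profile.columns):
            raise ValueError("whole-stack normalization needs n_td/n_tot columns")
        tot = int(profile["n_tot"].sum())
        if tot == 0:
            raise ValueError("zero cells: whole-stack reference undefined")
        ref = float(profile["n_td"].sum()) / tot
    elif mode == "max-bin":
        ref = float(np.nanmax(profile["efficiency"].to_numpy()))
    elif mode == "reference":
        if reference is None:
            raise ValueError("mode 'reference' needs an explicit reference value")
        ref = float(reference)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise ValueError("normalization reference must be positive")
    out["efficiency"] = out["efficiency"] / ref
    out.attrs["normalization"] = {"mode": mode, "reference": ref}
    return out


def levene_median_test(groups: list, alpha: float = 0.05) -> dict:
    """Equality-of-variance test on median-centred absolute deviations.

    The Brown–Forsythe variant of Levene's test: one-way ANOVA on
    |x − median(group)|.  Returns the statistic, p-value, and
    ``equal_variance`` = (p > alpha).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    devs = [np.abs(g - np.median(g)) for g in groups]
    if all(np.allclose(d, d[0]) for d in devs) and len({round(float(d[0]), 12) for d in devs}) == 1:
        # all deviation groups constant and equal: no variance heterogeneity signal
        return {"statistic": 0.0, "p_value": 1.0, "equal_variance": True}
    stat, p = stats.levene(*groups, center="median")
    if not np.isfinite(stat):
        raise ValueError("degenerate groups: Levene statistic undefined")
    return {"statistic": float(stat), "p_value": float(p), "equal_variance": bool(p > alpha)}


def significance_stars(p: float) -> str:
    """Star ladder: ****** (p ≤ 1e−6), ** (p ≤ 0.01), * (p ≤ 0.05), else n.s."""
    if p <= 1e-6:
        return "******"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def unpaired_t_test(g1, g2, alpha: float = 0.05) -> dict:
    """Two-sided unpaired t-test with pooled variance.

    Intended to follow a passed equal-variance (Levene median) test.  With
    zero pooled variance the statistic is degenerate: equal means give
    p = 1, unequal means p → 0, and the result is flagged.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    dof = len(a) + len(b) - 2
    pooled_var = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / dof
    flagged = False
    if pooled_var == 0:
        flagged = True
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return {
        "t": t,
        "dof": dof,
        "p_value": p,
        "significance": significance_stars(p),
        "alpha": alpha,
        "degenerate_variance": flagged,
    }


# ---------------------------------------------------------------------------
# Calibration against manual counting


def read_manual_counts(path) -> pd.DataFrame:
    """Read a manual-count CSV: plane_depth_um, annotator_id, n_transduced, n_total."""
    df = pd.read_csv(path)
    required = {"plane_depth_um", "annotator_id", "n_transduced", "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manual count table missing columns: {sorted(missing)}")
    if (df["n_transduced"] > df["n_total"]).any():
        raise ValueError("manual counts with n_transduced > n_total")
    return df


def manual_reference(
    manual: pd.DataFrame, planes_um: tuple[float, ...] = (25.0, 50.0)
) -> pd.DataFrame:
    """Per-plane manual efficiency, averaged over annotators, on selected planes."""
    if (manual["n_transduced"] > manual["n_total"]).any():
        raise ValueError("manual counts with n_transduced > n_total")
    sub = manual[manual["plane_depth_um"].isin(planes_um)].copy()
    present = set(sub["plane_depth_um"].unique())
    if present != set(planes_um):
        raise ValueError(
            f"manual table must cover planes {planes_um}, found {sorted(present)}"
        )
    sub["efficiency"] = sub["n_transduced"] / sub["n_total"]
    return (
        sub.groupby("plane_depth_um", sort=True)["efficiency"].mean().reset_index()
    )


def plane_efficiency(
    shell_labels: LabelVolume,
    records: list[ShellRecord],
    plane_depth_um: float,
    threshold: float,
) -> float:
    """2D surrogate efficiency at one z-plane.

    A plane's cells are those whose shell intersects the plane; the plane
    efficiency is the transduced fraction among them at the given overlap
    threshold.  This is the closest 3D-pipeline analogue of counting cells
    in a single extracted 2D image.
    """
    z = int(round(plane_depth_um / shell_labels.geometry.dz))
    if not (0 <= z < shell_labels.shape[0]):
        raise ValueError(f"plane depth {plane_depth_um} µm outside the stack")
    on_plane = set(np.unique(shell_labels.data[z])) - {0}
    hits = [r for r in records if r.label_id in on_plane]
    if not hits:
        raise UndefinedEfficiencyError(f"no shells intersect plane at {plane_depth_um} µm")
    n_td = sum(r.overlap_fraction >= threshold for r in hits)
    return n_td / len(hits)


def threshold_sweep(
    shell_labels: LabelVolume,
    records: list[ShellRecord],
    planes_um: tuple[float, ...],
    thresholds: tuple[float, ...],
) -> pd.DataFrame:
    """Plane-restricted efficiency for every (threshold, plane) combination."""
    rows = [
        {
            "threshold": thr,
            "plane_depth_um": plane,
            "efficiency": plane_efficiency(shell_labels, records, plane, thr),
        }
        for thr in thresholds
        for plane in planes_um
    ]
    return pd.DataFrame(rows)


def calibrate_threshold(
    software: pd.DataFrame,
    manual: pd.DataFrame,
    planes_um: tuple[float, ...] = (25.0, 50.0),
) -> dict:
    """Choose the overlap threshold best matching manual annotation.

    ``software`` holds per-threshold, per-plane efficiencies (columns
    ``threshold``, ``plane_depth_um``, ``efficiency``); ``manual`` is the
    raw count table.  The manual reference is the annotator-mean efficiency
    on the upper (25 µm) and centre (50 µm) planes; the chosen threshold
    minimises the mean absolute deviation from it over those planes, ties
    resolved toward the larger (more conservative) threshold.
    """
    if software.empty:
        raise ValueError("empty threshold sweep")
    ref = manual_reference(manual, planes_um).set_index("plane_depth_um")["efficiency"]
    sweep_rows = []
    for thr, grp in software.groupby("threshold", sort=True):
        grp = grp.set_index("plane_depth_um")
        missing = set(planes_um) - set(grp.index)
        if missing:
            raise ValueError(f"software sweep at threshold {thr} missing planes {missing}")
        devs = [abs(float(grp.loc[p, "efficiency"]) - float(ref.loc[p])) for p in planes_um]
        sweep_rows.append(
            {
                "threshold": float(thr),
                "software_efficiency": float(grp.loc[list(planes_um), "efficiency"].mean()),
                "mean_abs_deviation": float(np.mean(devs)),
            }
        )
    sweep = pd.DataFrame(sweep_rows).sort_values("threshold").reset_index(drop=True)
    best_dev = sweep["mean_abs_deviation"].min()
    chosen = sweep.loc[np.isclose(sweep["mean_abs_deviation"], best_dev), "threshold"].max()
    return {
        "chosen_threshold": float(chosen),
        "manual_reference": {float(p): float(ref.loc[p]) for p in planes_um},
        "sweep": sweep,
        "note": "2D plane efficiency = transduced fraction among shells intersecting the plane",
    }
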