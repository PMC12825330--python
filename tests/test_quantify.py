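"""Efficiency arithmetic, aggregation hierarchy, depth profiles, statistics,
and calibration against manual counts."""

import math

import numpy as np
import pandas as pd
import pytest

from shellcount import (
    aggregate,
    calibrate_threshold,
    depth_profile,
    depth_profile_hierarchy,
    efficiency,
    levene_median_test,
    normalize_profile,
    unpaired_t_test,
)
from shellcount.quantify import (
    UndefinedEfficiencyError,
    manual_reference,
    significance_stars,
)


class TestEfficiency:
    @pytest.mark.parametrize("n_td, n_tot, expected", [(84, 100, 0.84), (0, 250, 0.0), (7, 7, 1.0)])
    def test_exact_quotient(self, n_td, n_tot, expected):
        assert efficiency(n_td, n_tot) == expected

    def test_zero_total_is_undefined(self):
        with pytest.raises(UndefinedEfficiencyError):
            efficiency(0, 0)

    def test_transduced_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            efficiency(5, 4)


def _areas(rows):
    return pd.DataFrame(
        [
            {"condition": c, "timepoint": t, "organoid_id": o, "area_index": i,
             "n_td": td, "n_tot": tot, "efficiency": td / tot}
            for (c, t, o, i, td, tot) in rows
        ]
    )


class TestAggregate:
    def test_organoid_mean_of_areas(self):
        areas = _areas([("v", "d7", "o1", 0, 80, 100), ("v", "d7", "o1", 1, 60, 100)])
        org, cond = aggregate(areas)
        assert org.loc[0, "efficiency"] == pytest.approx(0.7)

    def test_condition_sd_and_sem_hand_arithmetic(self):
        # organoids at 0.7 and 0.9: mean 0.8, SD (N−1) ≈ 0.1414, SEM = 0.1
        areas = _areas([("v", "d7", "o1", 0, 70, 100), ("v", "d7", "o2", 0, 90, 100)])
        _, cond = aggregate(areas)
        assert cond.loc[0, "efficiency"] == pytest.approx(0.8)
        assert cond.loc[0, "sd"] == pytest.approx(0.141421, abs=1e-5)
        assert cond.loc[0, "sem"] == pytest.approx(0.1, abs=1e-9)

    def test_single_organoid_sem_is_missing_not_zero(self):
        areas = _areas([("v", "d7", "o1", 0, 80, 100)])
        _, cond = aggregate(areas)
        assert math.isnan(cond.loc[0, "sem"])

    def test_hierarchy_differs_from_pooled_ratio(self):
        # areas 1/10 and 90/100: pooled 91/110 ≈ 0.827, hierarchy (0.1 + 0.9)/2 = 0.5
        areas = _areas([("v", "d7", "o1", 0, 1, 10), ("v", "d7", "o1", 1, 90, 100)])
        org, cond = aggregate(areas)
        pooled = 91 / 110
        assert org.loc[0, "efficiency"] == pytest.approx(0.5)
        assert cond.loc[0, "efficiency"] == pytest.approx(0.5)
        assert abs(cond.loc[0, "efficiency"] - pooled) > 0.3

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            aggregate(pd.DataFrame({"efficiency": [0.5]}))


def _cells(depths, flags):
    return pd.DataFrame({"depth_um": depths, "transduced": flags})


class TestDepthProfile:
    def test_shallow_cells_fill_only_first_bin(self):
        prof = depth_profile(_cells([3.0, 4.0, 9.9], [True, False, True]))
        assert prof.loc[0, "bin_center_um"] == 5.0
        assert prof.loc[0, "included"]
        assert prof.loc[0, "n_tot"] == 3
        assert prof["included"].sum() == 1

    def test_bins_are_half_open(self):
        prof = depth_profile(_cells([10.0], [True]))
        # depth exactly 10 µm falls into the [10, 20) bin labelled 15 µm
        populated = prof[prof["included"]]
        assert list(populated["bin_center_um"]) == [15.0]

    def test_uniform_transduction_gives_flat_profile(self):
        rng = np.random.default_rng(0)
        depths = rng.uniform(0, 50, 500)
        prof = depth_profile(_cells(depths, [True] * 500))
        assert (prof.loc[prof["included"], "efficiency"] == 1.0).all()

    def test_count_weighted_bins_recompose_area_efficiency(self):
        rng = np.random.default_rng(1)
        depths = rng.uniform(0, 60, 400)
        flags = rng.random(400) < 0.37
        prof = depth_profile(_cells(depths, flags))
        pooled = (prof["n_td"].sum()) / (prof["n_tot"].sum())
        weighted = np.nansum(prof["efficiency"] * prof["n_tot"]) / prof["n_tot"].sum()
        assert weighted == pytest.approx(pooled)
        assert pooled == pytest.approx(np.mean(flags))

    def test_hierarchy_step_profile_recovered_from_phantom_truth(self, small_phantom):
        # per-layer truth: efficiency above vs below the boundary must differ
        truth = small_phantom.truth.copy()
        truth["organoid_id"] = "o1"
        truth["area_index"] = 0
        prof = depth_profile_hierarchy(
            truth[["organoid_id", "area_index", "depth_um", "transduced"]]
        )
        assert prof["n_organoids"].max() == 1
        assert len(prof) >= 3

    def test_empty_bins_excluded_from_hierarchy(self):
        cells = pd.DataFrame(
            {
                "organoid_id": ["o1"] * 4 + ["o2"] * 2,
                "area_index": [0, 0, 0, 0, 0, 0],
                "depth_um": [1.0, 2.0, 25.0, 26.0, 3.0, 4.0],
                "transduced": [True, True, True, False, False, False],
            }
        )
        prof = depth_profile_hierarchy(cells)
        by_bin = prof.set_index("bin_center_um")
        assert by_bin.loc[5.0, "n_organoids"] == 2
        assert by_bin.loc[25.0, "n_organoids"] == 1  # o2 has no cells there
        assert 15.0 not in by_bin.index


class TestNormalizeProfile:
    def _profile(self, effs, n_tot=None):
        n_tot = n_tot or [10] * len(effs)
        return pd.DataFrame(
            {
                "bin_center_um": 10.0 * np.arange(len(effs)) + 5.0,
                "efficiency": effs,
                "n_td": [int(e * n) for e, n in zip(effs, n_tot)],
                "n_tot": n_tot,
            }
        )

    def test_whole_stack_reference_flat_profile_becomes_ones(self):
        prof = self._profile([0.6, 0.6, 0.6])
        out = normalize_profile(prof, mode="whole-stack")
        np.testing.assert_allclose(out["efficiency"], 1.0)
        assert out.attrs["normalization"]["reference"] == pytest.approx(0.6)

    def test_max_bin_mode(self):
        out = normalize_profile(self._profile([0.2, 0.4]), mode="max-bin")
        np.testing.assert_allclose(out["efficiency"], [0.5, 1.0])

    def test_none_mode_is_identity(self):
        prof = self._profile([0.3, 0.7])
        out = normalize_profile(prof, mode="none")
        np.testing.assert_allclose(out["efficiency"], [0.3, 0.7])

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(self._profile([0.0, 0.0]), mode="whole-stack")


class TestLeveneMedian:
    def test_identical_groups(self):
        out = levene_median_test([[1, 2, 3], [1, 2, 3]])
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["equal_variance"]

    def test_location_shift_invariance(self):
        out = levene_median_test([[1, 2, 3], [11, 12, 13]])
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_anova_on_median_deviations(self):
        g1, g2 = [0, 0, 10, 10], [4, 5, 5, 6]
        # independent oracle: one-way ANOVA on |x − median| computed from scratch
        d1 = np.abs(np.array(g1) - np.median(g1))
        d2 = np.abs(np.array(g2) - np.median(g2))
        grand = np.concatenate([d1, d2]).mean()
        ssb = 4 * (d1.mean() - grand) ** 2 + 4 * (d2.mean() - grand) ** 2
        ssw = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
        expected = (ssb / 1) / (ssw / 6)
        out = levene_median_test([g1, g2])
        assert out["statistic"] == pytest.approx(expected)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            levene_median_test([[1, 2, 3]])


class TestTTest:
    def test_identical_groups_not_significant(self):
        out = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert out["t"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["significance"] == "n.s."

    def test_zero_variance_unequal_means_flagged(self):
        out = unpaired_t_test([0, 0, 0], [1, 1, 1])
        assert out["degenerate_variance"]
        assert out["p_value"] == 0.0

    def test_matches_hand_pooled_formula(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.5, 1.0, 6)
        sp2 = (7 * a.var(ddof=1) + 5 * b.var(ddof=1)) / 12
        expected_t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 8 + 1 / 6))
        out = unpaired_t_test(a, b)
        assert out["t"] == pytest.approx(expected_t)
        assert out["dof"] == 12

    @pytest.mark.parametrize(
        "p, stars",
        [(1e-7, "******"), (0.005, "**"), (0.03, "*"), (0.2, "n.s."), (0.05, "*")],
    )
    def test_star_ladder(self, p, stars):
        assert significance_stars(p) == stars


def _manual(values_by_plane):
    rows = []
    for plane, effs in values_by_plane.items():
        for i, e in enumerate(effs):
            rows.append(
                {"plane_depth_um": plane, "annotator_id": f"a{i}",
                 "n_transduced": int(e * 1000), "n_total": 1000}
            )
    return pd.DataFrame(rows)


def _software(sweep):
    rows = []
    for thr, eff in sweep.items():
        for plane in (25.0, 50.0):
            rows.append({"threshold": thr, "plane_depth_um": plane, "efficiency": eff})
    return pd.DataFrame(rows)


class TestCalibration:
    def test_manual_reference_averages_annotators(self):
        manual = _manual({25.0: [0.70, 0.76], 50.0: [0.72, 0.74], 75.0: [0.3, 0.4]})
        ref = manual_reference(manual)
        ref = ref.set_index("plane_depth_um")["efficiency"]
        assert ref.loc[25.0] == pytest.approx(0.73)
        assert 75.0 not in ref.index  # lowest plane excluded from the reference

    def test_chooses_argmin_deviation_threshold(self):
        manual = _manual({25.0: [0.73], 50.0: [0.73]})
        report = calibrate_threshold(_software({0.2: 0.95, 0.4: 0.84, 0.6: 0.60}), manual)
        assert report["chosen_threshold"] == 0.4

    def test_exact_match_has_zero_deviation(self):
        manual = _manual({25.0: [0.84], 50.0: [0.84]})
        report = calibrate_threshold(_software({0.4: 0.84, 0.6: 0.6}), manual)
        assert report["chosen_threshold"] == 0.4
        sweep = report["sweep"].set_index("threshold")
        assert sweep.loc[0.4, "mean_abs_deviation"] == pytest.approx(0.0)

    def test_tie_breaks_toward_larger_threshold(self):
        manual = _manual({25.0: [0.5], 50.0: [0.5]})
        report = calibrate_threshold(_software({0.3: 0.6, 0.5: 0.4}), manual)
        assert report["chosen_threshold"] == 0.5

    def test_single_candidate_returned_unchanged(self):
        manual = _manual({25.0: [0.7], 50.0: [0.7]})
        report = calibrate_threshold(_software({0.4: 0.9}), manual)
        assert report["chosen_threshold"] == 0.4

    def test_missing_plane_rejected(self):
        manual = _manual({25.0: [0.7]})
        with pytest.raises(ValueError, match="planes"):
            calibrate_threshold(_software({0.4: 0.9}), manual)
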