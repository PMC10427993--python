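"""Zonal footprint means, the occupancy rule and triplet comparisons."""

import numpy as np
import pandas as pd
import pytest

from neohybrid import (
    FootprintGrid,
    ValidationError,
    apply_occupancy_rule,
    hectad_mean_hfi,
    range_coverage_stats,
    triplet_observations,
)


def polygons(rows, crs="unspecified"):
    df = pd.DataFrame(rows, columns=["hectad_code", "xmin", "ymin", "xmax", "ymax"])
    df.attrs["crs_tag"] = crs
    return df


class TestHectadMeans:
    def test_uniform_grid_any_hectad(self):
        grid = FootprintGrid(np.full((10, 10), 10.0), 1.0, (0.0, 0.0))
        out, report = hectad_mean_hfi(grid, polygons([("H1", 2, 3, 7, 8)]))
        assert out.iloc[0]["mean_hfi"] == 10.0
        assert out.iloc[0]["n_cells"] == 25
        assert report["n_omitted_no_cells"] == 0

    def test_exact_four_cell_hectad(self):
        vals = np.array([[0.0, 10.0], [20.0, 30.0]])
        grid = FootprintGrid(vals, 1.0, (0.0, 0.0))
        out, _ = hectad_mean_hfi(grid, polygons([("H1", 0, 0, 2, 2)]))
        assert out.iloc[0]["mean_hfi"] == 15.0

    def test_cell_center_rule_on_straddling_hectad(self):
        # two cells with centers at x = 0.5 and 1.5; rectangle [0, 1) holds
        # only the first center
        vals = np.array([[10.0, 30.0]])
        grid = FootprintGrid(vals, 1.0, (0.0, 0.0))
        out, _ = hectad_mean_hfi(grid, polygons([("H1", 0, 0, 1, 1)]))
        assert out.iloc[0]["mean_hfi"] == 10.0

    def test_half_open_max_edges_no_double_count(self):
        vals = np.array([[10.0, 30.0]])
        grid = FootprintGrid(vals, 1.0, (0.0, 0.0))
        out, _ = hectad_mean_hfi(
            grid, polygons([("L", 0, 0, 1.5, 1), ("R", 1.5, 0, 3, 1)])
        )
        assert out.set_index("hectad_code")["n_cells"].sum() == 2

    def test_missing_cells_and_empty_hectads_reported(self):
        vals = np.array([[np.nan, 30.0]])
        grid = FootprintGrid(vals, 1.0, (0.0, 0.0))
        out, report = hectad_mean_hfi(
            grid, polygons([("A", 0, 0, 1, 1), ("B", 1, 0, 2, 1)])
        )
        assert out["hectad_code"].tolist() == ["B"]
        assert report["n_omitted_no_cells"] == 1

    def test_crs_mismatch_rejected(self):
        grid = FootprintGrid(np.ones((2, 2)), 1.0, (0.0, 0.0), crs_tag="mollweide-like")
        with pytest.raises(ValidationError):
            hectad_mean_hfi(grid, polygons([("H1", 0, 0, 1, 1)], crs="osgb-like"))


def occurrences(pairs):
    return pd.DataFrame(pairs, columns=["taxon_name", "hectad_code"])


def triplet_table(n=1):
    return pd.DataFrame(
        {
            "triplet_id": [f"T{i}" for i in range(n)],
            "hybrid_name": [f"H{i}" for i in range(n)],
            "native_name": [f"N{i}" for i in range(n)],
            "neophyte_name": [f"P{i}" for i in range(n)],
        }
    )


class TestOccupancyRule:
    @pytest.mark.parametrize("n_hectads,included", [(10, False), (11, True), (34, True)])
    def test_strictly_more_than_ten(self, n_hectads, included):
        occ = occurrences([("H0", f"K{i:02d}") for i in range(n_hectads)])
        out = apply_occupancy_rule(occ, triplet_table())
        assert bool(out.iloc[0]["included"]) is included

    def test_unknown_hybrid_counts_zero(self):
        out = apply_occupancy_rule(occurrences([("X", "K1")]), triplet_table())
        assert not out.iloc[0]["included"]


class TestObservations:
    def hfi(self):
        return pd.DataFrame(
            {"hectad_code": ["K1", "K2"], "mean_hfi": [12.0, 30.0], "n_cells": [100, 100]}
        )

    def test_join_only_covered_hectads(self):
        trip = triplet_table()
        trip["included"] = True
        occ = occurrences([("H0", "K1"), ("H0", "K2"), ("H0", "K9"), ("N0", "K1"), ("P0", "K2")])
        obs, report = triplet_observations(occ, self.hfi(), trip)
        assert len(obs[obs["taxon_type"] == "hybrid"]) == 2  # K9 has no coverage
        assert report["n_taxa_no_joinable_hectads"] == 0

    def test_shared_hectad_yields_one_observation_per_taxon(self):
        trip = triplet_table()
        trip["included"] = True
        occ = occurrences([("H0", "K1"), ("N0", "K1"), ("P0", "K1")])
        obs, _ = triplet_observations(occ, self.hfi(), trip)
        assert len(obs) == 3
        assert set(obs["taxon_type"]) == {"hybrid", "native", "neophyte"}

    def test_empty_join_reported(self):
        trip = triplet_table()
        trip["included"] = True
        occ = occurrences([("H0", "K9"), ("N0", "K1"), ("P0", "K1")])
        obs, report = triplet_observations(occ, self.hfi(), trip)
        assert "H0" in report["unjoined_taxa"]

    def test_join_integrity_hfi_equals_hectad_mean(self):
        trip = triplet_table()
        trip["included"] = True
        occ = occurrences([("H0", "K1"), ("H0", "K2"), ("N0", "K1"), ("P0", "K2")])
        obs, _ = triplet_observations(occ, self.hfi(), trip)
        lookup = self.hfi().set_index("hectad_code")["mean_hfi"]
        assert all(obs["hfi"].to_numpy() == lookup[obs["hectad_code"]].to_numpy())


def obs_df(rows):
    return pd.DataFrame(rows, columns=["triplet_id", "taxon_type", "hectad_code", "hfi"])


class TestRangeCoverage:
    def test_min_flag_when_hybrid_avoids_natural_end(self):
        rows = (
            [("T0", "hybrid", f"a{i}", v) for i, v in enumerate([20, 25, 30])]
            + [("T0", "native", f"b{i}", v) for i, v in enumerate([5, 15, 25])]
            + [("T0", "neophyte", f"c{i}", v) for i, v in enumerate([10, 20])]
        )
        df, counts = range_coverage_stats(obs_df(rows))
        assert bool(df.iloc[0]["hybrid_min_above_native_min"])
        assert counts["n_hybrid_min_above_native_min"] == 1

    def test_max_flag_requires_exceeding_both_parents(self):
        rows = (
            [("T0", "hybrid", "a", 30.0)]
            + [("T0", "native", "b", 35.0)]
            + [("T0", "neophyte", "c", 28.0)]
        )
        df, _ = range_coverage_stats(obs_df(rows))
        assert not bool(df.iloc[0]["hybrid_max_above_both_parents"])

    def test_identical_distributions_set_no_flags(self):
        rows = [("T0", t, f"{t}{i}", v) for t in ("hybrid", "native", "neophyte") for i, v in enumerate([10.0, 20.0])]
        df, _ = range_coverage_stats(obs_df(rows))
        assert not df.iloc[0]["hybrid_min_above_native_min"]
        assert not df.iloc[0]["hybrid_max_above_both_parents"]

    def test_missing_type_skipped_with_report(self):
        rows = [("T0", "hybrid", "a", 10.0), ("T0", "native", "b", 10.0)]
        df, counts = range_coverage_stats(obs_df(rows))
        assert len(df) == 0
        assert counts["n_skipped_missing_type"] == 1
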