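"""Census I/O and deterministic data-preparation rules."""

import numpy as np
import pandas as pd
import pytest

from treelight import census
from treelight.census import (
    CensusFormatError,
    CensusInterval,
    CensusSnapshot,
    TreeRecord,
    apply_rounding,
    compute_abundance,
    extract_growth_records,
    extract_recruits,
    partition_core,
    read_census,
    write_census,
)

from conftest import make_snapshot


class TestCensusIO:
    def test_round_trip_identity(self, three_tree_snapshot, tmp_path):
        path = tmp_path / "census.tsv"
        write_census(three_tree_snapshot, path)
        back = read_census(path)
        assert back.census_year == 1985
        assert back.plot_width == 100.0
        pd.testing.assert_frame_equal(back.trees, three_tree_snapshot.trees)

    def test_malformed_dbh_reports_line(self, three_tree_snapshot, tmp_path):
        path = tmp_path / "census.tsv"
        write_census(three_tree_snapshot, path)
        text = path.read_text().replace("120.0", "abc")
        path.write_text(text)
        with pytest.raises(CensusFormatError, match="line 3"):
            read_census(path)

    def test_empty_body_gives_zero_trees(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text(
            "# census_year=2000 plot_width=50 plot_height=50\n"
            + ",".join(census.CENSUS_COLUMNS)
            + "\n"
        )
        snap = read_census(path)
        assert len(snap) == 0

    def test_duplicate_tree_id_rejected(self):
        records = [
            TreeRecord("t1", "spA", 1.0, 1.0, 20.0),
            TreeRecord("t1", "spB", 2.0, 2.0, 30.0),
        ]
        with pytest.raises(CensusFormatError, match="duplicate"):
            CensusSnapshot.from_records(1985, 10, 10, records)

    def test_out_of_bounds_tree_rejected(self):
        records = [TreeRecord("t1", "spA", 120.0, 1.0, 20.0)]
        with pytest.raises(CensusFormatError, match="bounds"):
            CensusSnapshot.from_records(1985, 100, 100, records)


class TestPartitionCore:
    def test_plot_dimensions_of_the_study_site(self):
        grid = partition_core(1000.0, 500.0, margin=30.0, cell_size=5.0)
        assert (grid.nx, grid.ny) == (188, 88)
        assert grid.n_cells == 16_544

    @pytest.mark.parametrize(
        "w,h,margin,cell,expected",
        [(10, 10, 0, 5, 4), (100, 100, 30, 5, 64)],
    )
    def test_cell_counts(self, w, h, margin, cell, expected):
        assert partition_core(w, h, margin, cell).n_cells == expected

    def test_non_divisible_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            partition_core(12, 10, 0, 5)

    def test_cells_tile_core_exactly(self):
        grid = partition_core(100, 100, 10, 5)
        centers = grid.cell_centers()
        assert len(centers) == grid.n_cells == (grid.core_width / 5) * (
            grid.core_height / 5
        )
        # every center maps back to its own row-major cell id
        ids = grid.cell_id(centers[:, 0], centers[:, 1])
        assert np.array_equal(ids, np.arange(grid.n_cells))

    def test_half_open_cells_assign_boundary_points_once(self):
        grid = partition_core(20, 20, 0, 5)
        # a point on an interior cell edge belongs to exactly the upper cell
        assert grid.cell_id(np.array([5.0]), np.array([0.0]))[0] == 1
        assert grid.cell_id(np.array([20.0]), np.array([0.0]))[0] == -1


class TestRounding:
    @pytest.mark.parametrize(
        "dbh,expected",
        [(52, 50.0), (55, 55.0), (54.9, 50.0), (57, 57.0), (10, 10.0), (11, 10.0)],
    )
    def test_rule(self, dbh, expected):
        assert apply_rounding(dbh) == expected

    def test_vectorized_matches_scalar(self):
        vals = np.array([12.3, 54.999, 55.0, 200.0])
        assert np.array_equal(
            apply_rounding(vals), [apply_rounding(v) for v in vals]
        )

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            apply_rounding(0.0)


class TestExtractRecruits:
    def _interval(self, start_rows, end_rows):
        return CensusInterval(
            make_snapshot(start_rows, year=1985),
            make_snapshot(end_rows, year=1990),
        )

    def test_new_tree_in_core_is_counted(self):
        grid = partition_core(100, 100, 10, 5)
        interval = self._interval(
            [("t1", "spA", 50, 50, 100.0)],
            [("t1", "spA", 50, 50, 105.0), ("t2", "spB", 50.0, 50.0, 12.0)],
        )
        table = extract_recruits(interval, grid)
        assert table["count"].sum() == 1
        hit = table[table["count"] > 0].iloc[0]
        assert hit["species_id"] == "spB"
        assert grid.cell_id(np.array([50.0]), np.array([50.0]))[0] == hit["cell_id"]

    def test_margin_tree_excluded_survivor_not_recruit(self):
        grid = partition_core(100, 100, 10, 5)
        interval = self._interval(
            [("t1", "spA", 50, 50, 100.0)],
            [
                ("t1", "spA", 50, 50, 105.0),  # survivor, not a recruit
                ("t2", "spB", 5.0, 5.0, 12.0),  # in the 10 m margin
            ],
        )
        assert extract_recruits(interval, grid)["count"].sum() == 0

    def test_counts_sum_to_number_of_qualifying_recruits(self):
        rng = np.random.default_rng(3)
        n = 200
        end_rows = [
            (f"r{i}", f"sp{i%7}", rng.uniform(0, 100), rng.uniform(0, 100), 15.0)
            for i in range(n)
        ]
        grid = partition_core(100, 100, 10, 5)
        interval = self._interval([], end_rows)
        table = extract_recruits(interval, grid)
        xs = np.array([r[2] for r in end_rows])
        ys = np.array([r[3] for r in end_rows])
        in_core = (grid.cell_id(xs, ys) >= 0).sum()
        assert table["count"].sum() == in_core
        # dense table: every (cell, species) pair with a recruiting species
        assert len(table) == grid.n_cells * 7


class TestExtractGrowth:
    def _interval(self, start_rows, end_rows):
        return CensusInterval(
            make_snapshot(start_rows, year=1985),
            make_snapshot(end_rows, year=1990),
        )

    def test_rounding_rule_zeroes_small_increment(self):
        interval = self._interval(
            [("t1", "spA", 50, 50, 52.0)], [("t1", "spA", 50, 50, 53.0)]
        )
        rec = extract_growth_records(interval, use_rounding=True)
        assert rec["obs_growth"].iloc[0] == 0.0
        rec2 = extract_growth_records(interval, use_rounding=False)
        assert rec2["obs_growth"].iloc[0] == pytest.approx(0.2)

    def test_plain_increment_annualized(self):
        interval = self._interval(
            [("t1", "spA", 50, 50, 100.0)], [("t1", "spA", 50, 50, 110.0)]
        )
        rec = extract_growth_records(interval)
        assert rec["obs_growth"].iloc[0] == pytest.approx(2.0)
        assert rec["dbh0"].iloc[0] == 100.0

    def test_exclusion_rules(self):
        interval = self._interval(
            [
                ("t1", "spA", 10, 10, 100.0, {"palm": True}),
                ("t2", "spA", 20, 20, 100.0, {"stem_issue": True}),
                ("t3", "spA", 30, 30, 100.0, {"main_stem": False}),
                ("t4", "spA", 40, 40, 100.0),
                ("t5", "spA", 50, 50, 100.0),  # dies
            ],
            [
                ("t1", "spA", 10, 10, 110.0, {"palm": True}),
                ("t2", "spA", 20, 20, 110.0, {"stem_issue": True}),
                ("t3", "spA", 30, 30, 110.0, {"main_stem": False}),
                ("t4", "spA", 40, 40, 110.0),
                ("t5", "spA", 50, 50, 100.0, {"alive": False}),
            ],
        )
        rec = extract_growth_records(interval)
        assert rec["tree_id"].tolist() == ["t4"]

    def test_order_independent(self):
        rows_start = [("t%d" % i, "spA", i, i, 100.0 + i) for i in range(10)]
        rows_end = [("t%d" % i, "spA", i, i, 110.0 + i) for i in range(10)]
        interval = self._interval(rows_start, rows_end)
        interval_rev = self._interval(rows_start[::-1], rows_end[::-1])
        a = extract_growth_records(interval).sort_values("tree_id").reset_index(drop=True)
        b = (
            extract_growth_records(interval_rev)
            .sort_values("tree_id")
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(a, b)


class TestAbundance:
    def test_counts_alive_only(self, three_tree_snapshot):
        ab = compute_abundance(three_tree_snapshot)
        assert ab.to_dict() == {"spA": 2}

    def test_two_species_sum(self):
        snap = make_snapshot(
            [("t1", "spA", 1, 1, 20.0), ("t2", "spA", 2, 2, 20.0), ("t3", "spB", 3, 3, 20.0)]
        )
        ab = compute_abundance(snap)
        assert ab.sum() == 3 and set(ab.index) == {"spA", "spB"}

    def test_empty_snapshot(self):
        snap = make_snapshot([])
        assert compute_abundance(snap).empty
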