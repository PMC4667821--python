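"""Gridding, percentile ranks, priority selection and index summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloskew import (
    GridError,
    build_grid,
    correlate_indices,
    filter_cells,
    latitude_profile,
    percentile_rank,
    select_priority,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["species", "latitude", "longitude"])


class TestBuildGrid:
    def test_floor_convention(self):
        grid = build_grid(_records([("X", 10.5, -75.2)]))
        assert grid.cells == {(10, -76): frozenset({"X"})}

    def test_presence_not_abundance(self):
        grid = build_grid(_records([("X", 10.5, -75.2), ("X", 10.9, -75.9)]))
        assert grid.cells[(10, -76)] == frozenset({"X"})

    def test_hand_built_dictionary(self):
        rows = [
            ("a", 0.1, 0.1), ("b", 0.2, 0.9), ("c", 0.5, 0.5),
            ("a", 5.5, 5.5), ("d", 5.9, 5.1),
            ("e", -3.5, 100.5),
        ]
        grid = build_grid(_records(rows))
        assert grid.cells == {
            (0, 0): frozenset({"a", "b", "c"}),
            (5, 5): frozenset({"a", "d"}),
            (-4, 100): frozenset({"e"}),
        }

    def test_duplicated_records_idempotent(self):
        rows = [("a", 0.1, 0.1), ("b", 0.2, 0.9)]
        once = build_grid(_records(rows))
        twice = build_grid(_records(rows + rows))
        assert once.cells == twice.cells

    def test_out_of_range_reported_with_rows(self):
        rows = [("a", 0.1, 0.1), ("b", 95.0, 0.1), ("c", 0.1, 200.0)]
        with pytest.raises(GridError, match=r"\[1, 2\]"):
            build_grid(_records(rows))

    def test_unknown_species_dropped_with_count(self):
        rows = [("a", 0.1, 0.1), ("zz", 0.2, 0.2), ("zz", 3.5, 3.5)]
        with pytest.warns(UserWarning, match="dropped 2 records"):
            grid = build_grid(_records(rows), known_species={"a", "b"})
        assert grid.n_dropped_unknown == 2
        assert grid.dropped_species == {"zz"}
        assert grid.cells == {(0, 0): frozenset({"a"})}

    def test_missing_columns(self):
        with pytest.raises(GridError, match="missing"):
            build_grid(pd.DataFrame({"species": ["a"], "lat": [1.0]}))


class TestFilterCells:
    def test_more_than_ten_is_strict(self):
        cells = {
            (0, 0): frozenset(f"s{i}" for i in range(10)),
            (1, 1): frozenset(f"s{i}" for i in range(11)),
        }
        grid = build_grid(_records(
            [(sp, la + 0.5, lo + 0.5) for (la, lo), mem in cells.items() for sp in mem]
        ))
        kept = filter_cells(grid, min_sr=11)
        assert set(kept.cells) == {(1, 1)}

    def test_counting_oracle(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"s{rng.integers(40)}", float(la) + 0.5, float(la) + 0.5)
            for la in range(8)
            for _ in range(rng.integers(5, 30))
        ]
        grid = build_grid(_records(rows))
        direct = sum(1 for members in grid.cells.values() if len(members) >= 11)
        assert len(filter_cells(grid, 11)) == direct


class TestPercentileRank:
    def test_midrank_formula(self):
        np.testing.assert_allclose(
            percentile_rank([1, 2, 3, 4]), [12.5, 37.5, 62.5, 87.5]
        )

    def test_all_ties_rank_fifty(self):
        np.testing.assert_allclose(percentile_rank([7.0] * 5), [50.0] * 5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_order_preserving_and_transform_invariant(self, values):
        ranks = percentile_rank(values)
        assert np.all((ranks >= 0) & (ranks <= 100))
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(np.asarray(ranks)[order]) >= -1e-9)
        # doubling is exact in binary floats, so ties are preserved exactly
        transformed = percentile_rank([2.0 * v for v in values])
        np.testing.assert_allclose(transformed, ranks, atol=1e-9)


def _index_table(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "cell_lat": np.arange(n) % 60 - 30,
            "cell_lon": np.arange(n),
            "sr": rng.permutation(n) + 11,
            "pd": rng.permutation(n).astype(float) + 1,
            "avtd": rng.permutation(n).astype(float) + 1,
            "pe": rng.permutation(n).astype(float) + 1,
        }
    )


class TestSelectPriority:
    def test_exactly_five_percent_of_distinct_values(self):
        table = _index_table(100)
        pm = select_priority(table, quantile=0.95)
        for col in ("pd_top", "avtd_top", "pe_top", "sr_top"):
            assert int(pm.flags[col].sum()) == 5

    def test_constant_index_degenerates_with_warning(self):
        table = _index_table(20)
        table["pe"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            pm = select_priority(table, quantile=0.95)
        assert pm.flags["pe_top"].all()

    def test_union_nesting(self):
        table = _index_table(100)
        pm = select_priority(table)
        assert pm.full_priority >= pm.phylogenetic_priority

    def test_raising_quantile_never_adds_cells(self):
        table = _index_table(100, seed=3)
        loose = select_priority(table, quantile=0.90)
        tight = select_priority(table, quantile=0.95)
        for col in ("pd_top", "avtd_top", "pe_top", "sr_top"):
            assert set(np.flatnonzero(tight.flags[col])) <= set(
                np.flatnonzero(loose.flags[col])
            )

    def test_disjoint_hotspots_grow_the_full_union(self):
        # PE and SR hotspots planted in different cells
        table = _index_table(100, seed=5)
        table["pe"] = 1.0
        table.loc[:4, "pe"] = 10.0
        table["sr"] = 11
        table.loc[95:, "sr"] = 99
        pm = select_priority(table)
        assert len(pm.full_priority) > len(pm.phylogenetic_priority)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_priority(_index_table(0))

    def test_geojson_export(self, tmp_path):
        import json

        pm = select_priority(_index_table(40))
        path = tmp_path / "p.geojson"
        pm.to_geojson(path)
        gj = json.loads(path.read_text())
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) == len(pm.full_priority)


class TestCorrelations:
    def test_diagonal_and_duplicated_column(self):
        table = _index_table(30)
        table["avtd"] = table["pd"]
        corr = correlate_indices(table)
        assert corr.loc["sr", "sr"] == pytest.approx(1.0)
        assert corr.loc["pd", "avtd"] == pytest.approx(1.0)

    def test_exact_linear_dependence(self):
        table = _index_table(30)
        table["pe"] = 2.0 * table["pd"]
        corr = correlate_indices(table)
        assert corr.loc["pd", "pe"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        table = _index_table(30)
        table["avtd"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlate_indices(table)
        assert np.isnan(corr.loc["avtd", "pd"])
        assert corr.loc["avtd", "avtd"] == pytest.approx(1.0)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            correlate_indices(_index_table(2))


class TestLatitudeProfile:
    def test_single_bin_mean(self):
        table = pd.DataFrame(
            {"cell_lat": [2, 3, 4], "cell_lon": [0, 1, 2], "pe": [1.0, 2.0, 3.0]}
        )
        prof = latitude_profile(table, "pe", bin_width=10)
        assert len(prof.binned) == 1
        assert prof.binned["mean"].iloc[0] == pytest.approx(2.0)

    def test_symmetric_construction_gives_symmetric_profile(self):
        lats = np.array([-45, -35, -25, -15, 15, 25, 35, 45])
        vals = np.abs(lats).astype(float)
        table = pd.DataFrame(
            {"cell_lat": lats, "cell_lon": np.arange(8), "pe": vals}
        )
        prof = latitude_profile(table, "pe", bin_width=10)
        binned = prof.binned.set_index("bin_center")["mean"]
        for c in binned.index:
            assert binned[c] == pytest.approx(binned[-c])

    def test_profile_plots_without_error(self):
        import matplotlib

        matplotlib.use("Agg")
        from phyloskew.plot import plot_latitude_profile

        table = pd.DataFrame(
            {"cell_lat": [-40, -20, 0, 20, 40], "cell_lon": range(5),
             "pe": [4.0, 2.0, 1.0, 2.0, 4.0]}
        )
        ax = plot_latitude_profile(latitude_profile(table, "pe"))
        assert ax.get_ylabel() == "pe"

    def test_planted_gradient_detected(self):
        rng = np.random.default_rng(1)
        lats = rng.integers(-60, 60, size=200)
        pe = np.abs(lats) * 0.1 + rng.normal(0, 0.3, size=200)
        table = pd.DataFrame(
            {"cell_lat": lats, "cell_lon": np.arange(200), "pe": pe}
        )
        prof = latitude_profile(table, "pe")
        r = np.corrcoef(np.abs(lats + 0.5), pe)[0, 1]
        assert r > 0.5
        # LOWESS on |latitude| trends upward end to end
        assert prof.lowess_abs[-1, 1] > prof.lowess_abs[0, 1]
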