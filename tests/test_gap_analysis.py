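"""Conservation gap scores, categories, truncation and cohort bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from cwr_phylospace.errors import DataError
from cwr_phylospace.gap_analysis import (
    HP,
    LP,
    MP,
    SC,
    SCORE_COLUMNS,
    analyze_cohort,
    assign_unassessed,
    categorize,
    cohort_summary,
    combine_and_categorize,
    exsitu_scores,
    insitu_scores,
    truncate1,
)
from cwr_phylospace.occurrences import GridDomain


@pytest.fixture
def fine_grid():
    return GridDomain(origin_lon=0.0, origin_lat=0.0, cell_size=0.05, n_cols=10, n_rows=10)


def records_for(grid, points, types):
    lon = [grid.origin_lon + (c + 0.5) * grid.cell_size for _, c in points]
    lat = [grid.origin_lat + (r + 0.5) * grid.cell_size for r, _ in points]
    return pd.DataFrame({"species": "X", "lon": lon, "lat": lat, "type": list(types)})


class TestTruncation:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (100 * 50 / 95, 52.6),
            (100 * 36 / 95, 37.8),
            (100 * 9 / 95, 9.4),
            (100 * 73 / 95, 76.8),
            (100 * 1 / 3, 33.3),
            (88.9, 88.9),  # exactly-representable tenths survive
            (25.55, 25.5),
        ],
    )
    def test_truncates_not_rounds(self, value, expected):
        assert truncate1(value) == expected


class TestCategorize:
    @pytest.mark.parametrize(
        "score,cat",
        [(0, HP), (24.99, HP), (25, MP), (49.99, MP), (50, LP), (74.99, LP), (75, SC), (80, SC), (100, SC)],
    )
    def test_bins_left_closed(self, score, cat):
        assert categorize(score) == cat

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            categorize(-1)
        with pytest.raises(DataError):
            categorize(101)

    def test_monotone_step_function(self):
        order = [HP, MP, LP, SC]
        cats = [order.index(categorize(s)) for s in np.linspace(0, 100, 201)]
        assert cats == sorted(cats)


class TestExSituScores:
    def test_no_germplasm_scores_zero(self, fine_grid):
        records = records_for(fine_grid, [(0, 0), (1, 1)], "HH")
        sdm = np.ones((10, 10), dtype=np.uint8)
        eco = np.zeros((10, 10), dtype=int)
        out = exsitu_scores(records, sdm, eco, fine_grid)
        assert (out.SRSex, out.GRSex, out.ERSex, out.FCSex) == (0, 0, 0, 0)

    def test_equal_split_gives_srs_fifty(self, fine_grid):
        records = records_for(fine_grid, [(0, 0), (9, 9)], "GH")
        sdm = np.ones((10, 10), dtype=np.uint8)
        eco = np.zeros((10, 10), dtype=int)
        assert exsitu_scores(records, sdm, eco, fine_grid).SRSex == 50.0

    def test_toy_buffer_counts(self, fine_grid):
        """20 suitable cells, a buffer covering exactly 5 of them, and 2
        ecoregions of which the buffer touches 1 -> GRS 25, ERS 50."""
        sdm = np.zeros((10, 10), dtype=np.uint8)
        sdm[0, :] = 1  # 10 suitable cells in ecoregion A
        sdm[9, :] = 1  # 10 in ecoregion B
        eco = np.zeros((10, 10), dtype=int)
        eco[5:, :] = 1
        records = records_for(fine_grid, [(0, 2)], "G")
        # cells are ~5.56 km tall at the equator; 12 km reaches 2 cells away
        out = exsitu_scores(records, sdm, eco, fine_grid, buffer_radius_km=12.0)
        # covered suitable cells: row 0, cols 0..4 -> 5 of 20
        assert out.GRSex == pytest.approx(100 * 5 / 20)
        assert out.ERSex == pytest.approx(50.0)
        assert out.FCSex == pytest.approx((out.SRSex + 25 + 50) / 3)

    def test_no_suitable_cells_flagged(self, fine_grid):
        records = records_for(fine_grid, [(0, 0)], "G")
        out = exsitu_scores(records, np.zeros((10, 10)), np.zeros((10, 10), int), fine_grid)
        assert out.GRSex == 0 and out.ERSex == 0
        assert out.flagged


class TestInSituScores:
    def test_fully_protected_grid(self, fine_grid):
        records = records_for(fine_grid, [(2, 2), (3, 3)], "HH")
        sdm = np.ones((10, 10), dtype=np.uint8)
        eco = np.zeros((10, 10), dtype=int)
        out = insitu_scores(records, sdm, np.ones((10, 10), bool), eco, fine_grid)
        assert (out.SRSin, out.GRSin, out.ERSin) == (100.0, 100.0, 100.0)

    def test_empty_protected_mask(self, fine_grid):
        records = records_for(fine_grid, [(2, 2)], "H")
        sdm = np.ones((10, 10), dtype=np.uint8)
        out = insitu_scores(records, sdm, np.zeros((10, 10), bool), np.zeros((10, 10), int), fine_grid, pa_buffer_km=0)
        assert (out.SRSin, out.GRSin, out.ERSin, out.FCSin) == (0, 0, 0, 0)

    def test_half_protected_all_ecoregions_shared(self, fine_grid):
        sdm = np.ones((10, 10), dtype=np.uint8)
        pa = np.zeros((10, 10), bool)
        pa[:, :5] = True  # west half protected
        eco = np.tile(np.arange(2), (10, 5)).reshape(10, 10) % 2  # both ecoregions on both sides
        eco = np.tile(np.array([0, 1] * 5), (10, 1))
        records = records_for(fine_grid, [(0, 0)], "H")
        out = insitu_scores(records, sdm, pa, eco, fine_grid, pa_buffer_km=0)
        assert out.GRSin == pytest.approx(50.0)
        assert out.ERSin == pytest.approx(100.0)


class TestCombineAndCategorize:
    def test_component_means_worked_example(self):
        out = combine_and_categorize(33.05, 18.05)
        assert out["FCSc_mean"] == pytest.approx(25.55)
        assert out["category_combined"] == MP
        assert out["category_ex"] == MP
        assert out["category_in"] == HP

    def test_boundary_and_high_bin(self):
        assert combine_and_categorize(80.0, 80.0)["category_combined"] == SC
        assert combine_and_categorize(25.0, 25.0)["category_combined"] == MP

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            combine_and_categorize(120.0, 10.0)


class TestUnassessed:
    def test_high_priority_by_rule(self):
        df = assign_unassessed(["X", "Y"])
        assert (df["category_combined"] == HP).all()
        assert (~df["assessed"]).all()
        assert df[SCORE_COLUMNS].isna().all().all()

    def test_mixed_cohort_bookkeeping(self):
        assessed = pd.DataFrame(
            {
                "species": list("ABCDEF"),
                **{c: [10.0, 30, 55, 80, 20, 40] for c in SCORE_COLUMNS},
                "category_ex": [HP, MP, LP, SC, HP, MP],
                "category_in": [HP, MP, LP, SC, HP, MP],
                "category_combined": [HP, MP, LP, SC, HP, MP],
                "assessed": True,
            }
        )
        full = pd.concat([assessed, assign_unassessed(["U1", "U2", "U3", "U4"])], ignore_index=True)
        summary = cohort_summary(full)
        assert summary["n"] == 10
        assert summary["counts"].loc[HP, "category_combined"] == 6  # 2 assessed + 4 by rule
        # means ignore unassessed NaN rows
        assert summary["score_means"]["FCSex"] == pytest.approx(np.mean([10, 30, 55, 80, 20, 40]))


class TestCohortSummary:
    def test_truncated_percentage_shares(self):
        cats = [HP] * 50 + [MP] * 36 + [LP] * 9
        df = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(95)],
                **{c: 10.0 for c in SCORE_COLUMNS},
                "category_ex": cats,
                "category_in": [HP] * 73 + [MP] * 21 + [LP] * 1,
                "category_combined": cats,
                "assessed": True,
            }
        )
        summary = cohort_summary(df)
        assert summary["percentages"].loc[HP, "category_ex"] == 52.6
        assert summary["percentages"].loc[MP, "category_ex"] == 37.8
        assert summary["percentages"].loc[LP, "category_ex"] == 9.4
        assert summary["percentages"].loc[HP, "category_in"] == 76.8

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            cohort_summary(pd.DataFrame())


class TestAnalyzeCohort:
    def test_score_algebra_and_linearity(self, small_bundle):
        from cwr_phylospace.occurrences import clean_records
        from cwr_phylospace.rasters import refine_mask

        cfg = small_bundle.config
        cleaned, _ = clean_records(small_bundle.records, small_bundle.grid)
        pa_fine = refine_mask(small_bundle.layers.protected, cfg.sdm_refine_factor)
        eco_fine = np.kron(
            small_bundle.layers.ecoregions, np.ones((cfg.sdm_refine_factor,) * 2, dtype=int)
        )
        scores = analyze_cohort(
            cleaned, small_bundle.suitability.binary, pa_fine, eco_fine,
            small_bundle.suitability.fine_grid,
        )
        assessed = scores[scores["assessed"]]
        # FCS columns are the means of their three components
        np.testing.assert_allclose(
            assessed["FCSex"], assessed[["SRSex", "GRSex", "ERSex"]].mean(axis=1), atol=1e-9
        )
        np.testing.assert_allclose(
            assessed["FCSin"], assessed[["SRSin", "GRSin", "ERSin"]].mean(axis=1), atol=1e-9
        )
        np.testing.assert_allclose(
            assessed["FCSc_mean"], (assessed["FCSex"] + assessed["FCSin"]) / 2, atol=1e-9
        )
        # linearity: cohort FCSc mean equals the mean of the two FCS column means
        assert assessed["FCSc_mean"].mean() == pytest.approx(
            (assessed["FCSex"].mean() + assessed["FCSin"].mean()) / 2
        )
        bounded = assessed[SCORE_COLUMNS]
        assert ((bounded >= 0) & (bounded <= 100)).all().all()
        # unmodelled species fall to the HP-by-rule path
        assert (~scores["assessed"]).sum() == cfg.n_species - len(small_bundle.suitability.modelled)
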