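"""Protected-area representativeness of diversity hot spots per department.

Hot spots are the occupied cells at or above a percentile of a diversity
metric (default the 95th, linear-interpolation percentile, ties included)
or, for the randomization results, the cells carrying a significance
class. For each administrative department the share of its hot-spot
cells whose centre falls inside a protected area is reported, together
with row averages per department, column totals (means over departments
with data) and a grand average — all truncated to one decimal place.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cwr_phylospace.errors import AlignmentError
from cwr_phylospace.gap_analysis import truncate1
from cwr_phylospace.occurrences import GridDomain

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "SRob",
    "PDob",
    "PDr_sig_low",
    "PDr_sig_high",
    "RPDr_sig_low",
    "RPDr_sig_high",
]

TOTAL_ROW = "Total averages (%)"


def hotspot_cells(values: pd.Series, quantile_q: float = 95.0) -> np.ndarray:
    """Cell ids whose value is at or above the q-th percentile.

    ``values`` is indexed by cell id over occupied cells. The threshold
    uses the linear-interpolation percentile; ties at the threshold are
    included, and q=0 returns every occupied cell. With all values equal
    every cell qualifies (degenerate but well defined).
    """
    if len(values) == 0:
        return np.array([], dtype=int)
    threshold = np.percentile(values.to_numpy(float), quantile_q, method="linear")
    return values.index.to_numpy()[values.to_numpy(float) >= threshold]


def percent_protected(
    cells: np.ndarray,
    protected_mask: np.ndarray,
    departments: np.ndarray,
    grid: GridDomain,
) -> pd.Series:
    """Per-department share (%) of the given hot-spot cells that are protected.

    A cell counts as protected when the protected mask is True at that
    cell (centre-in rule on the analysis grid). Departments with no
    hot-spot cells get NaN — no data, not zero.
    """
    protected_mask = np.asarray(protected_mask, dtype=bool)
    departments = np.asarray(departments)
    if protected_mask.shape != (grid.n_rows, grid.n_cols) or departments.shape != protected_mask.shape:
        raise AlignmentError("protected mask and department partition must match the analysis grid")
    labels = np.unique(departments)
    out = pd.Series(np.nan, index=labels, dtype=float)
    if len(cells) == 0:
        return out
    rows, cols = np.divmod(np.asarray(cells, dtype=int), grid.n_cols)
    cell_dept = departments[rows, cols]
    cell_prot = protected_mask[rows, cols]
    for dept in np.unique(cell_dept):
        in_dept = cell_dept == dept
        out.loc[dept] = 100.0 * cell_prot[in_dept].sum() / in_dept.sum()
    return out


def summarize(columns: dict[str, pd.Series]) -> pd.DataFrame:
    """Assessment table: departments x metrics, all values truncated to
    one decimal.

    Row averages are means over each department's available (non-NaN)
    columns; the footer's column totals are means over departments with
    data for that column; the grand average is the mean of the column
    totals. Averages are computed from the truncated percentages, so the
    table can be reproduced from its own printed values.
    """
    table = pd.DataFrame(columns).map(truncate1)
    table["row_average"] = table.mean(axis=1, skipna=True).map(truncate1)
    totals = {col: truncate1(table[col].mean(skipna=True)) for col in table.columns if col != "row_average"}
    grand = truncate1(float(np.nanmean(list(totals.values()))))
    table = table.sort_values("row_average", ascending=False)
    footer = pd.DataFrame({**{k: [v] for k, v in totals.items()}, "row_average": [grand]}, index=[TOTAL_ROW])
    return pd.concat([table, footer])


def assess(
    diversity: pd.DataFrame,
    significance: pd.DataFrame,
    protected_mask: np.ndarray,
    departments: np.ndarray,
    grid: GridDomain,
    quantile_q: float = 95.0,
) -> pd.DataFrame:
    """Full Table-1-style assessment from the diversity and null-model tables.

    Six hot-spot sets are evaluated: top-percentile cells of observed SR
    and PD, and the significantly low/high cells of PD and RPD.
    """
    cell_sets = {
        "SRob": hotspot_cells(diversity.set_index("cell_id")["SR"], quantile_q),
        "PDob": hotspot_cells(diversity.set_index("cell_id")["PD_obs"], quantile_q),
        "PDr_sig_low": significance.loc[significance["class_PD"] == "sig_low", "cell_id"].to_numpy(),
        "PDr_sig_high": significance.loc[significance["class_PD"] == "sig_high", "cell_id"].to_numpy(),
        "RPDr_sig_low": significance.loc[significance["class_RPD"] == "sig_low", "cell_id"].to_numpy(),
        "RPDr_sig_high": significance.loc[significance["class_RPD"] == "sig_high", "cell_id"].to_numpy(),
    }
    columns = {
        name: percent_protected(cells, protected_mask, departments, grid)
        for name, cells in cell_sets.items()
    }
    return summarize(columns)
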