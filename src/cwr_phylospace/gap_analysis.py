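"""Per-species ex-situ / in-situ conservation gap scores and priority categories.

Each species is scored 0-100 on three axes of conservation coverage,
separately for germplasm collections (ex-situ) and protected areas
(in-situ):

* sampling (SRS): share of records already secured — germplasm records
  ex-situ, records inside (buffered) protected areas in-situ;
* geographic (GRS): share of the species' suitable habitat covered — by
  a radius around germplasm collection points ex-situ, by buffered
  protected areas in-situ;
* ecological (ERS): share of the ecoregions spanned by the suitable
  habitat that the covered portion also reaches.

The final conservation score FCS is the mean of the three; FCSc-mean
averages the ex-situ and in-situ FCS. Categories: high priority (HP)
below 25, medium (MP) in [25, 50), low (LP) in [50, 75), sufficiently
conserved (SC) at or above 75. Species without a usable distribution
model are not scored and fall to HP by rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cwr_phylospace.errors import DataError
from cwr_phylospace.occurrences import GridDomain, _assign_cells_vec
from cwr_phylospace.rasters import buffer_mask_km, cells_within_km

logger = logging.getLogger(__name__)

HP, MP, LP, SC = "HP", "MP", "LP", "SC"
CATEGORIES = (HP, MP, LP, SC)

SCORE_COLUMNS = [
    "SRSex", "GRSex", "ERSex", "FCSex",
    "SRSin", "GRSin", "ERSin", "FCSin",
    "FCSc_mean",
]

GERMPLASM = "G"
REFERENCE = "H"


def truncate1(x: float) -> float:
    """Truncate (floor) to one decimal place.

    Reported percentages use truncation, not rounding — 50/95 prints as
    52.6, 36/95 as 37.8. A tiny epsilon absorbs float noise so that
    exactly-representable tenths are not pushed down a notch.
    """
    if not math.isfinite(x):
        return x
    return math.floor(x * 10 + 1e-9) / 10


def categorize(score: float) -> str:
    """Priority category for a 0-100 conservation score (left-closed bins)."""
    if not (0 <= score <= 100):
        raise DataError(f"conservation score {score} outside [0, 100]")
    if score < 25:
        return HP
    if score < 50:
        return MP
    if score < 75:
        return LP
    return SC


def _cap(x: float) -> float:
    return float(min(100.0, max(0.0, x)))


def _mask_fraction(sub: np.ndarray, total: np.ndarray) -> tuple[float, bool]:
    """100 * |sub & total| / |total|; flagged True when |total| = 0."""
    denom = int(np.count_nonzero(total))
    if denom == 0:
        return 0.0, True
    return 100.0 * int(np.count_nonzero(sub & total)) / denom, False


def _ecoregion_fraction(covered: np.ndarray, suitable: np.ndarray, ecoregions: np.ndarray) -> tuple[float, bool]:
    eco_suit = set(np.unique(ecoregions[suitable]).tolist())
    if not eco_suit:
        return 0.0, True
    eco_cov = set(np.unique(ecoregions[covered & suitable]).tolist())
    return 100.0 * len(eco_cov & eco_suit) / len(eco_suit), False


@dataclass
class ExSituScores:
    SRSex: float
    GRSex: float
    ERSex: float
    FCSex: float
    flagged: bool  # True when the species had no suitable cells


@dataclass
class InSituScores:
    SRSin: float
    GRSin: float
    ERSin: float
    FCSin: float
    flagged: bool


def exsitu_scores(
    records: pd.DataFrame,
    sdm_binary: np.ndarray,
    ecoregions: np.ndarray,
    fine_grid: GridDomain,
    buffer_radius_km: float = 50.0,
) -> ExSituScores:
    """Ex-situ representativeness of one species.

    ``records`` holds that species' occurrences with columns lon, lat,
    type (G germplasm / H reference). The geographic and ecological
    scores measure how much of the suitable area (binary raster on the
    fine grid) lies within ``buffer_radius_km`` (great-circle) of a
    germplasm collection point.
    """
    sdm = np.asarray(sdm_binary, dtype=bool)
    g_mask = records["type"] == GERMPLASM
    n_g = int(g_mask.sum())
    n_h = len(records) - n_g
    srs = 100.0 * n_g / (n_g + n_h) if (n_g + n_h) else 0.0
    if n_g == 0:
        buffered = np.zeros_like(sdm)
    else:
        buffered = cells_within_km(
            fine_grid,
            records.loc[g_mask, "lon"].to_numpy(float),
            records.loc[g_mask, "lat"].to_numpy(float),
            buffer_radius_km,
        )
    grs, flag_g = _mask_fraction(buffered, sdm)
    ers, flag_e = _ecoregion_fraction(buffered, sdm, np.asarray(ecoregions))
    srs, grs, ers = _cap(srs), _cap(grs), _cap(ers)
    return ExSituScores(srs, grs, ers, (srs + grs + ers) / 3.0, flag_g or flag_e)


def insitu_scores(
    records: pd.DataFrame,
    sdm_binary: np.ndarray,
    protected_mask: np.ndarray,
    ecoregions: np.ndarray,
    fine_grid: GridDomain,
    pa_buffer_km: float = 5.0,
) -> InSituScores:
    """In-situ representativeness of one species against (buffered)
    protected areas; all layers aligned to the fine grid."""
    sdm = np.asarray(sdm_binary, dtype=bool)
    pa = buffer_mask_km(np.asarray(protected_mask, dtype=bool), fine_grid, pa_buffer_km)
    if len(records):
        cells = _assign_cells_vec(records["lon"].to_numpy(float), records["lat"].to_numpy(float), fine_grid)
        rows, cols = np.divmod(cells[cells >= 0], fine_grid.n_cols)
        inside = int(pa[rows, cols].sum())
        srs = 100.0 * inside / len(records)
    else:
        srs = 0.0
    grs, flag_g = _mask_fraction(pa, sdm)
    ers, flag_e = _ecoregion_fraction(pa, sdm, np.asarray(ecoregions))
    srs, grs, ers = _cap(srs), _cap(grs), _cap(ers)
    return InSituScores(srs, grs, ers, (srs + grs + ers) / 3.0, flag_g or flag_e)


def combine_and_categorize(fcs_ex: float, fcs_in: float) -> dict:
    """FCSc-mean and the three priority categories."""
    for v, name in ((fcs_ex, "FCSex"), (fcs_in, "FCSin")):
        if not (0 <= v <= 100):
            raise DataError(f"{name}={v} outside [0, 100]")
    fcsc = (fcs_ex + fcs_in) / 2.0
    return {
        "FCSc_mean": fcsc,
        "category_ex": categorize(fcs_ex),
        "category_in": categorize(fcs_in),
        "category_combined": categorize(fcsc),
    }


def assign_unassessed(species: list[str]) -> pd.DataFrame:
    """High-priority-by-rule rows for species lacking sufficient data.

    Scores are absent (NaN), never fabricated zeros, so cohort means stay
    means over assessed species only.
    """
    df = pd.DataFrame({"species": list(species)})
    for col in SCORE_COLUMNS:
        df[col] = np.nan
    df["category_ex"] = HP
    df["category_in"] = HP
    df["category_combined"] = HP
    df["assessed"] = False
    return df


def analyze_cohort(
    records: pd.DataFrame,
    suitability: dict[str, np.ndarray],
    protected_mask: np.ndarray,
    ecoregions: np.ndarray,
    fine_grid: GridDomain,
    buffer_radius_km: float = 50.0,
    pa_buffer_km: float = 5.0,
) -> pd.DataFrame:
    """Score every species in the occurrence table.

    Species without an entry in ``suitability`` are assigned HP with
    ``assessed=False``. Returns one row per species with the eight
    scores, FCSc-mean, three categories and the assessed flag.
    """
    if records.empty:
        raise DataError("empty occurrence table")
    pa = buffer_mask_km(np.asarray(protected_mask, dtype=bool), fine_grid, pa_buffer_km)
    rows = []
    unassessed = []
    for sp, sp_records in records.groupby("species", sort=True):
        sdm = suitability.get(sp)
        if sdm is None:
            unassessed.append(sp)
            continue
        ex = exsitu_scores(sp_records, sdm, ecoregions, fine_grid, buffer_radius_km)
        # protected mask pre-buffered above; pass buffer 0 to avoid doubling
        ins = insitu_scores(sp_records, sdm, pa, ecoregions, fine_grid, pa_buffer_km=0.0)
        combined = combine_and_categorize(ex.FCSex, ins.FCSin)
        rows.append(
            {
                "species": sp,
                "SRSex": ex.SRSex, "GRSex": ex.GRSex, "ERSex": ex.ERSex, "FCSex": ex.FCSex,
                "SRSin": ins.SRSin, "GRSin": ins.GRSin, "ERSin": ins.ERSin, "FCSin": ins.FCSin,
                **combined,
                "assessed": True,
            }
        )
    assessed_df = pd.DataFrame(rows)
    parts = [df for df in (assessed_df, assign_unassessed(unassessed)) if not df.empty]
    out = pd.concat(parts, ignore_index=True).sort_values("species", ignore_index=True)
    col_order = ["species", *SCORE_COLUMNS, "category_ex", "category_in", "category_combined", "assessed"]
    return out[col_order]


def cohort_summary(scores: pd.DataFrame) -> dict:
    """Category counts, truncated percentage shares and score means.

    Percentages are over all rows of the given table (pass an
    assessed-only slice to summarize the modelled cohort); means cover
    assessed species only, since unassessed species carry no scores.
    """
    if scores.empty:
        raise DataError("cannot summarize an empty cohort")
    n = len(scores)
    counts = {}
    percentages = {}
    for col in ("category_ex", "category_in", "category_combined"):
        vc = scores[col].value_counts()
        counts[col] = {cat: int(vc.get(cat, 0)) for cat in CATEGORIES}
        percentages[col] = {cat: truncate1(100.0 * counts[col][cat] / n) for cat in CATEGORIES}
    means = scores.loc[scores.get("assessed", True) == True, SCORE_COLUMNS].mean()  # noqa: E712
    return {
        "n": n,
        "counts": pd.DataFrame(counts),
        "percentages": pd.DataFrame(percentages),
        "score_means": means,
    }
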