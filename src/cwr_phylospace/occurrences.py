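"""Reading, cleaning and gridding of occurrence records.

Occurrence records (species, longitude, latitude, record type, source) are
cleaned against a rectangular degree grid with an optional study mask and
aggregated into a binary cell x species incidence matrix plus per-cell
sample counts — the structure every diversity metric downstream consumes.

Conventions (declared, since data providers rarely state theirs):

* coordinates are geographic degrees, no projection;
* cells are half-open ``[edge, edge + cell_size)`` in both axes, with the
  outermost upper edge closed so that points on the grid's boundary are kept;
* cell ids are 0-based, row-major from the lower-left origin;
* duplicate records (same species, same coordinates) count toward sampling
  effort ``N`` but collapse to a single incidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cwr_phylospace.errors import DataError, InvalidConfigError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "lon", "lat")

# boundary snap tolerance in cell units (see assign_cell)
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class GridDomain:
    """Rectangular analysis grid in geographic degrees.

    Parameters
    ----------
    origin_lon, origin_lat
        Lower-left corner of the grid.
    cell_size
        Cell edge length in degrees (default 0.1).
    n_cols, n_rows
        Grid extent in cells.
    study_mask
        Optional ``(n_rows, n_cols)`` boolean array; ``False`` cells are
        outside the study region. ``None`` means the whole grid is in.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_cols: int
    n_rows: int
    study_mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidConfigError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise InvalidConfigError("grid must have at least one cell")
        if self.study_mask is not None:
            mask = np.asarray(self.study_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise InvalidConfigError(
                    f"study_mask shape {mask.shape} != grid ({self.n_rows}, {self.n_cols})"
                )
            object.__setattr__(self, "study_mask", mask)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def max_lon(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def max_lat(self) -> float:
        return self.origin_lat + self.n_rows * self.cell_size

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def cell_rowcol(self, cell_id: int | np.ndarray):
        return np.divmod(cell_id, self.n_cols)

    def cell_center(self, cell_id: int | np.ndarray):
        """(lon, lat) of the centre of each cell id."""
        row, col = self.cell_rowcol(cell_id)
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat + (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_lower_left(self, cell_id: int | np.ndarray):
        row, col = self.cell_rowcol(cell_id)
        return (
            self.origin_lon + np.asarray(col) * self.cell_size,
            self.origin_lat + np.asarray(row) * self.cell_size,
        )

    def in_mask(self, cell_id: int | np.ndarray):
        if self.study_mask is None:
            return np.ones(np.shape(cell_id), dtype=bool) if np.ndim(cell_id) else True
        row, col = self.cell_rowcol(cell_id)
        return self.study_mask[row, col]

    def refine(self, factor: int) -> "GridDomain":
        """Refined grid with ``factor``x smaller cells covering the same extent."""
        if factor < 1 or int(factor) != factor:
            raise InvalidConfigError(f"refinement factor must be a positive integer, got {factor}")
        factor = int(factor)
        mask = None
        if self.study_mask is not None:
            mask = np.kron(self.study_mask, np.ones((factor, factor), dtype=bool))
        return GridDomain(
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size / factor,
            n_cols=self.n_cols * factor,
            n_rows=self.n_rows * factor,
            study_mask=mask,
        )


def assign_cell(lon: float, lat: float, grid: GridDomain) -> int | None:
    """Map a point to its grid cell id, or ``None`` outside the grid.

    Cells are half-open on the low side; a point on an interior shared edge
    belongs to the higher-index cell. The grid's outermost upper edge is
    closed, so the exact upper-right corner maps to the last cell.
    """
    if not (math.isfinite(lon) and math.isfinite(lat)):
        return None
    # epsilon (in cell units) snaps float-noisy boundary points onto the
    # edge so the half-open rule sends them to the higher-index cell; it
    # also closes the grid's outermost upper edge (x ~ n maps to n - 1)
    x = (lon - grid.origin_lon) / grid.cell_size
    y = (lat - grid.origin_lat) / grid.cell_size
    col = math.floor(x + _EDGE_EPS)
    row = math.floor(y + _EDGE_EPS)
    if col == grid.n_cols and x <= grid.n_cols + _EDGE_EPS:
        col -= 1
    if row == grid.n_rows and y <= grid.n_rows + _EDGE_EPS:
        row -= 1
    if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
        return None
    return grid.cell_id(row, col)


def _assign_cells_vec(lon: np.ndarray, lat: np.ndarray, grid: GridDomain) -> np.ndarray:
    """Vectorized assign_cell; -1 encodes "outside"."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = (lon - grid.origin_lon) / grid.cell_size
    y = (lat - grid.origin_lat) / grid.cell_size
    col = np.floor(x + _EDGE_EPS).astype(np.int64)
    row = np.floor(y + _EDGE_EPS).astype(np.int64)
    col = np.where((col == grid.n_cols) & (x <= grid.n_cols + _EDGE_EPS), grid.n_cols - 1, col)
    row = np.where((row == grid.n_rows) & (y <= grid.n_rows + _EDGE_EPS), grid.n_rows - 1, row)
    ok = (
        np.isfinite(lon)
        & np.isfinite(lat)
        & (col >= 0)
        & (col < grid.n_cols)
        & (row >= 0)
        & (row < grid.n_rows)
    )
    out = np.where(ok, row * grid.n_cols + col, -1)
    return out


@dataclass
class CleaningReport:
    """Per-rule removal counts produced by :func:`clean_records`."""

    n_input: int = 0
    missing_coords: int = 0
    outside_grid: int = 0
    outside_mask: int = 0
    excluded_species: int = 0
    blank_species: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.missing_coords
            + self.outside_grid
            + self.outside_mask
            + self.excluded_species
            + self.blank_species
        )

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "missing_coords": self.missing_coords,
            "outside_grid": self.outside_grid,
            "outside_mask": self.outside_mask,
            "excluded_species": self.excluded_species,
            "blank_species": self.blank_species,
            "n_kept": self.n_kept,
        }


def normalize_species_name(name: object) -> str:
    """Trim and collapse internal whitespace; exact matching elsewhere."""
    if name is None or (isinstance(name, float) and math.isnan(name)):
        return ""
    return " ".join(str(name).split())


def clean_records(
    records: pd.DataFrame,
    grid: GridDomain,
    exclusion_list: tuple[str, ...] | list[str] = (),
) -> tuple[pd.DataFrame, CleaningReport]:
    """Filter raw occurrence records against the grid and an exclusion list.

    Removal rules, applied per record in order: blank species name; missing
    or non-finite coordinates; species on the exclusion list; outside the
    grid; outside the study mask. The order of surviving records is
    preserved and species names are whitespace-normalized.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise DataError(f"occurrence table lacks required column {col!r}")
    report = CleaningReport(n_input=len(records))
    df = records.copy()
    df["species"] = df["species"].map(normalize_species_name)
    excluded = {normalize_species_name(s) for s in exclusion_list}

    lon = pd.to_numeric(df["lon"], errors="coerce").to_numpy(dtype=float)
    lat = pd.to_numeric(df["lat"], errors="coerce").to_numpy(dtype=float)
    blank = (df["species"] == "").to_numpy()
    bad_coords = ~blank & ~(np.isfinite(lon) & np.isfinite(lat))
    on_list = ~blank & ~bad_coords & df["species"].isin(excluded).to_numpy()

    cells = _assign_cells_vec(np.where(np.isfinite(lon), lon, 0.0), np.where(np.isfinite(lat), lat, 0.0), grid)
    considered = ~(blank | bad_coords | on_list)
    outside_grid = considered & (cells < 0)
    in_grid = considered & (cells >= 0)
    outside_mask = in_grid & ~np.asarray(grid.in_mask(np.where(cells >= 0, cells, 0)))

    report.blank_species = int(blank.sum())
    report.missing_coords = int(bad_coords.sum())
    report.excluded_species = int(on_list.sum())
    report.outside_grid = int(outside_grid.sum())
    report.outside_mask = int(outside_mask.sum())

    keep = in_grid & ~outside_mask
    cleaned = df.loc[keep].copy()
    cleaned["lon"] = lon[keep]
    cleaned["lat"] = lat[keep]
    if report.n_removed:
        logger.info("cleaning removed %d of %d records: %s", report.n_removed, report.n_input, report.as_dict())
    return cleaned, report


@dataclass
class PresenceMatrix:
    """Binary cell x species incidence with per-cell sampling effort.

    Only occupied cells (>= 1 record) are represented. ``incidence`` is a
    dense ``(n_occupied_cells, n_species)`` 0/1 array; ``n_samples`` counts
    every record (duplicates included) per cell.
    """

    grid: GridDomain
    cell_ids: np.ndarray
    species: list[str]
    incidence: np.ndarray
    n_samples: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def richness(self) -> np.ndarray:
        """Per-cell species richness (row sums)."""
        return self.incidence.sum(axis=1)

    @property
    def range_size(self) -> np.ndarray:
        """Per-species occupied-cell count (column sums)."""
        return self.incidence.sum(axis=0)

    def restrict_species(self, keep: list[str]) -> "PresenceMatrix":
        """Sub-matrix over ``keep`` (ordered as given); drops cells left empty."""
        idx = [self.species.index(s) for s in keep]
        inc = self.incidence[:, idx]
        occupied = inc.sum(axis=1) > 0
        return PresenceMatrix(
            grid=self.grid,
            cell_ids=self.cell_ids[occupied],
            species=list(keep),
            incidence=np.ascontiguousarray(inc[occupied]),
            n_samples=self.n_samples[occupied],
        )

    def to_cell_table(self) -> pd.DataFrame:
        lon, lat = self.grid.cell_lower_left(self.cell_ids)
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "lon": lon,
                "lat": lat,
                "n_samples": self.n_samples,
                "richness": self.richness,
            }
        )

    def to_triplets(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.incidence)
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids[rows],
                "species": [self.species[c] for c in cols],
                "presence": np.ones(len(rows), dtype=int),
            }
        )


def build_presence_matrix(records: pd.DataFrame, grid: GridDomain) -> PresenceMatrix:
    """Aggregate cleaned records into the incidence structure.

    Raises :class:`DataError` on empty input. Species are ordered
    alphabetically; occupied cells by ascending cell id.
    """
    if len(records) == 0:
        raise DataError("no records to aggregate: cleaned data set is empty")
    cells = _assign_cells_vec(records["lon"].to_numpy(float), records["lat"].to_numpy(float), grid)
    if np.any(cells < 0):
        raise DataError("records outside the grid passed to build_presence_matrix; clean first")
    species = sorted(records["species"].unique())
    sp_index = {s: i for i, s in enumerate(species)}
    cell_ids = np.unique(cells)
    cell_index = {c: i for i, c in enumerate(cell_ids)}

    incidence = np.zeros((len(cell_ids), len(species)), dtype=np.uint8)
    n_samples = np.zeros(len(cell_ids), dtype=np.int64)
    sp_codes = records["species"].map(sp_index).to_numpy()
    for cell, sp in zip(cells, sp_codes):
        i = cell_index[cell]
        incidence[i, sp] = 1
        n_samples[i] += 1
    return PresenceMatrix(
        grid=grid,
        cell_ids=cell_ids,
        species=species,
        incidence=incidence,
        n_samples=n_samples,
    )


def read_occurrences_csv(path, delimiter: str = ",") -> pd.DataFrame:
    """Read an occurrence CSV with header ``species,lon,lat,type,source``."""
    df = pd.read_csv(path, delimiter=delimiter, dtype={"species": str}, encoding="utf-8")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    return df
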