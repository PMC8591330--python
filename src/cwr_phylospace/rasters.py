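"""Grid raster helpers: ESRI ASCII I/O and great-circle buffering.

Rasters are plain numpy arrays aligned to a :class:`GridDomain`; array
row 0 is the grid's southernmost row (lower-left origin). The ASCII-grid
writer flips to the north-up order the format expects.
"""

from __future__ import annotations

import numpy as np

from cwr_phylospace.errors import DataError
from cwr_phylospace.occurrences import GridDomain

EARTH_RADIUS_KM = 6371.0088


def write_ascii_grid(path, values: np.ndarray, grid: GridDomain, nodata: float = -9999.0) -> None:
    """Write a (n_rows, n_cols) array as an ESRI ASCII grid; NaN -> nodata."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise DataError(f"raster shape {values.shape} != grid ({grid.n_rows}, {grid.n_cols})")
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon:.10g}\n")
        fh.write(f"yllcorner {grid.origin_lat:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in out[::-1]:  # ASCII grids are written north to south
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridDomain]:
    """Read an ESRI ASCII grid back into (values, grid); nodata -> NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="ascii") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    try:
        grid = GridDomain(
            origin_lon=header["xllcorner"],
            origin_lat=header["yllcorner"],
            cell_size=header["cellsize"],
            n_cols=int(header["ncols"]),
            n_rows=int(header["nrows"]),
        )
    except KeyError as exc:
        raise DataError(f"{path}: missing ASCII grid header field {exc}") from exc
    values = np.array(rows, dtype=float)[::-1]  # back to south-up
    if values.shape != (grid.n_rows, grid.n_cols):
        raise DataError(f"{path}: data block shape {values.shape} does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, grid


def cell_center_coords(grid: GridDomain) -> tuple[np.ndarray, np.ndarray]:
    """(lon, lat) arrays of shape (n_rows, n_cols) for all cell centres."""
    lon = grid.origin_lon + (np.arange(grid.n_cols) + 0.5) * grid.cell_size
    lat = grid.origin_lat + (np.arange(grid.n_rows) + 0.5) * grid.cell_size
    return np.meshgrid(lon, lat)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def cells_within_km(
    grid: GridDomain,
    points_lon: np.ndarray,
    points_lat: np.ndarray,
    radius_km: float,
) -> np.ndarray:
    """Boolean raster of cells whose centre lies within ``radius_km``
    (great-circle) of any of the given points. Empty point set -> all False."""
    lon_g, lat_g = cell_center_coords(grid)
    out = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    points_lon = np.atleast_1d(np.asarray(points_lon, dtype=float))
    points_lat = np.atleast_1d(np.asarray(points_lat, dtype=float))
    flat_lon = lon_g.ravel()
    flat_lat = lat_g.ravel()
    hit = np.zeros(flat_lon.size, dtype=bool)
    # chunk over points to bound memory on large grids
    for start in range(0, points_lon.size, 256):
        pl = points_lon[start : start + 256]
        pa = points_lat[start : start + 256]
        d = haversine_km(flat_lon[:, None], flat_lat[:, None], pl[None, :], pa[None, :])
        hit |= (d <= radius_km).any(axis=1)
    out[:] = hit.reshape(out.shape)
    return out


def buffer_mask_km(mask: np.ndarray, grid: GridDomain, radius_km: float) -> np.ndarray:
    """Expand a boolean cell mask by a great-circle radius around the
    centres of its True cells; the original cells stay included."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.n_rows, grid.n_cols):
        raise DataError(f"mask shape {mask.shape} != grid ({grid.n_rows}, {grid.n_cols})")
    if not mask.any() or radius_km <= 0:
        return mask.copy()
    lon_g, lat_g = cell_center_coords(grid)
    return mask | cells_within_km(grid, lon_g[mask], lat_g[mask], radius_km)


def refine_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Replicate a coarse boolean mask onto a factor-refined grid."""
    return np.kron(np.asarray(mask, dtype=bool), np.ones((factor, factor), dtype=bool))
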