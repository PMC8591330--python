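"""Composite raster indicators combining PD with predicted and gap richness.

Two indicators are built on the fine (distribution-model) grid:

* *PD conservation gap richness*: the coarse PD surface is bilinearly
  resampled to the fine grid, the ex-situ gap richness stack (suitable
  cells not yet covered by a germplasm collection buffer, summed over
  species) is computed, both are standardized by their maxima and
  averaged — high values mark diverse areas that remain uncollected;
* *PD and predicted species richness*: the same construction with the
  plain sum of the binary distribution models instead of the gap stack —
  high values mark concentrations of both PD and potential richness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from cwr_phylospace.errors import AlignmentError, DataError, InvalidConfigError
from cwr_phylospace.occurrences import GridDomain
from cwr_phylospace.rasters import cells_within_km

logger = logging.getLogger(__name__)


@dataclass
class IndicatorRaster:
    """A named fine-grid raster with NaN for no-data cells."""

    values: np.ndarray
    tag: str

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def value_range(self) -> tuple[float, float]:
        v = self.values[self.valid_mask]
        return (float(v.min()), float(v.max())) if v.size else (np.nan, np.nan)


def _check_aligned(stack: dict[str, np.ndarray]) -> tuple[int, int]:
    shapes = {np.asarray(r).shape for r in stack.values()}
    if len(shapes) > 1:
        raise AlignmentError(f"rasters in stack have differing shapes: {sorted(shapes)}")
    return shapes.pop()


def predicted_richness(sdm_stack: dict[str, np.ndarray]) -> IndicatorRaster:
    """Cell-wise sum of the binary distribution rasters."""
    if not sdm_stack:
        raise DataError("empty raster stack")
    shape = _check_aligned(sdm_stack)
    total = np.zeros(shape, dtype=float)
    for raster in sdm_stack.values():
        total += np.asarray(raster, dtype=bool)
    return IndicatorRaster(total, "predicted_richness")


def gap_richness(
    sdm_stack: dict[str, np.ndarray],
    germplasm_points: dict[str, tuple[np.ndarray, np.ndarray]],
    fine_grid: GridDomain,
    buffer_radius_km: float = 50.0,
) -> IndicatorRaster:
    """Cell-wise count of species whose suitable habitat is uncollected.

    Per species the gap cells are the suitable cells NOT within
    ``buffer_radius_km`` of any of its germplasm points (lon, lat
    arrays); species without points contribute their whole suitable
    area. Always <= predicted richness cell-wise.
    """
    if not sdm_stack:
        raise DataError("empty raster stack")
    shape = _check_aligned(sdm_stack)
    if shape != (fine_grid.n_rows, fine_grid.n_cols):
        raise AlignmentError(f"stack shape {shape} != fine grid ({fine_grid.n_rows}, {fine_grid.n_cols})")
    total = np.zeros(shape, dtype=float)
    for sp, raster in sdm_stack.items():
        suitable = np.asarray(raster, dtype=bool)
        pts = germplasm_points.get(sp)
        if pts is None or len(np.atleast_1d(pts[0])) == 0:
            total += suitable
            continue
        covered = cells_within_km(fine_grid, pts[0], pts[1], buffer_radius_km)
        total += suitable & ~covered
    return IndicatorRaster(total, "gap_richness")


def resample_to_fine(coarse: np.ndarray, factor: int, method: str = "bilinear") -> IndicatorRaster:
    """Bilinear resampling of a coarse per-cell surface onto the grid
    refined by an integer ``factor``.

    Interpolation is between coarse cell centres; fine cells outside the
    outermost centres clamp to the nearest edge value. NaN (no-data)
    cells propagate to the fine cells they influence. ``factor=1`` is
    the identity.
    """
    if method != "bilinear":
        raise InvalidConfigError(f"unsupported resampling method {method!r}")
    if factor < 1 or int(factor) != factor:
        raise InvalidConfigError(f"refinement factor must be a positive integer, got {factor}")
    factor = int(factor)
    coarse = np.asarray(coarse, dtype=float)
    if factor == 1:
        return IndicatorRaster(coarse.copy(), "pd_resampled")
    n_rows, n_cols = coarse.shape
    # fine-cell centres expressed in coarse index space
    fr = (np.arange(n_rows * factor) + 0.5) / factor - 0.5
    fc = (np.arange(n_cols * factor) + 0.5) / factor - 0.5
    rr, cc = np.meshgrid(fr, fc, indexing="ij")
    fine = map_coordinates(coarse, [rr, cc], order=1, mode="nearest")
    return IndicatorRaster(fine, "pd_resampled")


def standardize(raster: np.ndarray) -> np.ndarray:
    """Divide by the maximum over valid cells, yielding a [0, 1] surface."""
    values = np.asarray(raster, dtype=float)
    valid = np.isfinite(values)
    if not valid.any():
        raise DataError("cannot standardize: raster has no valid cells")
    peak = values[valid].max()
    if peak <= 0:
        raise DataError("cannot standardize: raster maximum is not positive")
    return values / peak


def combine_indicator(raster_a, raster_b, tag: str = "pd_gap_indicator") -> IndicatorRaster:
    """Mean of the two max-standardized rasters over their common valid mask.

    Cells missing (NaN) in either input are missing in the output; the
    result lies in [0, 1] and attains 1 only where both inputs attain
    their maxima simultaneously.
    """
    a = raster_a.values if isinstance(raster_a, IndicatorRaster) else np.asarray(raster_a, dtype=float)
    b = raster_b.values if isinstance(raster_b, IndicatorRaster) else np.asarray(raster_b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"raster shapes differ: {a.shape} vs {b.shape}")
    sa, sb = standardize(a), standardize(b)
    out = (sa + sb) / 2.0
    out[~(np.isfinite(a) & np.isfinite(b))] = np.nan
    return IndicatorRaster(out, tag)


def diversity_to_raster(cell_values: pd.Series | dict, grid: GridDomain) -> np.ndarray:
    """Scatter per-occupied-cell values onto the full coarse grid (NaN elsewhere)."""
    out = np.full((grid.n_rows, grid.n_cols), np.nan)
    items = cell_values.items() if hasattr(cell_values, "items") else cell_values
    for cell_id, value in items:
        row, col = divmod(int(cell_id), grid.n_cols)
        out[row, col] = value
    return out
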