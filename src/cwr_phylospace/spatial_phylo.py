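"""Per-cell species richness, sampling redundancy, PD and RPD.

Richness (SR) is the number of distinct taxa in a cell. Sampling
redundancy is ``1 - SR/N`` for a cell with N records: near 1 the cell is
well sampled, near 0 every sample added a new species. PD is Faith's
phylogenetic diversity — the summed length of the branches connecting the
cell's taxa to the root — and RPD divides it by the PD of the same taxa on
the comparison tree (equal branch lengths), so RPD > 1 flags an excess of
long branches and RPD < 1 an excess of short ones.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from cwr_phylospace.errors import DataError
from cwr_phylospace.occurrences import PresenceMatrix, normalize_species_name
from cwr_phylospace.phylotree import (
    PhyloTree,
    TipPathIndex,
    build_tip_path_index,
    mean_nonzero_branch_length,
)

logger = logging.getLogger(__name__)


def richness(assemblage) -> int:
    """Number of distinct species present (incidence row or species set)."""
    if isinstance(assemblage, (set, frozenset, list, tuple)):
        return len(set(assemblage))
    return int(np.count_nonzero(np.asarray(assemblage)))


def redundancy(sr: int, n_samples: int) -> float:
    """Sampling redundancy ``1 - SR/N``; requires N >= 1."""
    if n_samples < 1:
        raise DataError("redundancy undefined for a cell with no samples")
    if sr > n_samples:
        raise DataError(f"richness {sr} exceeds sample count {n_samples}")
    return 1.0 - sr / n_samples


def faith_pd(species: set[str] | list[str], index: TipPathIndex) -> float:
    """PD of a tip set: total length of the union of their root paths."""
    species = set(species)
    if not species:
        return 0.0
    tip_idx = index.tip_index()
    missing = species - tip_idx.keys()
    if missing:
        raise DataError(f"species not in tree: {sorted(missing)}")
    rows = [tip_idx[s] for s in species]
    union = index.path_matrix[rows].any(axis=0)
    return float(index.branch_lengths[union].sum())


def rpd(species: set[str] | list[str], index: TipPathIndex, comparison_index: TipPathIndex) -> float:
    """RPD = PD on the observed tree / PD of the same branch union on the
    comparison tree. Requires a non-empty species set."""
    if not species:
        raise DataError("RPD undefined for an empty assemblage")
    pd_obs = faith_pd(species, index)
    pd_comp = faith_pd(species, comparison_index)
    if pd_comp == 0:
        raise DataError("comparison-tree PD is zero; malformed comparison tree")
    return pd_obs / pd_comp


def match_species(matrix: PresenceMatrix, tree: PhyloTree) -> PresenceMatrix:
    """Restrict the incidence matrix to species present as tree tips.

    Matching is exact after whitespace normalization. Occurrence species
    without a tip are dropped with a warning; extra tips are retained in
    the tree (they still shape the comparison-tree mean).
    """
    tips = {normalize_species_name(t) for t in tree.tip_labels}
    keep = [s for s in matrix.species if normalize_species_name(s) in tips]
    dropped = sorted(set(matrix.species) - set(keep))
    if dropped:
        warnings.warn(
            f"{len(dropped)} occurrence species not found among tree tips; dropped: {dropped[:5]}...",
            stacklevel=2,
        )
    if not keep:
        raise DataError("no occurrence species match the tree tips")
    if keep == matrix.species:
        return matrix
    return matrix.restrict_species(keep)


def _branch_union_matrix(matrix: PresenceMatrix, index: TipPathIndex) -> np.ndarray:
    """(n_cells, n_branches) bool: branch j is spanned by cell i's taxa."""
    tip_idx = index.tip_index()
    rows = [tip_idx[normalize_species_name(s)] for s in matrix.species]
    paths = index.path_matrix[rows]  # (n_species, n_branches)
    counts = matrix.incidence.astype(np.float64) @ paths.astype(np.float64)
    return counts > 0


def pd_per_cell(incidence: np.ndarray, paths: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Vectorized PD for many cells at once.

    ``incidence`` is (cells x species) 0/1, ``paths`` (species x branches)
    bool aligned to the same species order, ``lengths`` (branches,).
    """
    spanned = incidence.astype(np.float64) @ paths.astype(np.float64) > 0
    return spanned @ lengths


def compute_all_cells(matrix: PresenceMatrix, tree: PhyloTree) -> pd.DataFrame:
    """Per-cell diversity table for every occupied cell.

    Columns: cell_id, lon, lat (cell lower-left corner), n_samples, SR,
    redundancy, PD_obs, PD_comp, RPD, PD_frac (PD_obs / total tree
    length). Unoccupied cells are absent, not zero.
    """
    matrix = match_species(matrix, tree)
    index = build_tip_path_index(tree)
    # comparison tree shares the topology, so reuse the branch union and
    # just price each spanned branch at the mean non-zero length
    mean_bl = mean_nonzero_branch_length(tree)
    normalized_tips = [normalize_species_name(t) for t in index.tip_labels]
    index = TipPathIndex(normalized_tips, index.path_matrix, index.branch_lengths)

    spanned = _branch_union_matrix(matrix, index)
    pd_obs = spanned @ index.branch_lengths
    pd_comp = spanned.sum(axis=1) * mean_bl
    total = index.total_length

    sr = matrix.richness.astype(int)
    lon, lat = matrix.grid.cell_lower_left(matrix.cell_ids)
    out = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "lon": lon,
            "lat": lat,
            "n_samples": matrix.n_samples,
            "SR": sr,
            "redundancy": 1.0 - sr / matrix.n_samples,
            "PD_obs": pd_obs,
            "PD_comp": pd_comp,
            "RPD": pd_obs / pd_comp,
            "PD_frac": pd_obs / total,
        }
    )
    return out
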