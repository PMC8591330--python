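"""Synthetic landscapes with the statistical structure the analysis assumes.

Real crop-wild-relative data couple a curated occurrence set, a dated
phylogeny, binary habitat-suitability rasters and administrative /
protected-area layers. The generator emulates each piece at configurable
scale: a Yule tree over synthetic species, spatially clustered Gaussian
species ranges sampled with uneven effort, a germplasm/reference split
per record, blocky protected areas, a contiguous department partition, a
Voronoi ecoregion partition, and suitability surfaces that decay from
each species' true range centre.

Every generator draws from its own stream seeded at ``config.seed`` plus
a fixed per-generator offset, so adding one generator never perturbs
another's output, and a fixed seed makes the whole bundle reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from cwr_phylospace.errors import InvalidConfigError
from cwr_phylospace.occurrences import GridDomain, assign_cell
from cwr_phylospace.phylotree import PhyloTree, parse_newick
from cwr_phylospace.rasters import cell_center_coords, write_ascii_grid

logger = logging.getLogger(__name__)

# per-generator seed offsets (one stream per generator call)
_TREE_OFFSET = 101
_OCCURRENCE_OFFSET = 211
_LAYERS_OFFSET = 307
_SUITABILITY_OFFSET = 401


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study region.

    Defaults describe the standard scenario: a 30 x 30 grid of 0.1-degree
    cells, 60 species, 3000 records (~50 per species, matching the
    record-per-species density of typical cleaned national CWR data
    sets), germplasm share 0.2, ~15% protected-area coverage, and
    distribution models available for 55% of the species (the rest fall
    to the high-priority-by-rule path of the gap analysis).
    """

    seed: int = 0
    n_species: int = 60
    grid: tuple = (30, 30, 0.1, -75.0, 0.0)  # n_rows, n_cols, cell_size, origin_lon, origin_lat
    n_records_total: int = 3000
    range_kernel_sd: float = 0.3  # degrees
    effort_bias: float = 1.0
    germplasm_fraction: float = 0.2
    pa_coverage: float = 0.15
    n_departments: int = 12
    n_ecoregions: int = 8
    tree_model: str = "yule"
    suitability_threshold: float = 0.5
    sdm_refine_factor: int = 2
    sdm_coverage: float = 0.55

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InvalidConfigError(f"n_species must be >= 2, got {self.n_species}")
        n_rows, n_cols, cell_size = self.grid[0], self.grid[1], self.grid[2]
        if cell_size <= 0:
            raise InvalidConfigError("cell_size must be > 0")
        if not (0 <= self.germplasm_fraction <= 1):
            raise InvalidConfigError("germplasm_fraction must be in [0, 1]")
        if not (0 <= self.pa_coverage <= 1):
            raise InvalidConfigError("pa_coverage must be in [0, 1]")
        if not (0 <= self.sdm_coverage <= 1):
            raise InvalidConfigError("sdm_coverage must be in [0, 1]")
        if self.effort_bias < 0:
            raise InvalidConfigError("effort_bias must be >= 0")
        if self.tree_model != "yule":
            raise InvalidConfigError(f"unknown tree model {self.tree_model!r}")
        n_cells = n_rows * n_cols
        if self.n_departments > n_cells or self.n_ecoregions > n_cells:
            raise InvalidConfigError("more departments or ecoregions than grid cells")
        if self.n_departments < 1 or self.n_ecoregions < 1:
            raise InvalidConfigError("need at least one department and one ecoregion")

    def make_grid(self) -> GridDomain:
        n_rows, n_cols, cell_size, origin_lon, origin_lat = self.grid
        return GridDomain(
            origin_lon=origin_lon,
            origin_lat=origin_lat,
            cell_size=cell_size,
            n_cols=int(n_cols),
            n_rows=int(n_rows),
        )

    def species_names(self) -> list[str]:
        return [f"Species_{i:04d}" for i in range(1, self.n_species + 1)]

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "grid" in data:
            data["grid"] = tuple(data["grid"])
        return cls(**data)


class _YuleNode:
    __slots__ = ("children", "birth", "end", "label")

    def __init__(self, birth: float):
        self.children: list["_YuleNode"] = []
        self.birth = birth
        self.end: float | None = None
        self.label: str | None = None


def make_tree(config: SyntheticConfig) -> PhyloTree:
    """Yule (pure-birth) tree with exactly ``n_species`` tips.

    Waiting times are exponential with rate equal to the number of live
    lineages (birth rate 1); the root carries no subtending edge, so all
    branch lengths are strictly positive and PD of the full tip set
    equals the total tree length.
    """
    rng = np.random.default_rng(config.seed + _TREE_OFFSET)
    root = _YuleNode(0.0)
    root.end = 0.0
    first, second = _YuleNode(0.0), _YuleNode(0.0)
    root.children = [first, second]
    active = [first, second]
    t = 0.0
    while len(active) < config.n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active[idx]
        node.end = t
        left, right = _YuleNode(t), _YuleNode(t)
        node.children = [left, right]
        active[idx] = left
        active.append(right)
    t_end = t + rng.exponential(1.0 / len(active))
    names = config.species_names()
    for leaf, name in zip(active, names):
        leaf.end = t_end
        leaf.label = name

    def newick(node: _YuleNode) -> str:
        if not node.children:
            return f"{node.label}:{node.end - node.birth:.12g}"
        inner = ",".join(newick(c) for c in node.children)
        if node is root:
            return f"({inner});"
        return f"({inner}):{node.end - node.birth:.12g}"

    return parse_newick(newick(root))


def make_effort_surface(config: SyntheticConfig) -> np.ndarray:
    """Multiplicative sampling-effort weights: exp(bias * smoothed noise).

    A low-frequency Gaussian random field concentrates collecting effort
    in some regions, so sampling redundancy varies across the landscape
    the way road- and herbarium-biased surveys do.
    """
    n_rows, n_cols = int(config.grid[0]), int(config.grid[1])
    rng = np.random.default_rng(config.seed + _OCCURRENCE_OFFSET + 1)
    noise = rng.standard_normal((n_rows, n_cols))
    smooth = gaussian_filter(noise, sigma=max(2.0, min(n_rows, n_cols) / 6.0), mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.exp(config.effort_bias * smooth)


def make_occurrences(config: SyntheticConfig, tree: PhyloTree) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence records around random range centres, plus the ranges table.

    Every species gets at least one record; remaining records are split
    by a lognormal abundance profile. Points are Gaussian around each
    centre, rejection-sampled to stay on the grid, and thinned by the
    effort surface when ``effort_bias > 0``. Returns ``(records,
    ranges)`` where ranges holds each species' true centre and kernel sd
    (the inputs the suitability generator needs).
    """
    grid = config.make_grid()
    rng = np.random.default_rng(config.seed + _OCCURRENCE_OFFSET)
    names = tree.tip_labels
    if sorted(names) != sorted(config.species_names()):
        raise InvalidConfigError("tree tips do not match the configured species set")
    if config.n_records_total < len(names):
        raise InvalidConfigError("n_records_total must cover at least one record per species")

    effort = make_effort_surface(config)
    effort_max = effort.max()
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=len(names))
    counts = np.ones(len(names), dtype=int)
    extra = config.n_records_total - len(names)
    if extra > 0:
        counts += rng.multinomial(extra, abundance / abundance.sum())

    centres_lon = grid.origin_lon + rng.random(len(names)) * grid.n_cols * grid.cell_size
    centres_lat = grid.origin_lat + rng.random(len(names)) * grid.n_rows * grid.cell_size

    species_col, lon_col, lat_col = [], [], []
    for i, name in enumerate(names):
        for _ in range(counts[i]):
            for _attempt in range(1000):
                lon = centres_lon[i] + rng.normal(0.0, config.range_kernel_sd)
                lat = centres_lat[i] + rng.normal(0.0, config.range_kernel_sd)
                cell = assign_cell(lon, lat, grid)
                if cell is None:
                    continue
                row, col = divmod(cell, grid.n_cols)
                if rng.random() <= effort[row, col] / effort_max:
                    break
            else:  # pathological kernel; fall back to the range centre
                lon, lat = centres_lon[i], centres_lat[i]
            species_col.append(name)
            lon_col.append(lon)
            lat_col.append(lat)

    n = len(species_col)
    records = pd.DataFrame(
        {
            "species": species_col,
            "lon": lon_col,
            "lat": lat_col,
            "type": np.where(rng.random(n) < config.germplasm_fraction, "G", "H"),
            "source": "synthetic",
        }
    )
    ranges = pd.DataFrame(
        {
            "species": names,
            "centre_lon": centres_lon,
            "centre_lat": centres_lat,
            "kernel_sd": config.range_kernel_sd,
        }
    )
    return records, ranges


@dataclass
class Layers:
    """Protected-area mask and the two categorical partitions (coarse grid)."""

    protected: np.ndarray  # bool (n_rows, n_cols)
    departments: np.ndarray  # int labels, exhaustive contiguous partition
    ecoregions: np.ndarray  # int labels, Voronoi partition


def make_layers(config: SyntheticConfig) -> Layers:
    """Blocky protected areas, contiguous departments, Voronoi ecoregions."""
    grid = config.make_grid()
    n_rows, n_cols = grid.n_rows, grid.n_cols
    n_cells = n_rows * n_cols
    rng = np.random.default_rng(config.seed + _LAYERS_OFFSET)

    protected = np.zeros((n_rows, n_cols), dtype=bool)
    target = int(round(config.pa_coverage * n_cells))
    guard = 0
    while protected.sum() < target:
        guard += 1
        if guard > 50 * n_cells:  # nearly-full mask: finish deterministically
            remaining = np.flatnonzero(~protected.ravel())[: target - int(protected.sum())]
            protected.ravel()[remaining] = True
            break
        r0 = int(rng.integers(n_rows))
        c0 = int(rng.integers(n_cols))
        h = int(rng.integers(1, 4))
        w = int(rng.integers(1, 4))
        for r in range(r0, min(r0 + h, n_rows)):
            for c in range(c0, min(c0 + w, n_cols)):
                if protected.sum() >= target:
                    break
                protected[r, c] = True

    departments = _grow_partition(n_rows, n_cols, config.n_departments, rng)
    ecoregions = _voronoi_partition(n_rows, n_cols, config.n_ecoregions, rng)
    return Layers(protected=protected, departments=departments, ecoregions=ecoregions)


def _grow_partition(n_rows: int, n_cols: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous exhaustive partition by round-robin region growth."""
    labels = np.full((n_rows, n_cols), -1, dtype=int)
    seeds = rng.choice(n_rows * n_cols, size=k, replace=False)
    frontiers: list[list[tuple[int, int]]] = []
    for i, s in enumerate(seeds):
        r, c = divmod(int(s), n_cols)
        labels[r, c] = i
        frontiers.append([(r, c)])
    remaining = n_rows * n_cols - k
    while remaining > 0:
        progressed = False
        for i in range(k):
            frontier = frontiers[i]
            while frontier:
                j = int(rng.integers(len(frontier)))
                r, c = frontier[j]
                nbrs = [
                    (rr, cc)
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                    if 0 <= rr < n_rows and 0 <= cc < n_cols and labels[rr, cc] < 0
                ]
                if not nbrs:
                    frontier[j] = frontier[-1]
                    frontier.pop()
                    continue
                rr, cc = nbrs[int(rng.integers(len(nbrs)))]
                labels[rr, cc] = i
                frontier.append((rr, cc))
                remaining -= 1
                progressed = True
                break
        if not progressed:
            break
    assert (labels >= 0).all(), "partition growth left unlabelled cells"
    return labels


def _voronoi_partition(n_rows: int, n_cols: int, k: int, rng: np.random.Generator) -> np.ndarray:
    seeds = rng.choice(n_rows * n_cols, size=k, replace=False)
    sr, sc = np.divmod(seeds, n_cols)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    return np.argmin(d2, axis=-1)


@dataclass
class SuitabilityStack:
    """Per-species suitability on the refined (fine) grid.

    ``continuous`` keeps the raw 0-1 surfaces so the binarization can be
    audited; ``binary`` holds the thresholded rasters actually consumed
    by the gap analysis and indicators. Only ``modelled`` species have
    entries — the rest emulate species whose distribution model could
    not be fitted.
    """

    fine_grid: GridDomain
    continuous: dict[str, np.ndarray]
    binary: dict[str, np.ndarray]
    modelled: list[str]


def make_suitability(config: SyntheticConfig, ranges: pd.DataFrame) -> SuitabilityStack:
    """Distance-decay suitability around each range centre, binarized.

    The continuous surface is a Gaussian bump ``exp(-d^2 / (2 (2 sd)^2))``
    in degree space (twice the occurrence kernel sd, a potential range
    wider than the sampled one); values at or above
    ``suitability_threshold`` become 1. Which species get a model is a
    seeded random draw of ``sdm_coverage`` of the cohort.
    """
    grid = config.make_grid()
    fine = grid.refine(config.sdm_refine_factor)
    rng = np.random.default_rng(config.seed + _SUITABILITY_OFFSET)
    names = list(ranges["species"])
    n_model = int(round(config.sdm_coverage * len(names)))
    modelled_idx = sorted(rng.choice(len(names), size=n_model, replace=False).tolist())
    lon_g, lat_g = cell_center_coords(fine)

    continuous: dict[str, np.ndarray] = {}
    binary: dict[str, np.ndarray] = {}
    for i in modelled_idx:
        row = ranges.iloc[i]
        sd = 2.0 * float(row["kernel_sd"])
        d2 = (lon_g - float(row["centre_lon"])) ** 2 + (lat_g - float(row["centre_lat"])) ** 2
        surface = np.exp(-d2 / (2.0 * sd * sd))
        continuous[row["species"]] = surface
        binary[row["species"]] = (surface >= config.suitability_threshold).astype(np.uint8)
    return SuitabilityStack(
        fine_grid=fine,
        continuous=continuous,
        binary=binary,
        modelled=[names[i] for i in modelled_idx],
    )


@dataclass
class SyntheticBundle:
    """Everything one seed generates: the full input set of the pipeline."""

    config: SyntheticConfig
    grid: GridDomain
    tree: PhyloTree
    records: pd.DataFrame
    ranges: pd.DataFrame
    layers: Layers
    suitability: SuitabilityStack


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Run all generators for one seed."""
    tree = make_tree(config)
    records, ranges = make_occurrences(config, tree)
    layers = make_layers(config)
    suitability = make_suitability(config, ranges)
    return SyntheticBundle(
        config=config,
        grid=config.make_grid(),
        tree=tree,
        records=records,
        ranges=ranges,
        layers=layers,
        suitability=suitability,
    )


def germplasm_points(records: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-species (lon, lat) arrays of germplasm-flagged records."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    g = records[records["type"] == "G"]
    for sp, sub in g.groupby("species"):
        out[sp] = (sub["lon"].to_numpy(float), sub["lat"].to_numpy(float))
    return out


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Materialize a bundle as CSV / newick / ASCII-grid files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(outdir / "config.yaml")
    bundle.records.to_csv(outdir / "occurrences.csv", index=False)
    bundle.ranges.to_csv(outdir / "ranges.csv", index=False)
    bundle.tree.write(outdir / "tree.nwk", schema="newick")
    grid = bundle.grid
    write_ascii_grid(outdir / "protected.asc", bundle.layers.protected.astype(float), grid)
    write_ascii_grid(outdir / "departments.asc", bundle.layers.departments.astype(float), grid)
    write_ascii_grid(outdir / "ecoregions.asc", bundle.layers.ecoregions.astype(float), grid)
    sdm_dir = outdir / "sdm"
    sdm_dir.mkdir(exist_ok=True)
    for sp, raster in bundle.suitability.binary.items():
        write_ascii_grid(sdm_dir / f"{sp}.asc", raster.astype(float), bundle.suitability.fine_grid)
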