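"""Staged pipeline over a working directory of plain-text intermediates.

Each stage reads the files earlier stages wrote into one working
directory and writes its own outputs there, so a full run and a
stage-by-stage run produce identical files. All randomness flows from
the seed recorded in ``config.yaml``; rerunning a stage with the same
directory contents is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cwr_phylospace import __version__
from cwr_phylospace.conservation_assessment import assess
from cwr_phylospace.errors import DataError, InvalidConfigError
from cwr_phylospace.gap_analysis import analyze_cohort, cohort_summary
from cwr_phylospace.indicators import (
    combine_indicator,
    diversity_to_raster,
    gap_richness,
    predicted_richness,
    resample_to_fine,
)
from cwr_phylospace.null_models import RandomizationConfig, run_null_analysis
from cwr_phylospace.occurrences import (
    GridDomain,
    build_presence_matrix,
    clean_records,
    read_occurrences_csv,
)
from cwr_phylospace.phylotree import read_tree
from cwr_phylospace.rasters import read_ascii_grid, refine_mask, write_ascii_grid
from cwr_phylospace.spatial_phylo import compute_all_cells
from cwr_phylospace.synthetic_data import (
    SyntheticConfig,
    generate,
    germplasm_points,
    write_bundle,
)

logger = logging.getLogger(__name__)

STAGES = ("clean", "diversity", "nulls", "gaps", "indicators", "assess")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side parameters stored alongside the synthetic config.

    ``n_reps`` defaults to 199 for the standard desk-scale scenario; the
    library-level :class:`RandomizationConfig` default remains 999, the
    conventional choice for production randomization tests.
    """

    n_reps: int = 199
    alpha: float = 0.05
    quantile_q: float = 95.0
    buffer_radius_km: float = 50.0
    pa_buffer_km: float = 5.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InvalidConfigError("n_reps must be >= 1")
        if not (0 < self.alpha < 1):
            raise InvalidConfigError("alpha must be in (0, 1)")
        if not (0 <= self.quantile_q <= 100):
            raise InvalidConfigError("quantile_q must be in [0, 100]")


def write_pipeline_config(workdir: Path, synthetic: SyntheticConfig, analysis: AnalysisConfig) -> None:
    data = {
        "synthetic": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(synthetic).items()},
        "analysis": asdict(analysis),
    }
    with open(Path(workdir) / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_pipeline_config(workdir: Path) -> tuple[SyntheticConfig, AnalysisConfig]:
    path = Path(workdir) / "config.yaml"
    if not path.exists():
        raise DataError(f"missing {path}; run the simulate stage (or provide a config) first")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    syn = dict(data.get("synthetic", {}))
    if "grid" in syn:
        syn["grid"] = tuple(syn["grid"])
    return SyntheticConfig(**syn), AnalysisConfig(**data.get("analysis", {}))


def _require(workdir: Path, *names: str) -> None:
    missing = [n for n in names if not (Path(workdir) / n).exists()]
    if missing:
        raise DataError(f"missing upstream intermediates in {workdir}: {missing}")


def stage_simulate(workdir, synthetic: SyntheticConfig, analysis: AnalysisConfig | None = None) -> None:
    workdir = Path(workdir)
    bundle = generate(synthetic)
    write_bundle(bundle, workdir)
    write_pipeline_config(workdir, synthetic, analysis or AnalysisConfig())


def stage_clean(workdir) -> None:
    workdir = Path(workdir)
    _require(workdir, "occurrences.csv", "config.yaml")
    synthetic, _ = read_pipeline_config(workdir)
    grid = synthetic.make_grid()
    raw = read_occurrences_csv(workdir / "occurrences.csv")
    cleaned, report = clean_records(raw, grid)
    cleaned.to_csv(workdir / "cleaned.csv", index=False)
    with open(workdir / "cleaning_report.json", "w", encoding="utf-8") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)


def _load_matrix_and_tree(workdir: Path):
    _require(workdir, "cleaned.csv", "tree.nwk", "config.yaml")
    synthetic, analysis = read_pipeline_config(workdir)
    grid = synthetic.make_grid()
    cleaned = read_occurrences_csv(workdir / "cleaned.csv")
    matrix = build_presence_matrix(cleaned, grid)
    tree = read_tree(workdir / "tree.nwk")
    return synthetic, analysis, grid, cleaned, matrix, tree


def stage_diversity(workdir) -> None:
    workdir = Path(workdir)
    _, _, _, _, matrix, tree = _load_matrix_and_tree(workdir)
    compute_all_cells(matrix, tree).to_csv(workdir / "diversity.csv", index=False)
    matrix.to_cell_table().to_csv(workdir / "cell_table.csv", index=False)
    matrix.to_triplets().to_csv(workdir / "incidence.csv", index=False)


def stage_nulls(workdir) -> None:
    workdir = Path(workdir)
    synthetic, analysis, _, _, matrix, tree = _load_matrix_and_tree(workdir)
    config = RandomizationConfig(n_reps=analysis.n_reps, seed=synthetic.seed, alpha=analysis.alpha)
    run_null_analysis(matrix, tree, config).to_csv(workdir / "significance.csv", index=False)


def _load_fine_layers(workdir: Path, synthetic: SyntheticConfig):
    _require(workdir, "protected.asc", "ecoregions.asc")
    factor = synthetic.sdm_refine_factor
    protected, _ = read_ascii_grid(workdir / "protected.asc")
    ecoregions, _ = read_ascii_grid(workdir / "ecoregions.asc")
    fine_grid = synthetic.make_grid().refine(factor)
    pa_fine = refine_mask(protected > 0, factor)
    eco_fine = np.kron(ecoregions.astype(int), np.ones((factor, factor), dtype=int))
    return fine_grid, pa_fine, eco_fine


def _load_sdm_stack(workdir: Path) -> dict[str, np.ndarray]:
    sdm_dir = Path(workdir) / "sdm"
    if not sdm_dir.is_dir():
        raise DataError(f"missing sdm/ raster directory in {workdir}")
    stack = {}
    for path in sorted(sdm_dir.glob("*.asc")):
        values, _ = read_ascii_grid(path)
        stack[path.stem] = values > 0
    return stack


def stage_gaps(workdir) -> None:
    workdir = Path(workdir)
    _require(workdir, "cleaned.csv", "config.yaml")
    synthetic, analysis = read_pipeline_config(workdir)
    cleaned = read_occurrences_csv(workdir / "cleaned.csv")
    fine_grid, pa_fine, eco_fine = _load_fine_layers(workdir, synthetic)
    stack = _load_sdm_stack(workdir)
    scores = analyze_cohort(
        cleaned,
        stack,
        pa_fine,
        eco_fine,
        fine_grid,
        buffer_radius_km=analysis.buffer_radius_km,
        pa_buffer_km=analysis.pa_buffer_km,
    )
    scores.to_csv(workdir / "gap_scores.csv", index=False)
    assessed = scores[scores["assessed"]]
    for label, cohort in (("assessed", assessed), ("full", scores)):
        summary = cohort_summary(cohort)
        summary["counts"].to_csv(workdir / f"gap_summary_counts_{label}.csv")
        summary["percentages"].to_csv(workdir / f"gap_summary_percentages_{label}.csv")
    assessed_means = cohort_summary(assessed)["score_means"]
    assessed_means.to_csv(workdir / "gap_score_means.csv", header=["mean"])


def stage_indicators(workdir) -> None:
    workdir = Path(workdir)
    _require(workdir, "diversity.csv", "cleaned.csv", "config.yaml")
    synthetic, analysis = read_pipeline_config(workdir)
    grid = synthetic.make_grid()
    fine_grid = grid.refine(synthetic.sdm_refine_factor)
    stack = _load_sdm_stack(workdir)
    cleaned = read_occurrences_csv(workdir / "cleaned.csv")
    diversity = pd.read_csv(workdir / "diversity.csv")

    pred = predicted_richness(stack)
    gaps = gap_richness(
        stack,
        germplasm_points(cleaned),
        fine_grid,
        buffer_radius_km=analysis.buffer_radius_km,
    )
    pd_coarse = diversity_to_raster(diversity.set_index("cell_id")["PD_obs"], grid)
    pd_fine = resample_to_fine(pd_coarse, synthetic.sdm_refine_factor)
    gap_ind = combine_indicator(pd_fine, gaps, "pd_gap_indicator")
    rich_ind = combine_indicator(pd_fine, pred, "pd_richness_indicator")
    for raster in (pred, gaps, pd_fine, gap_ind, rich_ind):
        write_ascii_grid(workdir / f"{raster.tag}.asc", raster.values, fine_grid)


def stage_assess(workdir) -> None:
    workdir = Path(workdir)
    _require(workdir, "diversity.csv", "significance.csv", "protected.asc", "departments.asc", "config.yaml")
    synthetic, analysis = read_pipeline_config(workdir)
    grid = synthetic.make_grid()
    diversity = pd.read_csv(workdir / "diversity.csv")
    significance = pd.read_csv(workdir / "significance.csv")
    protected, _ = read_ascii_grid(workdir / "protected.asc")
    departments, _ = read_ascii_grid(workdir / "departments.asc")
    table = assess(
        diversity,
        significance,
        protected > 0,
        departments.astype(int),
        grid,
        quantile_q=analysis.quantile_q,
    )
    table.to_csv(workdir / "assessment.csv", index_label="department")


_STAGE_FUNCS = {
    "clean": stage_clean,
    "diversity": stage_diversity,
    "nulls": stage_nulls,
    "gaps": stage_gaps,
    "indicators": stage_indicators,
    "assess": stage_assess,
}


def run_pipeline(workdir) -> dict:
    """Run every analysis stage in order and write a provenance manifest."""
    workdir = Path(workdir)
    synthetic, analysis = read_pipeline_config(workdir)
    config_hash = hashlib.sha256((workdir / "config.yaml").read_bytes()).hexdigest()
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": synthetic.seed,
        "config_sha256": config_hash,
        "stages": {},
    }
    try:
        for stage in STAGES:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](workdir)
            manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        raise DataError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        counts = {}
        for name in ("cleaned", "diversity", "significance", "gap_scores"):
            path = workdir / f"{name}.csv"
            if path.exists():
                counts[name] = sum(1 for _ in open(path, encoding="utf-8")) - 1
        manifest["row_counts"] = counts
        with open(workdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
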