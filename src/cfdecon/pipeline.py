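"""End-to-end pipeline: simulate -> segment -> markers -> atlas -> spike -> pk.

Each stage logs its parameters and counts and persists its outputs as TSV (or
PAT) under the configured output directory, so a failed run leaves partial
artifacts behind; the failing stage is named in the raised error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .blocks import (
    block_methylation_table,
    cluster_samples,
    segment_genome,
    top_variance_blocks,
)
from .config import RunConfig, dump_run_config
from .io import write_cpg_map, write_ledger_bed, write_pat
from .pk import MINUTES_PER_YEAR, PKParams, scenario_grid
from .spikein import (
    build_reference_atlas,
    detection_probability,
    prepare_assets,
    run_spikein_grid,
)

__all__ = ["run_pipeline", "StageError"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are kept on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage in order; returns the written artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _write(name: str, path: Path) -> Path:
        artifacts[name] = path
        return path

    grid = config.spike
    if grid.base_seed == 0 and config.seed != 0:
        grid.base_seed = config.seed

    stage = "simulate"
    try:
        logger.info("[%s] %s", stage, config.simulation)
        assets = prepare_assets(config.simulation, grid)
        write_cpg_map(assets.cmap, _write("cpg_map", outdir / "cpg_map.tsv"))
        write_ledger_bed(
            assets.ledger, _write("ledger", outdir / "planted_blocks.bed")
        )
        for ct, coll in assets.merged_references().items():
            write_pat(coll, _write(f"pat_{ct}", outdir / f"ref_{ct}.pat"))
        write_pat(
            assets.spike_pool, _write("pat_spike", outdir / "spike_source.pat")
        )

        stage = "segment"
        seg = config.segmentation
        blocks = segment_genome(
            assets.beta,
            assets.cmap,
            min_cpg=seg.min_cpg,
            max_bp=seg.max_bp,
            homogeneity_tol=seg.homogeneity_tol,
            homogeneity_stat=seg.homogeneity_stat,
        )
        logger.info("[%s] %d blocks", stage, len(blocks))
        blocks.to_tsv(_write("blocks", outdir / "blocks.tsv"))

        stage = "table"
        refs = assets.flat_references()
        table = block_methylation_table(
            blocks, refs, assets.cmap, min_depth=seg.min_depth_clustering
        )
        table.values.assign(block=blocks.block_ids).to_csv(
            _write("block_table", outdir / "block_table.tsv"), sep="\t",
            index=False,
        )
        top = top_variance_blocks(table, seg.top_variance_fraction)
        dendro = cluster_samples(top.subset(top.complete_mask()))
        pd.DataFrame(
            dendro.linkage_matrix,
            columns=["cluster_a", "cluster_b", "height", "size"],
        ).to_csv(_write("linkage", outdir / "linkage.tsv"), sep="\t", index=False)

        stage = "markers+atlas"
        atlas = build_reference_atlas(
            assets, grid, min_cpg=seg.min_cpg, k=config.markers.k
        )
        logger.info("[%s] atlas %d markers x %d cell types", stage,
                    atlas.n_markers, len(atlas.cell_types))
        atlas.to_tsv(_write("atlas", outdir / "atlas.tsv"))

        stage = "spike-eval"
        results = run_spikein_grid(grid, assets)
        results.to_csv(
            _write("spike_results", outdir / "spike_results.tsv"),
            sep="\t", index=False,
        )
        summary = (
            results.groupby(["min_cpg", "k", "coverage", "fraction"])
            .agg(
                est_mean=("est", "mean"),
                est_sd=("est", "std"),
                n=("est", "count"),
                n_detected_mean=("n_detected", "mean"),
            )
            .reset_index()
        )
        summary["detection_probability"] = [
            detection_probability(
                results[
                    (results["min_cpg"] == r.min_cpg)
                    & (results["k"] == r.k)
                    & (results["coverage"] == r.coverage)
                ],
                r.fraction,
                epsilon=grid.detection_epsilon,
            )
            for r in summary.itertuples()
        ]
        summary.to_csv(
            _write("spike_summary", outdir / "spike_summary.tsv"),
            sep="\t", index=False,
        )

        stage = "pk"
        pkp = config.pk
        base = PKParams(
            d=pkp.d_values[0],
            duration_min=MINUTES_PER_YEAR,
            t_half_min=pkp.t_half_min,
            vd_litres=pkp.vd_litres,
            n_cells=pkp.n_cells,
            genome_mass_pg=pkp.genome_mass_pg,
            total_cfdna_pg_per_ul=pkp.total_cfdna_pg_per_ul,
        )
        pk_grid = scenario_grid(
            [y * MINUTES_PER_YEAR for y in pkp.durations_years],
            list(pkp.d_values),
            base,
        )
        pk_grid.to_csv(_write("pk_grid", outdir / "pk_grid.tsv"), sep="\t")

        dump_run_config(config, _write("config", outdir / "run_config.yaml"))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    return artifacts
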