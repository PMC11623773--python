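"""Spike-in grids: detection probability, AUC, recovery linearity, RMSE.

This is the optimisation harness around the deconvolution: synthetic cfDNA
backgrounds are spiked with a target cell type's fragments at known
fractions, coverage and marker count are varied, each mixture is deconvolved,
and detection metrics are computed over replicates. The defaults mirror the
study conditions: spike fractions 0-10%, coverages 2.5-30x, marker counts
25-500, and 12 background "individuals" per condition.

The spike source is a sibling replicate of the target cell type — fragments
sampled from the same methylome with an RNG stream never used for the
reference collections — so the atlas is not fitted on the spiked reads.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .blocks import block_methylation_table, per_cpg_methylation, segment_genome
from .cpgmap import CpGMap
from .deconvolve import (
    Atlas,
    DeconvolutionConfig,
    MethylationDeconvolution,
    build_atlas,
)
from .fragments import FragmentCollection
from .markers import MarkerSelectionConfig, find_markers, rank_and_select
from .simulate import (
    ReferenceMethylome,
    SimulationConfig,
    build_cpg_map,
    mix_fragments,
    sample_fragments,
    simulate_reference_methylomes,
)

__all__ = [
    "SpikeGridConfig",
    "SimulationAssets",
    "prepare_assets",
    "marker_candidates",
    "build_reference_atlas",
    "run_spikein_grid",
    "detection_probability",
    "detection_auc",
    "recovery_regression",
    "recovery_rmse",
    "false_positive_model",
    "RecoveryFit",
    "FalsePositiveFit",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def _subseed(base: int, *keys) -> int:
    """Stable derived seed below 2**31 from a base seed and mixed keys."""
    h = base & 0xFFFFFFFF
    for k in keys:
        if isinstance(k, float):
            k = np.float64(k).tobytes()
        elif isinstance(k, int):
            k = int(k).to_bytes(8, "little", signed=True)
        else:
            k = str(k).encode()
        h = zlib.crc32(k, h)
    return int(np.random.SeedSequence([base % _SEED_MOD, h]).generate_state(1)[0]
               % _SEED_MOD)


@dataclass
class SpikeGridConfig:
    """Grid of spike-in conditions and harness parameters.

    Defaults are the full study grid; scale ``replicates`` and the axes down
    for quick runs. The 0% fraction must be present when AUC is wanted (it
    supplies the unspiked negatives).
    """

    spike_fractions: tuple[float, ...] = (0.0, 0.0001, 0.001, 0.005, 0.01, 0.05, 0.10)
    coverages: tuple[float, ...] = (2.5, 5.0, 10.0, 20.0, 30.0)
    marker_counts: tuple[int, ...] = (25, 50, 100, 250, 300, 400, 500)
    min_cpgs: tuple[int, ...] = (3, 4)
    replicates: int = 12
    base_seed: int = 0
    target_cell_type: str | None = None
    detection_epsilon: float = 0.0
    # segmentation / marker-selection / deconvolution parameters
    max_bp: int = 5000
    homogeneity_tol: float = 0.25
    homogeneity_stat: str = "max"
    marker_config: MarkerSelectionConfig = field(
        default_factory=MarkerSelectionConfig
    )
    deconv_config: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    # asset generation: references emulate deep (30x) WGBS methylomes,
    # three technical replicates per cell type
    n_ref_replicates: int = 3
    ref_coverage: float = 30.0
    pool_coverage: float = 30.0
    # cell types composing the background pools (default: every non-target
    # type); a sparse subset emulates cfDNA whose true origin spans few of
    # the atlas's cell types, the regime where spurious calls appear
    background_cell_types: tuple[str, ...] | None = None


@dataclass
class SimulationAssets:
    """Everything a spike-in grid needs, generated once per base seed."""

    sim_config: SimulationConfig
    cmap: CpGMap
    methylomes: dict[str, ReferenceMethylome]
    ledger: pd.DataFrame
    reference_samples: dict[str, dict[str, FragmentCollection]]
    beta: np.ndarray  # per-CpG methylation across all reference samples
    spike_pool: FragmentCollection
    background_pools: list[FragmentCollection]
    target_cell_type: str

    @property
    def groups(self) -> dict[str, list[str]]:
        return {ct: list(d) for ct, d in self.reference_samples.items()}

    def flat_references(self) -> dict[str, FragmentCollection]:
        return {
            name: coll
            for d in self.reference_samples.values()
            for name, coll in d.items()
        }

    def merged_references(self) -> dict[str, FragmentCollection]:
        return {
            ct: FragmentCollection.concatenate(list(d.values()), provenance=ct)
            for ct, d in self.reference_samples.items()
        }


def prepare_assets(
    sim_config: SimulationConfig, grid: SpikeGridConfig
) -> SimulationAssets:
    """Simulate the world once: methylomes, references, pools.

    Per cell type, ``n_ref_replicates`` reference collections are sampled at
    ``ref_coverage``; an extra target-cell-type replicate (separate seed)
    becomes the spike pool; one background pool per grid replicate mixes the
    non-target cell types at Dirichlet-drawn individual proportions.
    """
    seed0 = grid.base_seed
    cmap = build_cpg_map(sim_config)
    methylomes, ledger = simulate_reference_methylomes(
        cmap, sim_config, seed=_subseed(seed0, "methylomes")
    )
    cell_types = list(methylomes)
    target = grid.target_cell_type or cell_types[0]
    if target not in methylomes:
        raise ValueError(f"unknown target cell type {target!r}")

    reference_samples: dict[str, dict[str, FragmentCollection]] = {}
    for ct in cell_types:
        reference_samples[ct] = {}
        for r in range(grid.n_ref_replicates):
            name = f"{ct}_rep{r + 1}"
            reference_samples[ct][name] = sample_fragments(
                methylomes[ct],
                cmap,
                grid.ref_coverage,
                sim_config,
                seed=_subseed(seed0, "ref", ct, r),
            )

    spike_pool = sample_fragments(
        methylomes[target],
        cmap,
        grid.pool_coverage,
        sim_config,
        seed=_subseed(seed0, "spike-source", target),
    )

    background_pools = []
    if grid.background_cell_types is not None:
        others = list(grid.background_cell_types)
        bad = set(others) - (set(cell_types) - {target})
        if bad:
            raise ValueError(
                f"invalid background cell types: {sorted(bad)}"
            )
    else:
        others = [ct for ct in cell_types if ct != target]
    for rep in range(grid.replicates):
        rng = np.random.default_rng(_subseed(seed0, "individual", rep))
        props = rng.dirichlet(np.full(len(others), 5.0))
        parts = [
            sample_fragments(
                methylomes[ct],
                cmap,
                max(grid.pool_coverage * p, 1e-9),
                sim_config,
                seed=_subseed(seed0, "bg", rep, ct),
            )
            for ct, p in zip(others, props)
            if p > 0
        ]
        background_pools.append(
            FragmentCollection.concatenate(parts, provenance=f"individual{rep + 1}")
        )

    # segmentation input: one methylome per cell type (replicates merged),
    # so per-CpG noise is low and cell-specific boundaries are visible
    beta, _depth, _names = per_cpg_methylation(
        {
            ct: FragmentCollection.concatenate(list(d.values()), provenance=ct)
            for ct, d in reference_samples.items()
        },
        cmap,
    )
    return SimulationAssets(
        sim_config,
        cmap,
        methylomes,
        ledger,
        reference_samples,
        beta,
        spike_pool,
        background_pools,
        target,
    )


def marker_candidates(
    assets: SimulationAssets, grid: SpikeGridConfig, min_cpg: int
) -> dict[str, pd.DataFrame]:
    """Segment and test blocks once: marker candidates per cell type.

    Candidates do not depend on ``k``; the grid runner computes them once per
    segmentation setting and slices the top ``k`` afterwards.
    """
    blocks = segment_genome(
        assets.beta,
        assets.cmap,
        min_cpg=min_cpg,
        max_bp=grid.max_bp,
        homogeneity_tol=grid.homogeneity_tol,
        homogeneity_stat=grid.homogeneity_stat,
    )
    table = block_methylation_table(
        blocks,
        assets.flat_references(),
        assets.cmap,
        min_depth=grid.marker_config.min_depth,
    )
    groups = assets.groups
    out = {}
    for ct, members in groups.items():
        background = [
            s for other, mem in groups.items() if other != ct for s in mem
        ]
        out[ct] = find_markers(table, members, background, grid.marker_config)
    return out


def build_reference_atlas(
    assets: SimulationAssets,
    grid: SpikeGridConfig,
    min_cpg: int,
    k: int,
    candidates: dict[str, pd.DataFrame] | None = None,
) -> Atlas:
    """Segment, select k markers per cell type, and build the U-fraction atlas."""
    if candidates is None:
        candidates = marker_candidates(assets, grid, min_cpg)
    pieces = []
    for ct, cands in candidates.items():
        mset = rank_and_select(cands, k, ct)
        if len(mset):
            piece = mset.table.copy()
            piece["cell_type"] = ct
            pieces.append(piece)
    if not pieces:
        raise ValueError("no markers were selected for any cell type")
    markers = pd.concat(pieces, ignore_index=True)
    return build_atlas(assets.merged_references(), markers, grid.deconv_config)


def run_spikein_grid(
    grid: SpikeGridConfig, assets: SimulationAssets
) -> pd.DataFrame:
    """One deconvolution per grid cell x replicate, as a tidy frame.

    Columns: min_cpg, k, n_markers (atlas rows), coverage, fraction,
    replicate, seed, est (target cell type's estimate), n_detected (cell
    types above ``detection_epsilon``), and prop_<cell type> for every
    column of the atlas. Failed cells are recorded with NaN estimates rather
    than aborting the grid.
    """
    records: list[dict] = []
    cts = list(assets.methylomes)
    target = assets.target_cell_type
    for min_cpg in grid.min_cpgs:
        candidates = marker_candidates(assets, grid, min_cpg)
        for k in grid.marker_counts:
            try:
                atlas = build_reference_atlas(
                    assets, grid, min_cpg, k, candidates
                )
                model = MethylationDeconvolution(atlas, grid.deconv_config)
            except ValueError as exc:
                logger.warning(
                    "atlas failed for min_cpg=%s k=%s: %s", min_cpg, k, exc
                )
                atlas = model = None
            for coverage in grid.coverages:
                for rep in range(grid.replicates):
                    pool = assets.background_pools[rep]
                    for fraction in grid.spike_fractions:
                        seed = _subseed(
                            grid.base_seed, "mix", min_cpg, k, coverage,
                            rep, fraction,
                        )
                        rec = {
                            "min_cpg": min_cpg,
                            "k": k,
                            "n_markers": atlas.n_markers if atlas else 0,
                            "coverage": coverage,
                            "fraction": fraction,
                            "replicate": rep,
                            "seed": seed,
                            "est": np.nan,
                            "n_detected": np.nan,
                        }
                        for ct in cts:
                            rec[f"prop_{ct}"] = np.nan
                        if model is not None:
                            try:
                                mixture = mix_fragments(
                                    pool,
                                    assets.spike_pool,
                                    fraction,
                                    coverage,
                                    assets.cmap,
                                    seed=seed,
                                )
                                res = model.fit(mixture)
                                props = res.proportions
                                rec["est"] = float(props.get(target, np.nan))
                                rec["n_detected"] = len(
                                    res.detected(grid.detection_epsilon)
                                )
                                for ct in props.index:
                                    rec[f"prop_{ct}"] = float(props[ct])
                            except ValueError as exc:
                                logger.warning(
                                    "deconvolution failed (%s): %s", rec, exc
                                )
                        records.append(rec)
    return pd.DataFrame.from_records(records)


# -- metrics over grid results ---------------------------------------------


def _scores(
    results: pd.DataFrame, fraction: float, cell_type: str | None
) -> np.ndarray:
    col = "est" if cell_type is None else f"prop_{cell_type}"
    sub = results.loc[np.isclose(results["fraction"], fraction), col].dropna()
    return sub.to_numpy(dtype=np.float64)


def detection_probability(
    results: pd.DataFrame,
    fraction: float,
    cell_type: str | None = None,
    epsilon: float = 0.0,
) -> float:
    """Fraction of replicates where the cell type's estimate exceeds epsilon."""
    scores = _scores(results, fraction, cell_type)
    if scores.size == 0:
        raise ValueError(f"no replicates at spike fraction {fraction}")
    return float((scores > epsilon).mean())


def detection_auc(
    results: pd.DataFrame, fraction: float, cell_type: str | None = None
) -> float:
    """Rank-based (Mann-Whitney) AUC: spiked replicates vs 0% replicates.

    The estimated proportion is the score, spiked = positive class; tied
    scores contribute 1/2 (midrank convention).
    """
    pos = _scores(results, fraction, cell_type)
    neg = _scores(results, 0.0, cell_type)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both spiked and unspiked replicates for AUC")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass(frozen=True)
class RecoveryFit:
    """OLS of estimated on true spike fraction."""

    slope: float
    intercept: float
    adj_r2: float
    p_value: float  # two-sided, slope
    n_points: int


def recovery_regression(
    results: pd.DataFrame,
    fractions: Sequence[float] | None = None,
    cell_type: str | None = None,
    aggregate: bool = True,
) -> RecoveryFit:
    """Linearity of recovery: estimated ~ true fraction over the 1-10% range.

    With ``aggregate`` (default) replicate estimates are averaged first, so
    the regression has one point per spike fraction; ``aggregate=False``
    fits every replicate as its own point.
    """
    col = "est" if cell_type is None else f"prop_{cell_type}"
    sub = results.dropna(subset=[col])
    if fractions is None:
        sub = sub[(sub["fraction"] >= 0.01) & (sub["fraction"] <= 0.10)]
    else:
        sub = sub[sub["fraction"].isin(list(fractions))]
    if aggregate:
        sub = sub.groupby("fraction", as_index=False)[col].mean()
    x = sub["fraction"].to_numpy(dtype=np.float64)
    y = sub[col].to_numpy(dtype=np.float64)
    if np.unique(x).size < 3:
        raise ValueError("recovery regression needs >= 3 distinct fractions")
    if np.ptp(y) == 0.0:  # constant estimates: slope 0 by convention
        return RecoveryFit(0.0, float(y[0]), 0.0, 1.0, x.size)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RecoveryFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adj_r2=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]),
        n_points=int(fit.nobs),
    )


def recovery_rmse(
    results: pd.DataFrame,
    fractions: Sequence[float] | None = None,
    cell_type: str | None = None,
) -> float:
    """RMSE of estimated vs true fraction, normalized by the mean true value."""
    col = "est" if cell_type is None else f"prop_{cell_type}"
    sub = results.dropna(subset=[col])
    if fractions is not None:
        sub = sub[sub["fraction"].isin(list(fractions))]
    else:
        sub = sub[sub["fraction"] > 0]
    if len(sub) == 0:
        raise ValueError("no results to score")
    err = sub[col].to_numpy() - sub["fraction"].to_numpy()
    return float(np.sqrt(np.mean(err**2)) / np.mean(sub["fraction"]))


@dataclass(frozen=True)
class FalsePositiveFit:
    """OLS of detected-cell-type count on coverage and marker count."""

    params: pd.Series
    pvalues: pd.Series
    n_obs: int


def false_positive_model(results: pd.DataFrame) -> FalsePositiveFit:
    """Fit (n cell types detected) ~ coverage + n_markers with an intercept."""
    sub = results.dropna(subset=["n_detected"])
    x = sub[["coverage", "n_markers"]].to_numpy(dtype=np.float64)
    y = sub["n_detected"].to_numpy(dtype=np.float64)
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            "collinear design: coverage and n_markers must both vary"
        )
    fit = sm.OLS(y, design).fit()
    names = ["intercept", "coverage", "n_markers"]
    return FalsePositiveFit(
        params=pd.Series(fit.params, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        n_obs=int(fit.nobs),
    )
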