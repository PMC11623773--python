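"""Synthetic WGBS methylomes, fragments and cfDNA mixtures.

This module generates the ground-truth world the rest of the package is
evaluated against: a CpG universe, one reference methylome per cell type with
planted cell-type-specific hypomethylated blocks, read-level fragment
collections at configurable coverage with bisulfite miscall noise, and
cfDNA-style mixtures with a known spike-in fraction of a target cell type.

The defaults emulate the study conditions of a plasma-cfDNA tissue-of-origin
experiment: a multi-cell-type methylation atlas with ~0.8 methylation gap at
cell-specific blocks (low propensity 0.10 inside a cell type's own blocks vs
a 0.90 background), short fragments covering a handful of CpGs (truncated
geometric, mean 5, max 20), a 0.5% symmetric bisulfite miscall rate, and
coverages spanning 2.5-30x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpgmap import CpGMap
from .fragments import METH, UNMETH, FragmentCollection

__all__ = [
    "SimulationConfig",
    "ReferenceMethylome",
    "build_cpg_map",
    "simulate_reference_methylomes",
    "sample_fragments",
    "mix_fragments",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(ValueError):
    """Requested planted blocks do not fit in the CpG map."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults are the package's study conditions: 10 cell types, 500 planted
    cell-specific hypomethylated blocks each (enough to select up to k=500
    markers per cell type), 0.10 vs 0.90 methylation propensities (gap 0.8),
    mean 100 bp CpG spacing, truncated-geometric fragment lengths with mean
    5 CpGs capped at 20, and a 0.5% per-call miscall rate. Planted blocks
    span 12-24 CpGs (~1.2-2.4 kb): real co-methylated blocks average ~17
    CpGs genome-wide, and cell-type-specific hypomethylated regions are
    enhancer/domain scale, so markers carry tens of fragments at 10x. With
    block + gap footprints averaging ~24.5 CpGs the 130,000-CpG universe
    hosts all 5,000 blocks.
    """

    n_cell_types: int = 10
    n_cpgs: int = 130_000
    n_chromosomes: int = 1
    cpg_spacing_mean: float = 100.0
    cpg_spacing_model: str = "geometric"  # or "fixed"
    blocks_per_cell_type: int = 500
    block_min_cpgs: int = 12
    block_max_cpgs: int = 24
    gap_min_cpgs: int = 3
    gap_max_cpgs: int = 10
    low_propensity: float = 0.10
    high_propensity: float = 0.90
    frag_len_mean: float = 5.0
    frag_len_max: int = 20
    miscall_rate: float = 0.005
    coverage: float = 10.0
    cell_type_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ConfigurationError("n_cpgs must be >= 1")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")
        for name in ("low_propensity", "high_propensity", "miscall_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.cpg_spacing_model not in ("geometric", "fixed"):
            raise ConfigurationError("cpg_spacing_model must be geometric|fixed")
        if self.cpg_spacing_mean < 2:
            raise ConfigurationError("cpg_spacing_mean must be >= 2 bp")
        if self.frag_len_mean < 1 or self.frag_len_max < 1:
            raise ConfigurationError("fragment length parameters must be >= 1")
        if self.block_min_cpgs < 1 or self.block_max_cpgs < self.block_min_cpgs:
            raise ConfigurationError("invalid planted block size range")
        if self.n_chromosomes < 1 or self.n_chromosomes > self.n_cpgs:
            raise ConfigurationError("n_chromosomes must be in [1, n_cpgs]")

    @property
    def cell_types(self) -> tuple[str, ...]:
        if self.cell_type_names is not None:
            if len(self.cell_type_names) != self.n_cell_types:
                raise ConfigurationError("cell_type_names length != n_cell_types")
            return tuple(self.cell_type_names)
        width = max(2, len(str(self.n_cell_types)))
        return tuple(f"cell{i + 1:0{width}d}" for i in range(self.n_cell_types))


@dataclass
class ReferenceMethylome:
    """Per-CpG methylation propensity of one cell type."""

    cell_type: str
    propensity: np.ndarray

    def __post_init__(self) -> None:
        self.propensity = np.asarray(self.propensity, dtype=np.float64)
        if self.propensity.ndim != 1:
            raise ValueError("propensity must be 1-D (one value per CpG)")
        if self.propensity.size and (
            self.propensity.min() < 0 or self.propensity.max() > 1
        ):
            raise ValueError("propensities must lie in [0, 1]")


def build_cpg_map(config: SimulationConfig) -> CpGMap:
    """Draw the CpG universe (deterministic for a fixed config/seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cpgs
    if config.cpg_spacing_model == "fixed":
        spacing = np.full(n, int(round(config.cpg_spacing_mean)), dtype=np.int64)
    else:
        # minimum 2 bp between CpG starts; geometric tail gives the mean
        p = 1.0 / max(config.cpg_spacing_mean - 1.0, 1.0)
        spacing = 1 + rng.geometric(p, size=n).astype(np.int64)
    # chromosomes are contiguous, near-equal chunks; positions restart per chrom
    bounds = np.linspace(0, n, config.n_chromosomes + 1).astype(np.int64)
    bounds = np.unique(bounds)
    chroms = tuple(f"chr{i + 1}" for i in range(len(bounds) - 1))
    positions = np.empty(n, dtype=np.int64)
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        positions[lo:hi] = 1000 + np.cumsum(spacing[lo:hi]) - spacing[lo]
    return CpGMap(chroms, bounds, positions)


def simulate_reference_methylomes(
    cmap: CpGMap, config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, ReferenceMethylome], pd.DataFrame]:
    """One methylome per cell type plus the planted-block ground truth.

    Every planted block belongs to exactly one cell type: propensity is
    ``low_propensity`` there in the owner and ``high_propensity`` in all other
    cell types (and everywhere outside planted blocks), so the owner-vs-rest
    methylation gap equals ``high - low`` (0.8 by default, well above the 0.3
    marker-selection threshold).

    Returns
    -------
    methylomes
        Mapping cell type -> :class:`ReferenceMethylome`.
    ledger
        Ground-truth table of planted blocks: chrom, start_bp, end_bp,
        start_cpg, end_cpg, n_cpgs, cell_type.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_blocks = config.n_cell_types * config.blocks_per_cell_type
    # round-robin owners, then shuffled so genomic order carries no signal
    owners = np.tile(np.arange(config.n_cell_types), config.blocks_per_cell_type)
    rng.shuffle(owners)

    placements: list[tuple[int, int]] = []  # (start_cpg, end_cpg)
    placed = 0
    for ci in range(len(cmap.chroms)):
        lo, hi = int(cmap.chrom_offsets[ci]), int(cmap.chrom_offsets[ci + 1])
        cursor = lo
        while placed < n_blocks:
            gap = int(rng.integers(config.gap_min_cpgs, config.gap_max_cpgs + 1))
            size = int(rng.integers(config.block_min_cpgs, config.block_max_cpgs + 1))
            if cursor + gap + size > hi:
                break  # next chromosome; blocks never span boundaries
            start = cursor + gap
            placements.append((start, start + size))
            cursor = start + size
            placed += 1
        if placed >= n_blocks:
            break
    if placed < n_blocks:
        raise PlacementError(
            f"map of {cmap.n_cpgs} CpGs cannot host {n_blocks} planted blocks "
            f"(placed {placed}); increase n_cpgs or reduce blocks_per_cell_type"
        )

    cell_types = config.cell_types
    base = np.full(cmap.n_cpgs, config.high_propensity, dtype=np.float64)
    methylomes = {ct: ReferenceMethylome(ct, base.copy()) for ct in cell_types}
    rows = []
    for (start, end), owner in zip(placements, owners):
        ct = cell_types[owner]
        methylomes[ct].propensity[start:end] = config.low_propensity
        chrom = cmap.chrom_of(start)
        rows.append(
            {
                "chrom": chrom,
                "start_bp": int(cmap.positions[start]),
                "end_bp": int(cmap.positions[end - 1]) + 2,
                "start_cpg": start,
                "end_cpg": end,
                "n_cpgs": end - start,
                "cell_type": ct,
            }
        )
    ledger = pd.DataFrame(rows).sort_values(
        ["start_cpg"], kind="stable", ignore_index=True
    )
    return methylomes, ledger


def _truncated_geometric_mean(mean: float, cap: int) -> float:
    """E[min(G, cap)] for G ~ Geometric(1/mean) on {1, 2, ...}."""
    if mean <= 1.0:
        return 1.0
    p = 1.0 / mean
    return (1.0 - (1.0 - p) ** cap) / p


def sample_fragments(
    methylome: ReferenceMethylome,
    cmap: CpGMap,
    coverage: float,
    config: SimulationConfig,
    seed: int | None = None,
) -> FragmentCollection:
    """Sample a fragment collection at the given nominal coverage.

    Fragment starts are uniform over CpG indices; lengths are truncated
    geometric (mean ``frag_len_mean``, cap ``frag_len_max``), further clipped
    at the chromosome end so no fragment spans a boundary. Each covered CpG
    is called Bernoulli(propensity) then flipped with ``miscall_rate``.
    Expected total calls = ``coverage * n_cpgs`` (up to truncation effects).
    """
    if coverage <= 0:
        raise ConfigurationError("coverage must be > 0")
    if methylome.propensity.size != cmap.n_cpgs:
        raise ValueError("methylome does not match the CpG map")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mean_len = _truncated_geometric_mean(config.frag_len_mean, config.frag_len_max)
    n_frags = max(1, int(round(coverage * cmap.n_cpgs / mean_len)))

    starts = rng.integers(0, cmap.n_cpgs, size=n_frags)
    if config.frag_len_mean <= 1.0:
        lengths = np.ones(n_frags, dtype=np.int64)
    else:
        lengths = np.minimum(
            rng.geometric(1.0 / config.frag_len_mean, size=n_frags),
            config.frag_len_max,
        ).astype(np.int64)
    chrom_idx = cmap.chrom_index_of(starts)
    chrom_end = cmap.chrom_offsets[chrom_idx + 1]
    lengths = np.minimum(lengths, chrom_end - starts)

    total = int(lengths.sum())
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    call_idx = np.repeat(starts, lengths) + (
        np.arange(total, dtype=np.int64) - np.repeat(offsets[:-1], lengths)
    )
    p = methylome.propensity[call_idx]
    meth = rng.random(total) < p
    if config.miscall_rate > 0:
        meth ^= rng.random(total) < config.miscall_rate
    calls = np.where(meth, METH, UNMETH).astype(np.uint8)

    return FragmentCollection(
        chrom_idx.astype(np.int32),
        cmap.chroms,
        starts,
        lengths,
        calls,
        provenance=f"{methylome.cell_type}",
        seed=seed if seed is not None else config.seed,
    )


def mix_fragments(
    background: FragmentCollection,
    spike: FragmentCollection,
    spike_fraction: float,
    target_coverage: float,
    cmap: CpGMap,
    seed: int | None = None,
) -> FragmentCollection:
    """Down-/up-sample two pools into a mixture with a known spike fraction.

    The spike fraction is defined over CpG calls (information content), not
    fragment counts: the expected fraction of calls in the output that
    originate from the spike pool equals ``spike_fraction``, and the expected
    total number of calls equals ``target_coverage * n_cpgs``. Pools smaller
    than their budget are up-sampled by drawing fragments with replacement.
    Fragment provenance is retained in ``origin`` (0 = background, 1 = spike)
    for validation only.
    """
    if not 0.0 <= spike_fraction <= 1.0:
        raise ValueError("spike_fraction must lie in [0, 1]")
    if background.n_fragments == 0 and spike_fraction < 1.0:
        raise ValueError("background pool is empty but spike_fraction < 1")
    if spike.n_fragments == 0 and spike_fraction > 0.0:
        raise ValueError("spike pool is empty but spike_fraction > 0")
    rng = np.random.default_rng(seed)
    budget = target_coverage * cmap.n_cpgs

    def _draw(pool: FragmentCollection, calls_budget: float, tag: int):
        if calls_budget <= 0:
            out = pool.take(np.empty(0, dtype=np.int64))
            out.origin = np.empty(0, dtype=np.int8)
            return out
        weights = pool.counts / pool.counts.sum()
        mean_calls = pool.total_calls(include_missing=True) / pool.n_records
        n_draw = max(1, int(round(calls_budget / mean_calls)))
        idx = rng.choice(pool.n_fragments, size=n_draw, replace=True, p=weights)
        out = pool.take(np.sort(idx), counts=np.ones(n_draw, dtype=np.int64))
        out.origin = np.full(n_draw, tag, dtype=np.int8)
        return out

    bg_part = _draw(background, (1.0 - spike_fraction) * budget, 0)
    sp_part = _draw(spike, spike_fraction * budget, 1)
    mixed = FragmentCollection.concatenate(
        [bg_part, sp_part],
        provenance=(
            f"mix({background.provenance}+{spike.provenance}"
            f"@{spike_fraction:g},cov={target_coverage:g})"
        ),
    )
    mixed.seed = seed
    return mixed


def spike_call_fraction(mixture: FragmentCollection) -> float:
    """Realized fraction of calls from the spike pool (validation helper)."""
    if mixture.origin is None:
        raise ValueError("mixture carries no origin provenance")
    per_frag_calls = mixture.lengths * mixture.counts
    total = per_frag_calls.sum()
    if total == 0:
        return math.nan
    return float(per_frag_calls[mixture.origin == 1].sum() / total)
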