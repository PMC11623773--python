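"""Shared fixtures: tiny synthetic worlds and hand-built fragment sets."""

from __future__ import annotations

import numpy as np
import pytest

from cfdecon import (
    CpGMap,
    FragmentCollection,
    MethylationFragment,
    SimulationConfig,
    build_cpg_map,
    simulate_reference_methylomes,
)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """3 cell types, 4,000 CpGs, 20 planted blocks each — fast everywhere."""
    return SimulationConfig(
        n_cell_types=3,
        n_cpgs=4000,
        blocks_per_cell_type=20,
        block_min_cpgs=6,
        block_max_cpgs=10,
        seed=42,
    )


@pytest.fixture
def tiny_world(tiny_config):
    cmap = build_cpg_map(tiny_config)
    methylomes, ledger = simulate_reference_methylomes(cmap, tiny_config, seed=42)
    return tiny_config, cmap, methylomes, ledger


@pytest.fixture
def uniform_map():
    """Single-chromosome map with fixed 50 bp spacing, 100 CpGs."""
    cfg = SimulationConfig(
        n_cpgs=100, cpg_spacing_model="fixed", cpg_spacing_mean=50, seed=0
    )
    return build_cpg_map(cfg)


def collection_from(frags) -> FragmentCollection:
    return FragmentCollection.from_fragments(
        [MethylationFragment(*f) if not isinstance(f, MethylationFragment) else f
         for f in frags]
    )


@pytest.fixture
def make_collection():
    return collection_from
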