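"""Structured run configuration (YAML) with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deconvolve import DeconvolutionConfig
from .markers import MarkerSelectionConfig
from .simulate import SimulationConfig
from .spikein import SpikeGridConfig

__all__ = ["RunConfig", "SegmentationParams", "PKScenarioParams",
           "load_run_config", "dump_run_config", "ConfigError"]


class ConfigError(ValueError):
    """Unknown or invalid configuration keys."""


@dataclass
class SegmentationParams:
    min_cpg: int = 4
    max_bp: int = 5000
    homogeneity_tol: float = 0.25
    homogeneity_stat: str = "max"
    min_depth_clustering: int = 10
    top_variance_fraction: float = 0.01


@dataclass
class PKScenarioParams:
    d_values: tuple[float, ...] = (0.03, 0.00003)
    durations_years: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    t_half_min: float = 114.0
    vd_litres: float = 3.0
    n_cells: float = 500_000.0
    genome_mass_pg: float = 6.46
    total_cfdna_pg_per_ul: float = 297.0


@dataclass
class RunConfig:
    """Every stage's parameters under named sections, plus seed and outdir."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    markers: MarkerSelectionConfig = field(default_factory=MarkerSelectionConfig)
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    spike: SpikeGridConfig = field(default_factory=SpikeGridConfig)
    pk: PKScenarioParams = field(default_factory=PKScenarioParams)
    seed: int = 0
    outdir: str = "cfdecon_run"


_NESTED_IN_SPIKE = {"marker_config": MarkerSelectionConfig,
                    "deconv_config": DeconvolutionConfig}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path or cls.__name__} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{path or 'root'}'"
        )
    kwargs = {}
    for key, value in data.items():
        if cls is SpikeGridConfig and key in _NESTED_IN_SPIKE:
            value = _build(_NESTED_IN_SPIKE[key], value, f"{path}.{key}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "simulation": SimulationConfig,
    "segmentation": SegmentationParams,
    "markers": MarkerSelectionConfig,
    "deconvolution": DeconvolutionConfig,
    "spike": SpikeGridConfig,
    "pk": PKScenarioParams,
}


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("run configuration must be a YAML mapping")
    unknown = set(data) - (set(_SECTIONS) | {"seed", "outdir"})
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "outdir" in data:
        kwargs["outdir"] = str(data["outdir"])
    return RunConfig(**kwargs)


def dump_run_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration beside a run's outputs."""
    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            return {
                f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if f.init
            }
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(_plain(config), sort_keys=False))
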