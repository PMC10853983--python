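"""Structured pipeline configuration (YAML, strict keys)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cassfinder.detect import DetectorConfig
from cassfinder.dotplot import DotplotConfig
from cassfinder.promoter import MotifConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration key."""


@dataclass(frozen=True)
class SimulateConfig:
    """Synthetic study conditions for an end-to-end run."""

    background_length: int = 60000
    n_cassandra: int = 5
    n_trim: int = 2
    ltr_length: int = 270
    internal_length: int = 82
    divergence: float = 0.0
    tsd_length: int = 5
    gene_cbox_variant: str = "canonical"  # variant of the genomic 5S genes
    element_cbox_variant: str = "canonical"  # variant carried by Cassandra copies
    rdna_copies: int = 4
    rdna_linked: bool = True
    rdna_scale: float = 1.0  # scales the 35S marker-block lengths


@dataclass(frozen=True)
class ClusterConfig:
    threshold: float = 70.0
    min_indel: int = 10
    bin_size: int = 10


@dataclass(frozen=True)
class LinkageConfig:
    k: int = 31
    min_count: int = 2
    distance: int = 25
    read_length: int = 100
    coverage: float = 20.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 1
    outdir: str = "cassfinder_out"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    motifs: MotifConfig = field(default_factory=MotifConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    dotplot: DotplotConfig = field(default_factory=DotplotConfig)
    linkage: LinkageConfig = field(default_factory=LinkageConfig)


_SECTION_TYPES = {
    "simulate": SimulateConfig,
    "detector": DetectorConfig,
    "motifs": MotifConfig,
    "clustering": ClusterConfig,
    "dotplot": DotplotConfig,
    "linkage": LinkageConfig,
}


def _build(cls, data: dict, context: str):
    from cassfinder.align import Scoring

    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    data = dict(data)
    if isinstance(data.get("scoring"), dict):
        data["scoring"] = _build(Scoring, data["scoring"], f"{context}.scoring")
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected by section."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    for key, value in (overrides or {}).items():
        data[key] = value

    kwargs: dict = {}
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully-resolved configuration next to the outputs."""

    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(cfg), fh, sort_keys=False)
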