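"""Run configuration: every threshold in one place, YAML round-trip, and
provenance serialization into output directories."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


@dataclass
class RunConfig:
    # paths
    genome: str = ""
    out_dir: str = "results"
    reads: dict = field(default_factory=dict)  # condition -> [fq1, fq2]
    sam: dict = field(default_factory=dict)  # condition -> sam path
    catalog_bed: str = ""
    # thresholds
    min_repeat_length: int = 50
    min_identity: float = 85.0
    discordance_span: int = 1000
    cluster_support: int = 10
    snp_depth: int = 5
    snp_fraction: float = 0.8
    class1_depletion: float = 0.5
    class2_band: float = 0.25
    substoichiometric: float = 0.05
    # library geometry
    read_length: int = 36
    insert_mean: int = 220
    insert_sd: int = 20
    # simulation
    seed: int = 1
    genome_length: int = 100_000
    profile: str = "standard"
    circular: bool = True
    # panel
    n_ecotypes: int = 72
    n_groups: int = 6
    panel_genome_length: int = 40_000

    def validate(self) -> "RunConfig":
        positive = [
            ("min_repeat_length", self.min_repeat_length),
            ("discordance_span", self.discordance_span),
            ("cluster_support", self.cluster_support),
            ("snp_depth", self.snp_depth),
            ("read_length", self.read_length),
            ("insert_mean", self.insert_mean),
            ("insert_sd", self.insert_sd),
            ("class1_depletion", self.class1_depletion),
            ("class2_band", self.class2_band),
            ("substoichiometric", self.substoichiometric),
        ]
        for name, v in positive:
            if v <= 0:
                raise ConfigError(f"threshold {name} must be positive, got {v}")
        if not (0 < self.snp_fraction < 1):
            raise ConfigError("snp_fraction must be in (0, 1)")
        if not (0 < self.min_identity <= 100):
            raise ConfigError("min_identity must be in (0, 100]")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
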