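"""Pipeline configuration: a strict YAML-backed parameter set.

Every threshold defaults to the analysis constants of the study design
(65/35 markers, 25/70 domain bounds, 3 groups x 4 cells, 100 iterations,
>10-point difference, >=50% consensus, QC >10% mapping / >500k CpGs, 2-kb
windows, 0.04-2 input band, RPKM>1 enrichment).  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import SimConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: dict = field(default_factory=dict)     # SimConfig overrides

    # classifier
    n_down: int = 65
    n_up: int = 35
    padj_threshold: float = 0.05
    ratio_threshold: float = 0.8

    # methylome
    min_mapping: float = 10.0
    min_cpgs: int = 500_000
    noncpg_lower: float = 1.0
    domain_low: float = 25.0
    domain_high: float = 70.0
    group_size: int = 4
    n_groups: int = 3
    n_iterations: int = 100
    diff_threshold: float = 10.0
    alpha: float = 0.05
    consensus: float = 0.5
    min_calls: int = 10

    # chromatin
    window_size: int = 2000
    input_low: float = 0.04
    input_high: float = 2.0
    enrich_threshold: float = 1.0
    n_random: int = 100

    def validate(self) -> "PipelineConfig":
        if self.domain_low >= self.domain_high:
            raise ConfigError("PipelineConfig: domain_low must be < domain_high")
        if not 0 < self.consensus <= 1:
            raise ConfigError("PipelineConfig: consensus must be in (0, 1]")
        if self.input_low >= self.input_high:
            raise ConfigError("PipelineConfig: input_low must be < input_high")
        for name in ("n_down", "n_up", "group_size", "n_groups", "n_iterations",
                     "window_size", "min_calls", "n_random"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"PipelineConfig.{name} must be positive")
        if self.diff_threshold < 0 or not 0 < self.alpha < 1:
            raise ConfigError("PipelineConfig: bad diff_threshold/alpha")
        sim_fields = {f.name for f in fields(SimConfig)}
        unknown = set(self.sim) - sim_fields
        if unknown:
            raise ConfigError(f"PipelineConfig.sim: unknown keys {sorted(unknown)}")
        return self

    def sim_config(self) -> SimConfig:
        cfg = SimConfig(seed=self.seed, **self.sim)
        if "seed" in self.sim:
            cfg.seed = self.sim["seed"]
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown configuration keys {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
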