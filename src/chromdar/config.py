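"""Pipeline configuration.

Every numeric threshold used by the analysis is a config key whose default is
the value used throughout the package's reference workflow, so a default run
reproduces the standard analysis and any threshold can be overridden from a
flat YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    vehicle_label: str = "VEH"
    min_samples_for_consensus: int = 5
    dar_alpha: float = 0.05
    link_windows_bp: list[int] = field(default_factory=lambda: [2000, 20000])
    tss_flank_bp: int = 1000
    tss_window_bp: int = 100
    permutations: int = 1000
    rng_seed: int = 0
    fisher_switch_count: int = 10
    frip_floor: float = 0.2
    cpm_prior: float = 0.5
    drop_chroms: list[str] = field(default_factory=lambda: ["chrY"])
    contig_allowlist: list[str] | None = None
    n_pcs: int = 5
    correlation_method: str = "spearman"  # or "pearson"

    def __post_init__(self) -> None:
        if not (0.0 < self.dar_alpha < 1.0):
            raise ConfigurationError("dar_alpha must be in (0, 1)")
        for key in ("min_samples_for_consensus", "tss_flank_bp", "tss_window_bp",
                    "permutations", "fisher_switch_count"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be positive")
        if any(w <= 0 for w in self.link_windows_bp):
            raise ConfigurationError("link windows must be positive")
        if self.tss_flank_bp % self.tss_window_bp != 0:
            raise ConfigurationError("tss_flank_bp must be divisible by tss_window_bp")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ConfigurationError(
                f"unknown correlation_method {self.correlation_method!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a key-value mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
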