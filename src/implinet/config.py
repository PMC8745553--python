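"""Declarative pipeline configuration.

Every analysis threshold lives here and nowhere else; stages receive their
constants from the config object, and every output's metadata block
serializes the thresholds that produced it.  Defaults are the study's
printed constants: z critical 1.64 (one-tailed α = 0.05), 30% housekeeping
flag fraction, −0.5 dependency threshold, −0.74 risk cutoff, 20/58-month
survival group bounds, 0.5/2 fold-change bounds and the 0.0006–10 µM dose
window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .survival import SEVEN_GENES


@dataclass
class PipelineConfig:
    seed: int = 0
    cohorts: dict = field(default_factory=dict)  # label -> {expr: path, cnv: path}
    seed_genes: tuple[str, ...] = SEVEN_GENES
    z_crit: float = 1.64
    variance: str = "conditional"
    target_fraction: float = 0.30
    cnv_gain_threshold: float = 0.3
    cnv_loss_threshold: float = -0.3
    min_samples: int = 20
    min_seed_degree: int = 2
    dependency_threshold: float = -0.5
    proliferation_rule: str = "majority"  # majority | count
    proliferation_min_lines: int = 10
    risk_cutoff: float = -0.74
    partition_fraction: float = 0.5
    survival_short_max: float = 20.0
    survival_long_min: float = 58.0
    fc_bounds: tuple[float, float] = (0.5, 2.0)
    dose_window: tuple[float, float] = (0.0006, 10.0)
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seed_genes", "fc_bounds", "dose_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seed_genes"] = list(self.seed_genes)
        d["fc_bounds"] = list(self.fc_bounds)
        d["dose_window"] = list(self.dose_window)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
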