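"""Pipeline configuration: every tunable threshold in one place.

Defaults reproduce the analysis protocol exactly: contaminant removal,
precursor filter Global.PG.Q.Value < 0.01 / Precursor.Charge > 1 /
Channel.Q.Value < 0.03, >= 3 non-missing values per experimental group,
significance at adjusted p < 0.05, and the 10% constancy tolerance of the
temporal clusters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # paths
    report_path: str = "report.tsv"
    design_path: str = "design.tsv"
    output_dir: str = "output"

    # quantification
    contaminant_prefix: str = "Cont_"
    pg_q: float = 0.01
    channel_q: float = 0.03
    min_charge_exclusive: int = 1
    ratio_pooling: str = "pool"          # pool | ms1-only
    normalize: bool = True

    # statistics
    min_per_group: int = 3
    alpha: float = 0.05
    trend: bool = True
    robust: bool = True
    center_heavy: bool = True

    # clustering
    rel_tol: float = 0.10

    # simulation
    n_proteins: int = 200
    n_replicates: int = 3
    include_inhibitors: bool = True
    n_autophagy_substrates: int = 20
    n_proteasome_substrates: int = 20
    n_contaminants: int = 5
    noise_cv: float = 0.1
    mnar_threshold: float = 0.0
    mcar_rate: float = 0.01
    qvalue_fail_rate: float = 0.02
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)
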