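"""Experimental design: sample coordinates and the pulse-labeling factorial.

A dynamic-SILAC pulse experiment is described by runs, each located at
condition (homeostatic vs. TNF-alpha-induced atrophy) x chase time
(0/24/72 h after the switch to heavy medium) x proteolysis-inhibitor arm
(none / BafA1 blocking the autophagy-lysosome pathway / lactacystin
blocking the proteasome) x replicate. Baseline t0 runs precede both the
atrophy stimulus and the inhibitors, so t0 is always (homeostatic, none).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CONDITIONS = ("homeostatic", "atrophy")
TIMES_H = (0, 24, 72)
INHIBITORS = ("none", "BafA1", "Lac")

_COND_CODE = {"homeostatic": "H", "atrophy": "A"}
_CODE_COND = {v: k for k, v in _COND_CODE.items()}

_RUN_ID_RE = re.compile(r"^([HA])(\d+)_(none|BafA1|Lac)_r(\d+)$")

DESIGN_COLUMNS = ["run_id", "condition", "time_h", "inhibitor", "replicate"]


@dataclass(frozen=True, order=True)
class SampleKey:
    """Experimental coordinates of one LC-MS run."""

    condition: str
    time_h: int
    inhibitor: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.time_h not in TIMES_H:
            raise ValueError(f"time_h must be one of {TIMES_H}, got {self.time_h}")
        if self.inhibitor not in INHIBITORS:
            raise ValueError(f"unknown inhibitor {self.inhibitor!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.time_h == 0 and (self.condition != "homeostatic" or self.inhibitor != "none"):
            # t0 is harvested before TNF-alpha and before any inhibitor
            raise ValueError("t0 runs must be (homeostatic, none)")

    @property
    def run_id(self) -> str:
        return f"{_COND_CODE[self.condition]}{self.time_h}_{self.inhibitor}_r{self.replicate}"

    @property
    def group(self) -> str:
        """Experimental-group label (condition x time x inhibitor cell)."""
        return f"{_COND_CODE[self.condition]}{self.time_h}_{self.inhibitor}"

    @classmethod
    def from_run_id(cls, run_id: str) -> "SampleKey":
        m = _RUN_ID_RE.match(run_id)
        if m is None:
            raise ValueError(f"malformed run_id {run_id!r}")
        cond, t, inh, rep = m.groups()
        return cls(_CODE_COND[cond], int(t), inh, int(rep))


def make_design(n_replicates: int, include_inhibitors: bool = True) -> list[SampleKey]:
    """Full factorial design of the pulse-labeling experiment.

    Baseline t0 runs (homeostatic, no inhibitor) plus
    {homeostatic, atrophy} x {24, 72} h x inhibitor arms, each with
    ``n_replicates`` replicates. Deterministic ordering: t0 first, then
    condition, time, inhibitor, replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    inhibitors = INHIBITORS if include_inhibitors else ("none",)
    design = [SampleKey("homeostatic", 0, "none", r) for r in range(1, n_replicates + 1)]
    for condition in CONDITIONS:
        for time_h in (24, 72):
            for inhibitor in inhibitors:
                for r in range(1, n_replicates + 1):
                    design.append(SampleKey(condition, time_h, inhibitor, r))
    return design


def design_to_frame(design: Sequence[SampleKey]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_id": [k.run_id for k in design],
            "condition": [k.condition for k in design],
            "time_h": [k.time_h for k in design],
            "inhibitor": [k.inhibitor for k in design],
            "replicate": [k.replicate for k in design],
        }
    )


def frame_to_design(frame: pd.DataFrame) -> list[SampleKey]:
    missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    keys = []
    for row in frame.itertuples(index=False):
        key = SampleKey(row.condition, int(row.time_h), row.inhibitor, int(row.replicate))
        if key.run_id != row.run_id:
            raise ValueError(
                f"run_id {row.run_id!r} inconsistent with its fields (expected {key.run_id!r})"
            )
        keys.append(key)
    if len({k.run_id for k in keys}) != len(keys):
        raise ValueError("duplicate run_id in design table")
    return keys


def write_design(design: Sequence[SampleKey], path: str | Path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> list[SampleKey]:
    return frame_to_design(pd.read_csv(path, sep="\t"))


def groups_of(design: Iterable[SampleKey]) -> dict[str, list[str]]:
    """Map experimental-group label -> ordered run_ids."""
    out: dict[str, list[str]] = {}
    for key in design:
        out.setdefault(key.group, []).append(key.run_id)
    return out
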