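"""Four-way temporal clustering of total protein intensity trajectories.

Each protein's replicate-averaged normalized total intensity at t0, t24
and t72 (inhibitor-free runs; the shared baseline t0 serves both
conditions) is assigned to one of four trajectory clusters:

    1 increasing   — steady rise from t0 to t72
    2 constant     — variation within 10% of the profile's maximum change
    3 intermittent — drop or rise at t24 returning to baseline at t72
    4 decreasing   — steady fall from t0 to t72

The tolerance is tau = rel_tol * delta_max with delta_max the largest
absolute pairwise change among the three time points (per protein, which
keeps the rule scale-invariant). The constancy test compares delta_max to
the profile maximum, since a profile's total excursion being small
relative to its own level is what "constant" means. Rule precedence is
fixed: constant, then monotone up/down, then intermittent, else
unassigned.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import SampleKey

DEFAULT_REL_TOL = 0.10

CLUSTER_NAMES = {1: "increasing", 2: "constant", 3: "intermittent", 4: "decreasing", 0: "unassigned"}


def average_replicates(total: pd.DataFrame, design: Sequence[SampleKey]) -> pd.DataFrame:
    """Replicate-mean total intensity per protein, condition and time point.

    Only inhibitor-free runs enter; t0 (acquired before the atrophy
    stimulus) provides the baseline for both conditions. Returns a long
    table (protein_id, condition, i0, i24, i72) with NaN where a time
    point has no observation.
    """
    frames = []
    for condition in ("homeostatic", "atrophy"):
        cols = {}
        for t in (0, 24, 72):
            runs = [
                k.run_id
                for k in design
                if k.inhibitor == "none"
                and k.time_h == t
                and (k.condition == condition or t == 0)
                and k.run_id in total.columns
            ]
            cols[f"i{t}"] = total[runs].mean(axis=1) if runs else pd.Series(np.nan, index=total.index)
        frame = pd.DataFrame(cols)
        frame.insert(0, "condition", condition)
        frame.insert(0, "protein_id", total.index)
        frames.append(frame.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def assign_cluster(
    i0: float,
    i24: float,
    i72: float,
    rel_tol: float = DEFAULT_REL_TOL,
    delta_max: float | None = None,
) -> int:
    """Cluster id (1-4, 0 = unassigned) for one intensity triple.

    ``delta_max`` overrides the per-protein maximum pairwise change with a
    dataset-wide value for the alternative (non-scale-invariant) reading.
    """
    vals = (i0, i24, i72)
    if any(v is None or not np.isfinite(v) for v in vals):
        return 0
    if any(v < 0 for v in vals):
        raise ValueError("intensities must be non-negative")
    if all(v == 0 for v in vals):
        raise ValueError("all-zero profile has no defined trajectory")
    dmax_own = max(abs(i24 - i0), abs(i72 - i24), abs(i72 - i0))
    dmax = dmax_own if delta_max is None else float(delta_max)
    tau = rel_tol * dmax

    if dmax_own <= rel_tol * max(vals):  # (a) constant: total excursion small vs level
        return 2
    if i0 < i24 - tau and i24 < i72 + tau and i72 > i0:  # (b) monotone up within tolerance
        return 1
    if i0 > i24 + tau and i24 > i72 - tau and i72 < i0:  # (c) monotone down
        return 4
    if abs(i72 - i0) <= tau and abs(i24 - i0) > tau:  # (d) excursion at t24, back to baseline
        return 3
    return 0


def assign_clusters(
    profiles: pd.DataFrame,
    rel_tol: float = DEFAULT_REL_TOL,
    dataset_delta_max: bool = False,
) -> pd.DataFrame:
    """Add ``cluster`` (id) and ``cluster_name`` columns to a profile table."""
    out = profiles.copy()
    dmax_global = None
    if dataset_delta_max:
        diffs = np.column_stack(
            [
                (out["i24"] - out["i0"]).abs(),
                (out["i72"] - out["i24"]).abs(),
                (out["i72"] - out["i0"]).abs(),
            ]
        )
        dmax_global = float(np.nanmax(diffs))
    clusters = []
    for row in out.itertuples(index=False):
        if any(not np.isfinite(v) for v in (row.i0, row.i24, row.i72)):
            clusters.append(0)
        else:
            clusters.append(assign_cluster(row.i0, row.i24, row.i72, rel_tol, dmax_global))
    out["cluster"] = clusters
    out["cluster_name"] = [CLUSTER_NAMES[c] for c in clusters]
    return out


def cluster_percentages(profiles: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-condition cluster fractions, percentages ceiling-rounded.

    Fractions are over assigned proteins only and sum to 1 before
    rounding; the reported integer percentages follow the round-up
    convention (51/50 rather than 50/50 for 0.501/0.499).
    """
    out: dict[str, dict[str, float]] = {}
    for condition, sub in profiles.groupby("condition"):
        assigned = sub.loc[sub["cluster"] > 0]
        if len(assigned) == 0:
            continue
        entry: dict[str, float] = {"n_assigned": int(len(assigned)), "n_unassigned": int((sub["cluster"] == 0).sum())}
        for cid in (1, 2, 3, 4):
            frac = float((assigned["cluster"] == cid).sum()) / len(assigned)
            entry[f"cluster{cid}_fraction"] = frac
            entry[f"cluster{cid}_percent"] = int(math.ceil(frac * 100.0))
        out[str(condition)] = entry
    return out
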