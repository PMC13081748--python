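"""Reference-free heavy/light channel quantification from DIA precursor reports.

Processing chain (each step is an exported operation):

1. ``drop_contaminants``  — remove contaminant protein groups by id prefix.
2. ``pair_and_filter``    — group rows into H/L precursor pairs and apply the
   report-level quality filter (Global.PG.Q.Value < 0.01, Precursor.Charge > 1,
   Channel.Q.Value < 0.03, strict); a pair is kept only if BOTH channels pass,
   a single-channel precursor if its sole channel passes.
3. per-precursor log2(H/L) ratios from MS1.Translated and Precursor.Translated,
   pooled to a protein-group ratio per run by the median.
4. ``single_channel_mask`` — protein-run cells observed in one channel only
   get their whole abundance allocated to that channel.
5. ``total_protein_intensity`` — sum of Precursor.Quantity over surviving
   precursors (both channels).
6. ``normalize_totals``   — per-run scalar shift alignment in log2 space
   (sample-shift normalization, directLFQ-style contract).
7. ``split_total``        — normalized totals split into heavy and light by
   the protein-group ratio or the single-channel mask.

``build_channel_matrices`` runs the whole chain and returns protein x run
heavy / light / total matrices plus a processing log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import SampleKey
from .simulate import REPORT_COLUMNS

PAIR_KEY = ["Run", "Protein.Group", "Modified.Sequence", "Precursor.Charge"]

DEFAULT_PG_Q = 0.01
DEFAULT_CHANNEL_Q = 0.03
DEFAULT_MIN_CHARGE_EXCLUSIVE = 1


class DataIntegrityError(ValueError):
    """Raised when the input report violates its schema contract."""


class NormalizationError(ValueError):
    """Raised when runs cannot be aligned (no shared proteins)."""


@dataclass
class ChannelMatrices:
    """Protein x run heavy/light/total abundance matrices (NaN = missing)."""

    heavy: pd.DataFrame
    light: pd.DataFrame
    total: pd.DataFrame
    log: dict = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return list(self.total.index)

    @property
    def runs(self) -> list[str]:
        return list(self.total.columns)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, mat in (("heavy", self.heavy), ("light", self.light), ("total", self.total)):
            mat.rename_axis("Protein.Group").to_csv(outdir / f"{name}.tsv", sep="\t")
        (outdir / "processing_log.json").write_text(json.dumps(self.log, indent=2))

    @classmethod
    def read(cls, outdir: str | Path) -> "ChannelMatrices":
        outdir = Path(outdir)
        mats = {
            name: pd.read_csv(outdir / f"{name}.tsv", sep="\t", index_col="Protein.Group")
            for name in ("heavy", "light", "total")
        }
        log_path = outdir / "processing_log.json"
        log = json.loads(log_path.read_text()) if log_path.exists() else {}
        return cls(heavy=mats["heavy"], light=mats["light"], total=mats["total"], log=log)


def drop_contaminants(report: pd.DataFrame, contaminant_prefix: str = "Cont_") -> tuple[pd.DataFrame, int]:
    """Remove rows whose protein group starts with the contaminant prefix."""
    is_cont = report["Protein.Group"].astype(str).str.startswith(contaminant_prefix)
    n_removed = int(is_cont.sum())
    return report.loc[~is_cont].reset_index(drop=True), n_removed


def _row_passes(report: pd.DataFrame, pg_q: float, channel_q: float, min_charge_exclusive: int) -> pd.Series:
    return (
        (report["Global.PG.Q.Value"] < pg_q)
        & (report["Precursor.Charge"] > min_charge_exclusive)
        & (report["Channel.Q.Value"] < channel_q)
    )


def pair_and_filter(
    report: pd.DataFrame,
    pg_q: float = DEFAULT_PG_Q,
    channel_q: float = DEFAULT_CHANNEL_Q,
    min_charge_exclusive: int = DEFAULT_MIN_CHARGE_EXCLUSIVE,
) -> tuple[pd.DataFrame, dict]:
    """Pair heavy/light precursor rows and apply the quality filter.

    Returns a wide table with one row per surviving
    (run, protein group, sequence, charge): intensity columns for each
    channel (NaN where the channel is absent) and ``is_pair``. A pair is
    kept only if both channels satisfy every criterion; a single-channel
    precursor if its channel does. Duplicate rows for one key + channel
    raise :class:`DataIntegrityError`.
    """
    counts = {"input_rows": int(len(report))}
    if len(report) == 0:
        empty = pd.DataFrame(
            columns=PAIR_KEY
            + ["L_ms1", "L_ptr", "L_qty", "H_ms1", "H_ptr", "H_qty", "is_pair"]
        )
        counts.update({"pairs_kept": 0, "singles_kept": 0, "dropped": 0})
        return empty, counts

    dup = report.duplicated(subset=PAIR_KEY + ["Channel"], keep=False)
    if dup.any():
        offender = report.loc[dup, PAIR_KEY + ["Channel"]].iloc[0].to_dict()
        raise DataIntegrityError(f"duplicate precursor rows for {offender}")

    passes = _row_passes(report, pg_q, channel_q, min_charge_exclusive)
    work = report.assign(_pass=passes)
    wide = work.pivot(
        index=PAIR_KEY,
        columns="Channel",
        values=["MS1.Translated", "Precursor.Translated", "Precursor.Quantity", "_pass"],
    )

    def col(values: str, channel: str) -> pd.Series:
        if (values, channel) in wide.columns:
            return wide[(values, channel)].astype(float)
        return pd.Series(np.nan, index=wide.index)

    has_l = col("_pass", "L").notna()
    has_h = col("_pass", "H").notna()
    pass_l = col("_pass", "L") == 1.0
    pass_h = col("_pass", "H") == 1.0

    is_pair = has_l & has_h
    keep = (is_pair & pass_l & pass_h) | (has_l & ~has_h & pass_l) | (has_h & ~has_l & pass_h)

    out = pd.DataFrame(
        {
            "L_ms1": col("MS1.Translated", "L"),
            "L_ptr": col("Precursor.Translated", "L"),
            "L_qty": col("Precursor.Quantity", "L"),
            "H_ms1": col("MS1.Translated", "H"),
            "H_ptr": col("Precursor.Translated", "H"),
            "H_qty": col("Precursor.Quantity", "H"),
            "is_pair": is_pair,
        },
        index=wide.index,
    ).loc[keep].reset_index()
    counts["pairs_kept"] = int(out["is_pair"].sum())
    counts["singles_kept"] = int((~out["is_pair"]).sum())
    counts["dropped"] = int(len(wide) - len(out))
    return out, counts


def precursor_log2_ratios(pair: pd.Series | dict) -> list[float]:
    """log2(H/L) ratios of one paired precursor, one per quantity type.

    MS1.Translated and Precursor.Translated each contribute a ratio when
    both channels have positive signal of that type; 0-2 values result.
    """
    get = pair.get if isinstance(pair, dict) else pair.__getitem__
    for side in ("L", "H"):
        if all(pd.isna(get(f"{side}_{q}")) for q in ("ms1", "ptr", "qty")):
            raise ValueError("precursor_log2_ratios requires both channels present")
    out = []
    for q in ("ms1", "ptr"):
        h, l = get(f"H_{q}"), get(f"L_{q}")
        if pd.notna(h) and pd.notna(l) and h > 0 and l > 0:
            out.append(math.log2(h / l))
    return out


def proteingroup_ratio(ratios: Sequence[float]) -> float:
    """Protein-group log2(H/L) for one run: median of pooled precursor ratios."""
    if len(ratios) == 0:
        raise ValueError("no precursor ratios to aggregate")
    return float(np.median(ratios))


def protein_run_table(paired: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Roll paired precursors up to protein-run grain.

    Returns one row per (protein group, run): ``total`` (sum of
    Precursor.Quantity over both channels, paired and single), ``log2_ratio``
    (median of pooled per-precursor log2 H/L, NaN when maskless) and
    ``mask`` in {both, heavy_only, light_only}. Cells whose only evidence is
    a mix of heavy-only and light-only singles carry no ratio and no valid
    mask; they are dropped and counted.
    """
    if len(paired) == 0:
        return (
            pd.DataFrame(columns=["Protein.Group", "Run", "total", "log2_ratio", "mask"]),
            {"protein_runs": 0, "mask_both": 0, "mask_heavy_only": 0,
             "mask_light_only": 0, "dropped_mixed_singles": 0, "dropped_zero_total": 0},
        )
    work = paired.copy()
    # per-precursor ratios, vectorized over the two quantity types
    ratio_cols = []
    for q in ("ms1", "ptr"):
        h, l = work[f"H_{q}"], work[f"L_{q}"]
        valid = work["is_pair"] & h.notna() & l.notna() & (h > 0) & (l > 0)
        work[f"r_{q}"] = np.where(valid, np.log2(h.where(valid, 1.0) / l.where(valid, 1.0)), np.nan)
        ratio_cols.append(f"r_{q}")

    work["qty_sum"] = work[["L_qty", "H_qty"]].fillna(0.0).sum(axis=1)
    work["has_l"] = work[["L_ms1", "L_ptr", "L_qty"]].notna().any(axis=1)
    work["has_h"] = work[["H_ms1", "H_ptr", "H_qty"]].notna().any(axis=1)

    grouped = work.groupby(["Protein.Group", "Run"], sort=True)
    agg = grouped.agg(
        total=("qty_sum", "sum"),
        any_pair=("is_pair", "any"),
        any_l=("has_l", "any"),
        any_h=("has_h", "any"),
    )
    long = work.melt(
        id_vars=["Protein.Group", "Run"], value_vars=ratio_cols, value_name="r"
    ).dropna(subset=["r"])
    pooled = long.groupby(["Protein.Group", "Run"])["r"].median()
    agg["log2_ratio"] = pooled.reindex(agg.index)

    mask = np.select(
        [
            agg["any_pair"] & agg["log2_ratio"].notna(),
            agg["any_h"] & ~agg["any_l"],
            agg["any_l"] & ~agg["any_h"],
        ],
        ["both", "heavy_only", "light_only"],
        default="mixed",
    )
    agg["mask"] = mask
    counts = {
        "protein_runs": int(len(agg)),
        "mask_both": int((agg["mask"] == "both").sum()),
        "mask_heavy_only": int((agg["mask"] == "heavy_only").sum()),
        "mask_light_only": int((agg["mask"] == "light_only").sum()),
        "dropped_mixed_singles": int((agg["mask"] == "mixed").sum()),
        "dropped_zero_total": int(((agg["mask"] != "mixed") & (agg["total"] <= 0)).sum()),
    }
    agg = agg.loc[(agg["mask"] != "mixed") & (agg["total"] > 0)]
    agg.loc[agg["mask"] != "both", "log2_ratio"] = np.nan
    out = agg.reset_index()[["Protein.Group", "Run", "total", "log2_ratio", "mask"]]
    return out, counts


def single_channel_mask(paired: pd.DataFrame) -> pd.DataFrame:
    """Mask label per (protein group, run): both / heavy_only / light_only."""
    table, _ = protein_run_table(paired)
    return table[["Protein.Group", "Run", "mask"]]


def total_protein_intensity(group: pd.DataFrame) -> float:
    """Summed Precursor.Quantity (both channels) for one protein in one run.

    Returns NaN when every surviving quantity is zero or absent (the cell
    is recorded as missing).
    """
    total = float(group[["L_qty", "H_qty"]].fillna(0.0).to_numpy().sum())
    return total if total > 0 else float("nan")


def normalize_totals(total: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sample-shift normalization of the total-intensity matrix.

    Each run's log2 totals are shifted by one scalar. Raw shifts are the
    median log2 difference to the lexicographically first run over shared
    proteins; the run whose raw shift is the median of all raw shifts
    anchors the scale (its shift is 0), so within-run ratios are exactly
    preserved and re-normalizing is a no-op.
    """
    if total.shape[1] < 2:
        raise NormalizationError("normalization requires at least 2 runs")
    log_mat = np.log2(total.where(total > 0))
    runs = sorted(total.columns)
    ref0 = runs[0]
    raw = {}
    for run in runs:
        shared = log_mat[run] - log_mat[ref0]
        shared = shared.dropna()
        if len(shared) == 0:
            raise NormalizationError(f"run {run!r} shares no proteins with run {ref0!r}")
        raw[run] = float(shared.median())
    med = float(np.median(list(raw.values())))
    anchor = min(runs, key=lambda r: (abs(raw[r] - med), r))
    shifts = {run: raw[run] - raw[anchor] for run in runs}
    factors = pd.Series({run: 2.0 ** -shifts[run] for run in total.columns})
    normalized = total.mul(factors, axis=1)
    return normalized, shifts


def split_total(total: float, log2_ratio: float, mask: str) -> tuple[float, float]:
    """Split one normalized total into (heavy, light) by ratio or mask."""
    if mask == "heavy_only":
        return total, float("nan")
    if mask == "light_only":
        return float("nan"), total
    if mask == "both":
        if not np.isfinite(log2_ratio):
            raise DataIntegrityError("mask=both requires a finite log2 ratio")
        light = total / (1.0 + 2.0 ** log2_ratio)
        return total - light, light
    raise ValueError(f"unknown mask {mask!r}")


def build_channel_matrices(
    report: pd.DataFrame,
    design: Sequence[SampleKey],
    contaminant_prefix: str = "Cont_",
    pg_q: float = DEFAULT_PG_Q,
    channel_q: float = DEFAULT_CHANNEL_Q,
    min_charge_exclusive: int = DEFAULT_MIN_CHARGE_EXCLUSIVE,
    normalize: bool = True,
) -> ChannelMatrices:
    """Run the full quantification chain on a precursor report.

    contaminant removal -> pairing/filter -> ratio rollup + mask -> totals
    -> per-run shift normalization -> heavy/light split. Matrix columns
    follow the design's run order; rows are sorted protein groups.
    """
    log: dict = {}
    report, n_cont = drop_contaminants(report, contaminant_prefix)
    log["contaminant_rows_removed"] = n_cont
    paired, filter_counts = pair_and_filter(report, pg_q, channel_q, min_charge_exclusive)
    log["filter"] = filter_counts
    table, rollup_counts = protein_run_table(paired)
    log["rollup"] = rollup_counts

    run_order = [k.run_id for k in design]
    unknown = set(table["Run"]) - set(run_order)
    if unknown:
        raise DataIntegrityError(f"report contains runs absent from the design: {sorted(unknown)}")

    total = table.pivot(index="Protein.Group", columns="Run", values="total").reindex(columns=run_order)
    total = total.sort_index()
    if normalize:
        total, shifts = normalize_totals(total)
        log["normalization_shifts"] = shifts
    else:
        log["normalization_shifts"] = {run: 0.0 for run in run_order}

    ratio = table.pivot(index="Protein.Group", columns="Run", values="log2_ratio").reindex(
        index=total.index, columns=run_order
    )
    mask = table.pivot(index="Protein.Group", columns="Run", values="mask").reindex(
        index=total.index, columns=run_order
    )

    tot = total.to_numpy(dtype=float)
    rho = ratio.to_numpy(dtype=float)
    msk = mask.to_numpy(dtype=object)
    with np.errstate(over="ignore"):
        frac_light = 1.0 / (1.0 + 2.0 ** rho)
    light = np.where(msk == "both", tot * frac_light, np.nan)
    heavy = np.where(msk == "both", tot - tot * frac_light, np.nan)
    light = np.where(msk == "light_only", tot, light)
    heavy = np.where(msk == "heavy_only", tot, heavy)
    # reconstitute the total from the split parts so that conservation
    # (heavy + light = total) holds exactly, not merely to rounding
    tot = np.where(msk == "both", heavy + light, tot)

    heavy_df = pd.DataFrame(heavy, index=total.index, columns=total.columns)
    light_df = pd.DataFrame(light, index=total.index, columns=total.columns)
    total = pd.DataFrame(tot, index=total.index, columns=total.columns)
    log["n_proteins"] = int(total.shape[0])
    log["n_runs"] = int(total.shape[1])
    return ChannelMatrices(heavy=heavy_df, light=light_df, total=total, log=log)
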