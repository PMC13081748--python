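"""Synthetic dynamic-SILAC precursor reports with known turnover kinetics.

The generator emits DIA-NN-dialect precursor tables (one row per
precursor x channel x run) for a pulse-labeling design in which cells
switch from light (K0/R0) to heavy (K8/R10) medium at t = 0. Each
protein follows first-order degradation and zero-order synthesis:

    light(t) = A0 * exp(-k_deg * t)
    heavy(t) = (k_syn / k_deg) * (1 - exp(-k_deg * t))

so the light channel reports the decay of the preexisting pool and the
heavy channel the accumulation of newly made protein. Under atrophy both
rates are scaled by per-protein multipliers. A proteolysis inhibitor
administered for the final 3 h before harvest suspends degradation of
that pathway's substrates over the window (synthesis continues), which
is what makes substrates accumulate in the light channel relative to
vehicle-treated runs.

Protein-level signal is split across precursors by fixed "flyability"
efficiencies, multiplied by log-normal noise per precursor x channel x
run and quantity type, censored below a hard intensity threshold (MNAR)
and thinned at random (MCAR). Everything is a pure function of the
inputs and one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import SampleKey

REPORT_COLUMNS = [
    "Run",
    "Protein.Group",
    "Modified.Sequence",
    "Precursor.Charge",
    "Channel",
    "Global.PG.Q.Value",
    "Channel.Q.Value",
    "MS1.Translated",
    "Precursor.Translated",
    "Precursor.Quantity",
]

TRUTH_COLUMNS = [
    "protein_id",
    "baseline_abundance",
    "k_deg",
    "k_syn",
    "atrophy_kdeg_mult",
    "atrophy_ksyn_mult",
    "substrate_of",
    "n_peptides",
    "peptide_efficiencies",
    "is_contaminant",
    "seed",
]

INHIBITOR_TARGETS = {"BafA1": "autophagy", "Lac": "proteasome"}
_AA = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth kinetic parameters for one simulated protein."""

    protein_id: str
    baseline_abundance: float
    k_deg: float  # per hour, first-order
    k_syn: float  # intensity units per hour, zero-order
    atrophy_kdeg_mult: float = 1.0
    atrophy_ksyn_mult: float = 1.0
    substrate_of: str = "none"  # none | autophagy | proteasome
    n_peptides: int = 3
    peptide_efficiencies: tuple[float, ...] = ()
    is_contaminant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_deg <= 0:
            raise ValueError("k_deg must be positive")
        if self.k_syn < 0:
            raise ValueError("k_syn must be non-negative")
        if self.baseline_abundance <= 0:
            raise ValueError("baseline_abundance must be positive")
        if self.substrate_of not in ("none", "autophagy", "proteasome"):
            raise ValueError(f"unknown substrate_of {self.substrate_of!r}")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        eff = self.peptide_efficiencies
        if not eff:
            object.__setattr__(
                self, "peptide_efficiencies", tuple([1.0 / self.n_peptides] * self.n_peptides)
            )
        else:
            if len(eff) != self.n_peptides:
                raise ValueError("peptide_efficiencies length must equal n_peptides")
            if any(e <= 0 for e in eff):
                raise ValueError("peptide_efficiencies must be positive")
            if abs(sum(eff) - 1.0) > 1e-9:
                raise ValueError("peptide_efficiencies must sum to 1")


def expected_channel_abundance(
    truth: SimulationTruth,
    sample: SampleKey,
    inhibitor_block: float = 1.0,
    inhibitor_window_h: float = 3.0,
) -> tuple[float, float]:
    """Noise-free (light, heavy) protein abundance for one run.

    First-order decay of the preexisting light pool, zero-order synthesis
    into the heavy pool. If the run's inhibitor targets this protein's
    degradative pathway, degradation is reduced by ``inhibitor_block``
    (1.0 = complete suspension) for the final ``inhibitor_window_h`` hours
    before harvest; synthesis continues through the window.
    """
    t = float(sample.time_h)
    if t < 0:
        raise ValueError("time must be non-negative")
    k = truth.k_deg
    s = truth.k_syn
    if sample.condition == "atrophy":
        k *= truth.atrophy_kdeg_mult
        s *= truth.atrophy_ksyn_mult

    inhibited = (
        sample.inhibitor != "none"
        and INHIBITOR_TARGETS.get(sample.inhibitor) == truth.substrate_of
    )
    w = min(inhibitor_window_h, t) if inhibited else 0.0
    k_win = k * (1.0 - inhibitor_block)  # residual degradation during the block

    # phase 1: 0 .. t-w at rate k; phase 2: t-w .. t at rate k_win
    light = truth.baseline_abundance * math.exp(-k * (t - w)) * math.exp(-k_win * w)
    heavy = (s / k) * (1.0 - math.exp(-k * (t - w))) if t > w else 0.0
    if w > 0:
        if k_win > 0:
            heavy = heavy * math.exp(-k_win * w) + (s / k_win) * (1.0 - math.exp(-k_win * w))
        else:
            heavy = heavy + s * w
    return max(light, 0.0), max(heavy, 0.0)


def make_truths(
    n_proteins: int,
    seed: int,
    n_autophagy_substrates: int = 0,
    n_proteasome_substrates: int = 0,
    n_contaminants: int = 0,
    frac_atrophy_regulated: float = 0.2,
    half_life_range_h: tuple[float, float] = (12.0, 96.0),
    substrate_half_life_range_h: tuple[float, float] = (2.0, 4.0),
    baseline_log10_mean: float = 6.0,
    baseline_log10_sd: float = 0.5,
    n_peptides_range: tuple[int, int] = (2, 5),
    contaminant_prefix: str = "Cont_",
) -> list[SimulationTruth]:
    """Draw a ground-truth protein panel.

    Half-lives are log-uniform (typical mammalian proteome spread);
    pathway substrates are short-lived so a 3 h degradation block is
    visible. Synthesis defaults to flux balance (k_syn = A0 * k_deg,
    constant total) with atrophy multipliers perturbing a subset of
    proteins in either direction.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    n_special = n_autophagy_substrates + n_proteasome_substrates + n_contaminants
    if n_special > n_proteins:
        raise ValueError("substrate/contaminant counts exceed n_proteins")
    rng = np.random.default_rng(seed)
    roles = (
        ["autophagy"] * n_autophagy_substrates
        + ["proteasome"] * n_proteasome_substrates
        + ["contaminant"] * n_contaminants
        + ["none"] * (n_proteins - n_special)
    )
    truths = []
    for i, role in enumerate(roles):
        is_cont = role == "contaminant"
        lo, hi = substrate_half_life_range_h if role in ("autophagy", "proteasome") else half_life_range_h
        half_life = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        k_deg = math.log(2.0) / half_life
        a0 = 10.0 ** rng.normal(baseline_log10_mean, baseline_log10_sd)
        kd_mult = ks_mult = 1.0
        if rng.random() < frac_atrophy_regulated:
            # atrophy perturbs turnover up or down ~1.5-2.5x
            kd_mult = float(math.exp(rng.uniform(math.log(1.5), math.log(2.5)))) if rng.random() < 0.5 else 1.0
            ks_mult = float(math.exp(rng.uniform(-math.log(2.5), math.log(2.5))))
        npep = int(rng.integers(n_peptides_range[0], n_peptides_range[1] + 1))
        raw = rng.dirichlet(np.full(npep, 4.0))
        eff = tuple((raw / raw.sum()).tolist())
        pid = f"{contaminant_prefix}P{i:04d}" if is_cont else f"P{i:04d}"
        truths.append(
            SimulationTruth(
                protein_id=pid,
                baseline_abundance=a0,
                k_deg=k_deg,
                k_syn=a0 * k_deg,
                atrophy_kdeg_mult=kd_mult,
                atrophy_ksyn_mult=ks_mult,
                substrate_of=role if role in ("autophagy", "proteasome") else "none",
                n_peptides=npep,
                peptide_efficiencies=eff,
                is_contaminant=is_cont,
                seed=seed,
            )
        )
    return truths


def _peptide_table(truths: Sequence[SimulationTruth], rng: np.random.Generator, charge1_rate: float) -> pd.DataFrame:
    """One row per (protein, precursor): sequence, charge, efficiency."""
    rows = []
    for truth in truths:
        for j, eff in enumerate(truth.peptide_efficiencies):
            length = int(rng.integers(8, 16))
            seq = "".join(rng.choice(_AA, size=length)) + ("K" if rng.random() < 0.5 else "R")
            charge = 1 if rng.random() < charge1_rate else int(rng.integers(2, 4))
            rows.append((truth.protein_id, seq, charge, eff))
    return pd.DataFrame(rows, columns=["protein_group", "modified_sequence", "precursor_charge", "efficiency"])


def simulate_report(
    truths: Sequence[SimulationTruth],
    design: Sequence[SampleKey],
    noise_cv: float = 0.1,
    mnar_threshold: float = 0.0,
    mcar_rate: float = 0.0,
    seed: int = 0,
    qvalue_fail_rate: float = 0.02,
    charge1_rate: float = 0.08,
    inhibitor_block: float = 1.0,
    inhibitor_window_h: float = 3.0,
    t0_emit_heavy: bool = False,
) -> pd.DataFrame:
    """Simulate a channel-resolved precursor report for a full design.

    Returns a table in DIA-NN report dialect (``REPORT_COLUMNS``). Zero
    expected signal (e.g. heavy at t0) yields no row rather than a
    fabricated 0 unless ``t0_emit_heavy`` forces explicit zero heavy rows
    at baseline. Identical arguments and seed give identical output.
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    if not design:
        raise ValueError("design must be non-empty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not 0 <= mcar_rate < 1:
        raise ValueError("mcar_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    peptides = _peptide_table(truths, rng, charge1_rate)
    n_pep = len(peptides)
    pep_protein_idx = np.repeat(np.arange(len(truths)), [t.n_peptides for t in truths])
    efficiency = peptides["efficiency"].to_numpy()

    # expected protein-level abundance per (protein, run, channel)
    light = np.empty((len(truths), len(design)))
    heavy = np.empty((len(truths), len(design)))
    for i, truth in enumerate(truths):
        for r, sample in enumerate(design):
            light[i, r], heavy[i, r] = expected_channel_abundance(
                truth, sample, inhibitor_block, inhibitor_window_h
            )

    frames = []
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    for channel, expected in (("L", light), ("H", heavy)):
        # (n_pep, n_runs) expected precursor signal
        exp_pep = expected[pep_protein_idx, :] * efficiency[:, None]
        if sigma > 0:
            # independent draw per quantity type; mean-one multiplicative noise
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(3, n_pep, len(design))))
        else:
            noise = np.ones((3, n_pep, len(design)))
        ms1 = exp_pep * noise[0]
        ptr = exp_pep * noise[1]
        qty = exp_pep * noise[2]
        frame = pd.DataFrame(
            {
                "Run": np.tile([s.run_id for s in design], n_pep),
                "Protein.Group": np.repeat(peptides["protein_group"].to_numpy(), len(design)),
                "Modified.Sequence": np.repeat(peptides["modified_sequence"].to_numpy(), len(design)),
                "Precursor.Charge": np.repeat(peptides["precursor_charge"].to_numpy(), len(design)),
                "Channel": channel,
                "MS1.Translated": ms1.ravel(),
                "Precursor.Translated": ptr.ravel(),
                "Precursor.Quantity": qty.ravel(),
                "_expected": exp_pep.ravel(),
                "_pep": np.repeat(np.arange(n_pep), len(design)),
            }
        )
        frames.append(frame)
    report = pd.concat(frames, ignore_index=True)

    # zero expected signal -> absent row, not fabricated zero
    keep = report["_expected"] > 0
    if t0_emit_heavy:
        t0_runs = {s.run_id for s in design if s.time_h == 0}
        keep |= (report["Channel"] == "H") & report["Run"].isin(t0_runs)
    report = report.loc[keep].drop(columns="_expected").reset_index(drop=True)
    pep_index = report.pop("_pep").to_numpy()

    # q-values: a controllable fraction of rows violates the filter thresholds.
    # Failures are structured the way DIA q-values behave: a marginal
    # precursor x channel fails in every run, a protein-group q failure
    # knocks out a whole protein-run cell, and a small independent per-row
    # component remains.
    n = len(report)
    marginal = pd.Series(
        rng.random(n_pep * 2) < qvalue_fail_rate,
        index=pd.MultiIndex.from_product(
            [range(n_pep), ["L", "H"]], names=["pep", "ch"]
        ),
    )
    row_marginal = marginal.loc[list(zip(pep_index, report["Channel"]))].to_numpy()
    fail_ch = row_marginal | (rng.random(n) < qvalue_fail_rate / 5)

    pg_run_fail = pd.Series(
        rng.random(len(truths) * len(design)) < qvalue_fail_rate / 2,
        index=pd.MultiIndex.from_product(
            [[t.protein_id for t in truths], [s.run_id for s in design]],
            names=["pg", "run"],
        ),
    )
    fail_pg = pg_run_fail.loc[list(zip(report["Protein.Group"], report["Run"]))].to_numpy()

    report["Global.PG.Q.Value"] = np.where(
        fail_pg, rng.uniform(0.01, 0.05, n), rng.uniform(0.0, 0.0099, n)
    )
    report["Channel.Q.Value"] = np.where(
        fail_ch, rng.uniform(0.03, 0.2, n), rng.uniform(0.0, 0.0299, n)
    )

    # missingness: MNAR censoring below the detection floor, then MCAR
    observed = report["Precursor.Quantity"] >= mnar_threshold
    observed &= rng.random(n) >= mcar_rate
    report = report.loc[observed, REPORT_COLUMNS].reset_index(drop=True)
    return report


# -- text I/O ---------------------------------------------------------------

def write_report(report: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing:
        raise ValueError(f"report missing mandatory columns: {missing}")
    report.loc[:, REPORT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    report = pd.read_csv(path, sep="\t")
    missing = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing:
        raise ValueError(f"report missing mandatory columns: {missing}")
    report["Channel"] = report["Channel"].astype(str)
    return report.loc[:, REPORT_COLUMNS]


def write_truths(truths: Sequence[SimulationTruth], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "protein_id": [t.protein_id for t in truths],
            "baseline_abundance": [t.baseline_abundance for t in truths],
            "k_deg": [t.k_deg for t in truths],
            "k_syn": [t.k_syn for t in truths],
            "atrophy_kdeg_mult": [t.atrophy_kdeg_mult for t in truths],
            "atrophy_ksyn_mult": [t.atrophy_ksyn_mult for t in truths],
            "substrate_of": [t.substrate_of for t in truths],
            "n_peptides": [t.n_peptides for t in truths],
            "peptide_efficiencies": [";".join(f"{e:.12g}" for e in t.peptide_efficiencies) for t in truths],
            "is_contaminant": [t.is_contaminant for t in truths],
            "seed": [t.seed for t in truths],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_truths(path: str | Path) -> list[SimulationTruth]:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in TRUTH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"truth table missing columns: {missing}")
    out = []
    for row in frame.itertuples(index=False):
        eff = tuple(float(x) for x in str(row.peptide_efficiencies).split(";"))
        eff = tuple(e / sum(eff) for e in eff)  # absorb text round-trip error
        out.append(
            SimulationTruth(
                protein_id=str(row.protein_id),
                baseline_abundance=float(row.baseline_abundance),
                k_deg=float(row.k_deg),
                k_syn=float(row.k_syn),
                atrophy_kdeg_mult=float(row.atrophy_kdeg_mult),
                atrophy_ksyn_mult=float(row.atrophy_ksyn_mult),
                substrate_of=str(row.substrate_of),
                n_peptides=int(row.n_peptides),
                peptide_efficiencies=eff,
                is_contaminant=bool(row.is_contaminant),
                seed=int(row.seed),
            )
        )
    return out
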