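# silacflux

Dynamic-SILAC protein turnover analysis for DIA proteomics: reference-free
heavy/light channel quantification from DIA-NN-style precursor reports,
empirical-Bayes differential turnover statistics, rule-based turnover
classification, and four-way temporal intensity clustering — together with a
synthetic pulse-labeling data generator that carries known kinetic ground
truth, so every stage of the pipeline can be verified end to end.

## The problem

In a dynamic-SILAC pulse experiment, cells grown in light medium (K0/R0) are
switched to heavy medium (K8/R10) at t = 0. Every protein made after the
switch is heavy; the preexisting pool stays light. Sampling at t0/t24/t72,
with or without an atrophy stimulus (TNF-α) and with or without a 3 h
pre-harvest block of the autophagy-lysosome pathway (Bafilomycin A1) or the
proteasome (Lactacystin), turns one proteomics readout into three:

- **light channel** — decay of the preexisting pool (degradation),
- **heavy channel** — accumulation of newly synthesized protein,
- **light accumulation under an inhibitor** — which degradative pathway a
  protein is a substrate of.

The pipeline consumes channel-resolved DIA-NN precursor reports (columns
`Run`, `Protein.Group`, `Modified.Sequence`, `Precursor.Charge`, `Channel`,
`Global.PG.Q.Value`, `Channel.Q.Value`, `MS1.Translated`,
`Precursor.Translated`, `Precursor.Quantity`) and a run-design table.

## Method

1. **Quantification** (`silacflux.quantify`): contaminants removed; H/L
   precursor pairs kept only when *both* channels satisfy
   `Global.PG.Q.Value < 0.01`, `Precursor.Charge > 1`,
   `Channel.Q.Value < 0.03`; per-precursor log2(H/L) ratios from
   MS1.Translated and Precursor.Translated are pooled to a protein-group
   ratio ρ per run by the median; protein-run cells seen in one channel only
   get a single-channel mask; totals are the summed `Precursor.Quantity` of
   both channels, aligned across runs by a per-run scalar shift in log2
   space (sample-shift normalization), and split into heavy and light as
   H = T·2^ρ/(1+2^ρ), L = T/(1+2^ρ) (or allocated entirely to the masked
   channel). Heavy + light = total holds exactly in every dual-channel cell.
2. **Statistics** (`silacflux.stats`): per protein, a one-factor linear
   model over the experimental groups; residual variances shrunk toward a
   scaled inverse-chi-square prior fitted by method of moments on
   log-variances (intensity trend and outlier-robust winsorization
   optional, both on by default); moderated t per contrast and an omnibus
   moderated F with d0 + df degrees of freedom; Benjamini–Hochberg
   adjustment per contrast. Calls: **degraded** (light, log2FC < 0,
   adj. p < 0.05), **synthesized** (heavy, log2FC > 0, adj. p < 0.05),
   **accumulated** (light, inhibitor or atrophy contrast, log2FC > 0,
   adj. p < 0.05).
3. **Clustering** (`silacflux.clusters`): replicate-averaged total
   intensities at t0/t24/t72 assigned to increasing(1) / constant(2) /
   intermittent(3) / decreasing(4) trajectories with a 10 % tolerance of
   the per-protein maximum change Δ_max.
4. **Simulation** (`silacflux.simulate`): first-order degradation,
   zero-order synthesis — light(t) = A₀e^(−k·t),
   heavy(t) = (s/k)(1 − e^(−k·t)) — with atrophy rate multipliers,
   inhibitor-suspended degradation over the final 3 h for pathway
   substrates, peptide-level signal splitting, log-normal noise, MNAR
   censoring and MCAR dropout, emitted in the DIA-NN report dialect.

## Worked example

```python
import silacflux as sf
import silacflux.stats as st

design = sf.make_design(3, include_inhibitors=True)          # 39 runs
truths = sf.make_truths(200, seed=1, n_autophagy_substrates=20,
                        n_proteasome_substrates=20, n_contaminants=5)
report = sf.simulate_report(truths, design, seed=1)
print(f"report rows: {len(report)}, runs: {len(design)}")

matrices = sf.build_channel_matrices(report, design)
print("filter counts:", matrices.log["filter"])

contrasts = [
    st.ContrastSpec("H72_vs_H24_light", "light", "H72_none", "H24_none", "turnover"),
    st.ContrastSpec("H72_vs_H24_heavy", "heavy", "H72_none", "H24_none", "turnover"),
    st.ContrastSpec("H24_BafA1_vs_none_light", "light", "H24_BafA1", "H24_none", "accumulation"),
]
results = st.run_contrasts(
    {"heavy": matrices.heavy, "light": matrices.light, "total": matrices.total},
    design, contrasts,
)
for name, res in results.items():
    print(name, dict(res["call"].value_counts()))
```

prints

```
report rows: 52050, runs: 39
filter counts: {'input_rows': 50550, 'pairs_kept': 21430, 'singles_kept': 1816, 'dropped': 3040}
H72_vs_H24_light {'degraded': 180}
H72_vs_H24_heavy {'not_significant': 107, 'synthesized': 76}
H24_BafA1_vs_none_light {'not_significant': 163, 'accumulated': 17}
```

All 180 tested proteins are called degraded in the light channel between 24 h
and 72 h of chase — expected, since every preexisting protein decays and two
extra days of chase are highly detectable; 76 proteins accumulate
significantly in the heavy channel; and 17 proteins accumulate in the light
channel when autophagy is blocked for 3 h — these recover the simulated
short-lived autophagy substrates (20 seeded, of which the short-half-life
ones at 24 h are detectable), with no false substrate calls at this seed.

The same chain is available from the shell:

```bash
silacflux all --out run1 --seed 1      # simulate → quantify → stats → cluster → report
silacflux quantify --report report.tsv --design design.tsv --out out/
```

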