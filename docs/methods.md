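# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `silacflux`. It is written for users deciding whether the
defaults fit their data and for maintainers changing them.

## Kinetic model of the pulse experiment

Each protein is modeled with first-order degradation (rate `k_deg`, h⁻¹) and
zero-order synthesis (rate `k_syn`, intensity units·h⁻¹). After the switch
to heavy medium at t = 0,

    light(t) = A0 · exp(−k_deg · t)
    heavy(t) = (k_syn / k_deg) · (1 − exp(−k_deg · t))

with A0 the preexisting (light) pool. This is the minimal standard
turnover model for pulse labeling: the light channel is a pure decay curve,
the heavy channel relaxes toward the steady-state level `k_syn/k_deg`.
Under the atrophy condition both rates are scaled by per-protein
multipliers (`atrophy_kdeg_mult`, `atrophy_ksyn_mult`).

A proteolysis inhibitor given for the final 3 h before harvest suspends
degradation of that pathway's substrates over the window while synthesis
continues. The implementation integrates the two-phase ODE exactly: with
window w and block strength β (default 1.0 = complete suspension),

    light(t) = A0 · exp(−k(t−w)) · exp(−k(1−β)w)
    heavy(t) = heavy(t−w) · exp(−k(1−β)w) + accrual over w

where the accrual is `s·w` when β = 1 (pure zero-order build-up during the
block) and the usual relaxation term otherwise. The heavy channel therefore
gains the synthesis made during the block — a term that matters when
comparing inhibitor arms on the heavy channel, even though the headline
accumulation readout is the light channel.

Not modeled: amino-acid recycling / incomplete heavy incorporation,
cell division (dilution), delayed inhibitor action, chromatography or the
DIA search itself. The generator emits the report grain only.

## Synthetic-data generator: what it emulates and what it does not

The design is the full factorial {homeostatic, atrophy} × {24, 72 h} ×
{vehicle, BafA1, Lac} plus baseline t0 (homeostatic, vehicle — t0 is
harvested before the stimulus and the inhibitors exist), n = 3 replicates:
39 runs. t0 runs are emitted light-only by default (`t0_emit_heavy` writes
explicit zero heavy rows instead), since no pulse time has elapsed.

Protein-level signal is split across 2–5 precursors by fixed Dirichlet
"flyability" efficiencies summing to 1. Noise is multiplicative log-normal
with mean 1, drawn independently per precursor × channel × run × quantity
type (MS1.Translated, Precursor.Translated, Precursor.Quantity each get
their own draw, so the two ratio estimates per precursor are genuinely
distinct observations).

Default parameter choices, with reasoning:

- `noise_cv = 0.1` — a 10 % precursor-level CV, typical technical quality
  for modern DIA quantification.
- half-lives log-uniform on 12–96 h for bulk proteins (the broad middle of
  mammalian proteome turnover); 2–4 h for pathway substrates. Substrates
  must be short-lived for a 3 h degradation block to produce a visible
  light-channel excess (the effect is exactly `exp(3·k_deg)`, i.e.
  log2FC = 3·k_deg/ln 2 ≈ 0.75–1.5 for these half-lives); this mirrors the
  biology — it is precisely the strongly fluxed, short-lived cargo and
  receptor proteins whose accumulation a brief lysosomal block reveals.
- `k_syn = A0 · k_deg` (flux balance) as the baseline, so totals are
  stationary unless a condition perturbs synthesis or degradation;
  atrophy multipliers perturb ~20 % of proteins by 1.5–2.5×.
- q-values are drawn so that a configurable fraction of rows violates the
  filter thresholds, with the *structure* real DIA q-values have: a
  marginal precursor × channel fails in every run (ionization and
  interference are precursor properties), a failing Global.PG.Q.Value
  removes a whole protein-run cell, and a small independent per-row
  component (rate/5) remains. Row-independent failures would make the
  plain H+L total sums incomparable across runs in a way real, correlated
  q-values do not.
- Missingness: MNAR as a hard censoring threshold on intensity (default
  off; enable to exercise detection limits) plus MCAR row dropout
  (default 1 %). Both regimes occur in DIA data and together they exercise
  the ≥3-per-group observation filter.
- Real q-value *semantics* (error-rate calibration) are not modeled — only
  pass/fail of the printed thresholds is meaningful.

Consequently, passing tests demonstrate correct bookkeeping, estimator
behavior and statistical calibration under a faithful but idealized noise
model; they do not demonstrate robustness to interference, retention-time
drift, batch structure or label recycling, none of which the generator
produces.

## Channel quantification

Filtering is strict (`<`, `>`) exactly as configured: `Global.PG.Q.Value
< 0.01`, `Precursor.Charge > 1`, `Channel.Q.Value < 0.03`. A pair is kept
only when both channels pass; a pair with one failing channel is dropped
entirely; single-channel precursors are kept when their sole channel
passes and feed the mask path. Duplicate rows for the same
(run, protein group, sequence, charge, channel) are a hard data-integrity
error, not a warning.

Both MS1.Translated and Precursor.Translated contribute one log2(H/L)
observation per paired precursor (when both channels are positive for that
type); the protein-run ratio ρ is the median of the pooled observations.
Pooling is the least-assumptive combination rule; zero intensities are
treated as missing for ratios (log undefined) but contribute 0 to totals.

Mixed-evidence cells: if a protein has at least one true pair in a run, the
cell's mask is `both`, and single-channel precursors of that protein still
contribute their quantity to the total (it is real signal) but not to ρ.
A cell whose only evidence is a mixture of heavy-only *and* light-only
singles has no defined ratio and no single channel to allocate to; such
cells are dropped and counted in the processing log
(`dropped_mixed_singles`). They are vanishingly rare under realistic
missingness.

### Normalization

Totals are aligned across runs by one scalar shift per run in log2 space —
the sample-shift contract of intensity-based normalization tools, with the
trace-level machinery deliberately out of scope (the interface accepts any
replacement). Shifts are computed as the median log2 difference to the
lexicographically first run over shared proteins; the run whose raw shift
is the median of all raw shifts anchors the scale (its shift is defined as
0 and every other run's shift is measured relative to it). This anchoring
makes the operation *exactly* idempotent and leaves within-run ratios
untouched; when the data are consistent (one true scalar per run) the
recovered shifts equal the injected ones to numerical precision. A run
sharing no proteins with the reference run is a normalization error naming
the run. Ties in anchor choice break lexicographically.

Note a structural consequence of scalar-shift normalization on plain
summed totals: the surviving-precursor set must be stable across runs for
totals to be comparable. Precursor-correlated q-value failures (the
realistic case) preserve this; heavy random per-row dropout would not, and
no per-run scalar can repair it.

### Splitting

Normalized totals are split as L = T/(1+2^ρ), H = T − L, so H + L = T
*exactly* (the stored total of a dual-channel cell is reconstituted from
the parts to keep the identity exact in floating point, a ≤1-ulp
adjustment). Masked cells allocate the whole total to the observed channel
and leave the other missing.

## Differential statistics

Per channel, intensities are log2-transformed; the heavy matrix is
median-centered per run (column median 0) — light and total matrices rely
on the quantification-stage normalization. Proteins need ≥3 non-missing
values in every experimental group entering the analysis (group =
condition × time × inhibitor); the filter can be restricted to the groups a
contrast family actually references, which is what `run_contrasts` does.

The per-protein model is a one-factor layout: cell means, pooled residual
variance s² = RSS/df, df = n_obs − #groups with data. Variances are shrunk
toward a scaled inverse-chi-square prior (d0, s0²) fitted across proteins
by method of moments on e = log s² − ψ(df/2) + log(df/2):

    Var(e) − mean ψ′(df/2) = ψ′(d0/2)      →  d0 via trigamma inversion
    mean(e) = log s0² + log(d0/2) − ψ(d0/2) →  s0²

with s²_post = (d0·s0² + df·s²)/(d0 + df). When the moments imply no
excess spread, d0 = ∞ and s²_post = s0² (the arithmetic mean of the s²
when no trend is fitted). `trend=True` replaces the constant level with a
running median of e over mean log2 intensity (window = max(11, 10 % of n),
edge-padded), re-centered at the winsorized mean — the median of a
log-chi-square variable is offset from its mean, and without re-centering
the prior would be biased high and the tests conservative. `robust=True`
winsorizes e at ±3 scaled MADs before the moment fit, protecting d0 and
s0² from hypervariable outliers. Both are on by default. Degenerate
inputs: all-zero variances skip moderation with a warning; zero-df
proteins are excluded from the fit and reported `not_tested`.

Moderated t: log2FC/(s_post·√(1/n₁+1/n₂)) on d0 + df degrees of freedom
(normal limit when d0 = ∞). Moderated F: between-group mean square over
s²_post on (g−1, d0+df) (chi-square/df1 limit when d0 = ∞); for two groups
F = t². With d0 = 0 the machinery reduces exactly to the ordinary pooled
two-sample t — a limit the tests pin. The whole chain is additionally
cross-checked against Bioconductor limma's `eBayes` on a fixture (t, p,
F, s²_post, d0, s0² agree to ≤1e-6 relative).

p-values are BH-adjusted within each contrast × channel family
(`not_tested` proteins carry no p and are outside the family). Both the
pairwise moderated t (which drives the classification) and the omnibus F
are reported per protein; the classification follows the per-contrast
sign-and-significance rules with strict inequalities and α = 0.05 by
default.

## Temporal clusters

Profiles are replicate means of the normalized totals at t0/t24/t72 from
inhibitor-free runs; the shared t0 baseline (acquired before the stimulus)
serves both conditions. A protein missing any of the three time points is
`unassigned`.

Per profile, Δ_max = max |pairwise change| among the three values and
τ = rel_tol·Δ_max (rel_tol = 0.10). Rule order is fixed:

1. **constant(2)** if Δ_max ≤ rel_tol · max(i0, i24, i72). The constancy
   test must normalize by the profile's own level: "Δ_max ≤ 0.1·Δ_max" is
   vacuous, so total excursion relative to the profile maximum is the
   interpretation adopted (flagged prominently because it is an
   interpretation, not the only conceivable one).
2. **increasing(1)** if i0 < i24 − τ and i24 < i72 + τ and i72 > i0: the
   first step must rise beyond tolerance; the second may dip within it.
3. **decreasing(4)**: mirror image.
4. **intermittent(3)** if |i72 − i0| ≤ τ and |i24 − i0| > τ: an excursion
   at t24 returning to baseline.
5. otherwise **unassigned**.

Δ_max is per-protein, which makes the assignment scale-invariant
(property-tested); a dataset-wide Δ_max mode exists behind a flag for the
alternative reading but breaks scale invariance. Reported percentages are
ceiling-rounded; the underlying fractions sum to 1 over assigned proteins.

## Problem sizes and determinism

The verification battery (`scripts/acceptance.py`, ~15 s) uses: a
200-protein × 39-run synthetic experiment for conservation; 40 and 30
proteins for the noise-free and analytic checks; 1000 randomized cases per
brute-force oracle; 2000 proteins for the null type-I simulation; 20 × 1000
proteins for FDR/sensitivity; 5 × 150 proteins (30 substrates each) for
accumulation recovery. These sizes give stable estimates while keeping the
battery fast; they are not tuned to any particular outcome. Every stochastic
step flows from a single integer seed through `numpy.random.default_rng`;
identical seeds give byte-identical generator output.

Two statistical behaviors worth knowing: the type-I error of moderated
tests is slightly overdispersed relative to a pure binomial because all
tests share the estimated prior (a property of empirical-Bayes moderation,
not a defect); and the accumulation benchmark's sensitivity depends
directly on the substrate half-life / noise calibration documented above —
halve the effect or double the noise and no correct implementation would
recall 80 % of substrates after BH correction at n = 3.

## Known limitations

- The normalization stand-in preserves only per-run scale, not
  precursor-level trace structure; datasets with heavy uncorrelated
  precursor dropout will show inflated total-intensity variance.
- The min-observation filter interacts with MNAR censoring: short-lived
  proteins vanish from late light-channel groups by design, and contrasts
  touching those groups will report them `not_tested` rather than impute.
- BH is applied per contrast family; no cross-contrast hierarchy or
  global FDR is attempted.
- The cluster-2 normalization and the mixed-singles drop are documented
  interpretations of underspecified corners; both are logged at run time.
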