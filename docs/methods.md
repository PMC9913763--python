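# Methods

## Design and model

The pipeline analyses a factorial knockout design: four strains (control,
ΔatfA, ΔatfB, ΔatfAΔatfB) × two treatments (untreated, MSB) × replicates,
one scenario per cell type.  Both transcription factors are assumed to act
positively, so a dependent gene is *downregulated* when its regulator is
missing; dependence is decided from downregulation in two comparisons per
factor (single mutant vs control, and double mutant vs the other single
mutant), which suppresses misidentification relative to using either
comparison alone.  Mycelial and conidial data are never compared directly;
only transcriptomes differing in exactly one design feature are.

### Differential expression

Counts for one comparison *A vs B* (B the reference) are modelled per gene
as NB(mean = s·exp(β₀ + β_group [+ β_batch]), dispersion α) with a log
link.

- **Normalisation**: median-of-ratios size factors computed on the
  comparison's samples; requires at least one gene positive everywhere.
- **Dispersion**: per-gene method of moments, `α̂ = max(floor, (v − m)/m²)`
  with the grand mean `m` and the within-group variance `v` pooled across
  the two groups (floor 10⁻⁸).  With three replicates this estimate has
  only ~4 degrees of freedom, so it is moderated toward the 10–90%
  trimmed mean of all per-gene estimates with prior weight 10 df:
  `α = (df·α̂ + 10·ᾱ)/(df + 10)`.  Without moderation the Wald test is
  uncalibrated (measured type-I error ≈ 0.11 at nominal 0.05 with a normal
  reference) and any heavy-tailed correction destroys power.
- **Test**: Wald statistic on β_group referred to a t distribution on
  residual + prior (df + 10) degrees of freedom, the quasi-likelihood
  convention for moderated variance estimates.  Null simulations at the
  generator's default regime measure type-I error 0.045–0.052 at nominal
  0.05 across seeds.  `log2FC = β_group/ln 2`; BH adjustment runs within
  each comparison over tested genes.
- **Batch**: conidial scenarios add additive batch indicators to the
  design (two batches in the default layout), matching samples that
  originate from separate experiments.

### Regulation calls and the set algebra

A tested gene is called up if `log2FC > 1`, down if `log2FC < −1` — strict
inequalities, so a fold change of exactly ±1 is *not* regulated — gated by
the raw Wald p < 0.05.  The gate is deliberately the *unadjusted* p: the
call is a per-gene decision rule feeding a classification, and gating on a
BH-adjusted quantity would make each gene's category depend on how many
other genes happen to be regulated in the same comparison (measured on
synthetic data, a padj gate costs 10–35% recall in the partially
substituting categories at three replicates, while the raw-p gate keeps
precision above 0.95).  Both the padj gate and the pure fold-change rule
remain available (`gate_on="padj"`, `require_significance=False`).

The five primary sets of a condition and their literal derived formulas
(differences, intersections, unions up to Set26/Set27, plus the ⁺ mirrors
computed by identical algebra on the up-calls) are evaluated set-wise; the
per-gene category is equivalently the unique match of its 5-bit membership
pattern against a 9-entry decision table, and the equivalence of the two
routes over all 32 patterns is asserted in the tests.  Genes not tested in
a comparison (all-zero or non-converged) are absent from its sets — i.e.
treated as not regulated.

MSB-responsiveness: Set0/Set0⁺ use the control strain's MSB-vs-untreated
comparison; a union over all four strains is exposed separately
(`msb_responsive_union`) since "responsive in any strain" is also a useful
notion.  The default condition run computes the control comparison only.

### Enrichment and reporting

Group enrichment is the one-sided hypergeometric tail
P(X ≥ overlap) — identical to Fisher's exact test with alternative
"greater" — BH-adjusted across the groups of one call; raw p is kept in
the output because small curated group collections are conventionally read
at raw p < 0.05.  The universe defaults to all genes tested in the
condition.  Overlap percentages are rounded half-up to integers relative
to a declared reference set.  Condition summaries enforce the partition
invariants (|Set26| = ΣAA,AB,A/B,A-B breakdown; A-B sub-sets partition
Set25) and raise on violation.

## The synthetic generator

Each gene draws a class: one of the nine dependence categories, an MSB
response (up/down), or none.  A category fixes the strain mean multipliers
(control always high); the canonical level patterns are the unique
noiseless realisations of each category's membership bits under the strict
|log2FC| > 1 rule.  Counts are NB with mean
`baseline × strain multiplier × MSB multiplier × depth factor × batch
factor`.

Defaults, and why:

- `effect_multipliers` high/mid/low = 1 / 0.25 / 0.0625: adjacent log2 gaps
  of 2, clearing the threshold of 1 with margin in every designed contrast.
- `baseline_mean_log_range` = [10, 10⁴] expected counts at the reference
  depth of 10⁶ — typical bulk RNA-seq coverage; `mean_depth` rescales all
  means proportionally.
- `dispersion`: per-gene gamma(shape 2, mean 0.05), a realistic bulk
  dispersion spread; a scalar can be fixed instead (0 gives Poisson).
- `class_proportions`: AA dominates (8%), BB/AB/A/B/A-B2/A-B4 are moderate
  (0.5–1.2%), A-B1/A-B3/A-B5 rare (≤ 0.12%), MSB up/down 6%/8%, the rest
  unaffected — mirroring the observed relative abundances in this design,
  where the AtfA-only class is an order of magnitude larger than any
  joint-dependence class and the asymmetric-intermediate classes are
  nearly absent.
- `msb_effect` = 4: MSB-responsive genes shift 4-fold in all strains under
  treatment.
- batch factors (conidial scenario): per-gene log-normal(0, σ = 0.1)
  multipliers per batch.
- knockout markers: an *atfA*-like gene with zero mean in ΔatfA
  backgrounds and an *atfB*-like gene with zero mean in ΔatfB backgrounds
  and mid-level mean in the ΔatfA single mutant (the cross-regulation
  observed in this system).  Markers carry category "none" and are
  excluded from recovery scoring.

All draws come from one `numpy` generator seeded by `config.seed`, in a
fixed documented order, so identical configs give bitwise-identical
outputs.

**What the generator does not emulate**: read-level artifacts (alignment,
positional bias, multimapping), correlated co-regulation between genes,
treatment×strain interactions beyond the designed patterns, partial
knockdowns, or compositional distortions from extreme library imbalance.
Passing recovery tests therefore demonstrates that the inference machinery
is correct and well-calibrated under the declared generative model — not
that real-data set sizes would be reproduced, which additionally depend on
alignment and quantification specifics upstream of this pipeline.

## Numerical choices

- NB GLM fitted by vectorised IRLS sharing one design matrix across genes;
  convergence when the largest coefficient update falls below 10⁻¹² (so
  A-vs-B and B-vs-A fits agree to ~10⁻¹⁰ in log2FC), max 200 iterations;
  non-converged genes are flagged and excluded from calls.
- A weak ridge (λ = 0.05) on non-intercept coefficients keeps estimates
  and standard errors finite when a group is all zeros (the Wald statistic
  otherwise collapses); for typical genes the Fisher information exceeds λ
  by 3–4 orders of magnitude, so the bias is negligible.
- Linear predictors are clipped to ±50 before exponentiation.
- Degenerate inputs: genes all-zero in a comparison are `not_tested` and
  excluded from the BH denominator; genes zero in one group only are
  tested (finite fold change via the penalised fit; no pseudocounts touch
  the data); zero-variance genes get the dispersion floor.
- Ties/order: category sets are provably disjoint, so no tie-breaking is
  needed; a double assignment raises.

## Problem sizes

The test suite simulates up to 10,000 genes × 24 samples for end-to-end
recovery (seconds on one core thanks to the vectorised IRLS), 2,000 genes
for null calibration, and 20,000 for proportion checks; the analysis
drivers use 4,000 genes per scenario.  These sizes give multinomial and
Monte-Carlo errors well inside the asserted tolerances.

## Known limitations

- The DE engine is deliberately simplified: no empirical-Bayes dispersion
  trend by mean, no LFC shrinkage, no outlier replacement or independent
  filtering, so its per-gene results will not match DESeq2 bit-for-bit
  (agreement on simulated data is to ~0.1 median |Δlog2FC|).
- Dependence categories are purely observational set memberships; the
  pipeline makes no claim about direct vs indirect regulation (e.g. AtfA
  acting through *atfB* transcription) or heterodimer formation.
- With three replicates, genes whose informative contrast is mid-vs-low at
  baselines below ~30 counts are at the edge of detectability; the rare
  A-B classes are the first to lose recall.
- The RPKM denominator is the column sum of the supplied matrix, not an
  external mapped-read total.
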