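# atfdep

Transcription-factor dependence calling from factorial knockout RNA-seq.

## The problem

Two positively acting bZIP transcription factors — AtfA and AtfB in
*Aspergillus nidulans* — jointly shape the oxidative-stress transcriptome.
Given bulk RNA-seq counts for the factorial strain panel (control, ΔatfA,
ΔatfB, ΔatfAΔatfB) under two treatments (untreated, MSB-treated) and in two
cell types (mycelium, conidium), the question for each gene is *which
factor(s) it depends on, and how the two factors interact at that gene*:
does it need AtfA only (**AA**), AtfB only (**BB**), both with no
substitution (**AB**), either one (**A/B**), or both with partial
substitution (**A-B1–5**, distinguished by which single deletion is
stronger)?

`atfdep` implements the full inference pipeline for this design as a tested
library with a CLI, plus a synthetic-data generator with known ground truth
so every stage can be validated without any sequencing data.

## The method

1. **Differential expression.** For each ordered comparison *A vs B* a
   per-gene negative-binomial GLM with log link is fitted,
   `K_gs ~ NB(s_s · exp(β₀ + β_group + β_batch), α_g)`, with median-of-ratios
   size factors `s_s`, moment-based dispersions `α_g` moderated toward a
   global value, and a Wald test on `β_group`; `log2FC = β_group / ln 2`.
2. **Regulation calls.** A gene is *downregulated* if `log2FC < −1` and
   *upregulated* if `log2FC > 1` (strict), gated by the raw Wald p < 0.05
   to suppress low-information fold changes (gate configurable).
3. **Set algebra.** Five primary downregulated sets per condition —
   Set1 (ΔatfA vs control), Set2 (ΔatfB vs control), Set3 (ΔatfAΔatfB vs
   control, = Set13), Set11 (ΔatfAΔatfB vs ΔatfB), Set12 (ΔatfAΔatfB vs
   ΔatfA) — are combined by literal formulas, e.g.

   ```
   Set8  = (Set1 ∩ Set3) \ Set2        Set18 = (Set11 ∩ Set13) \ Set12
   Set21 = Set8 ∩ Set18   (AA)         Set23 = Set10 ∩ Set16   (AB)
   Set24 = Set20 ∩ Set6   (A/B)        Set25 = A-B1 ∪ … ∪ A-B5 (A-B)
   Set26 = Set21 ∪ Set23 ∪ Set24 ∪ Set25   (AtfA-dependent genes)
   Set27 = Set22 ∪ Set23 ∪ Set24 ∪ Set25   (AtfB-dependent genes)
   ```

   Each gene's five-bit membership pattern maps to at most one category;
   exactly 9 of the 32 patterns are categorisable.  Set0/Set0⁺ collect the
   MSB-responsive genes of the control strain, and every set has an
   upregulated mirror (Set1⁺ … Set27⁺).
4. **Enrichment and reporting.** One-sided Fisher (hypergeometric) tests of
   gene groups (GMT) within the dependent sets, MSB cross-tabulations, and
   per-condition summaries with cross-condition overlap tables.

## Worked example

```python
from atfdep import (SimConfig, simulate_experiment, run_condition,
                    evaluate_recovery, summarize_condition)

cfg = SimConfig(n_genes=2000, seed=1)            # 4 strains x 2 treatments x 3 reps
counts, samples, truth = simulate_experiment(cfg)
res = run_condition(counts, samples, "mycelium", "untreated")
summary = summarize_condition(res["system"], res["labels"],
                              universe=res["universe"], condition=res["condition"])
print("Set1 (down/up):", summary.primary_counts["Set1"][1], "/",
      summary.primary_counts["Set1"][0])
print("|Set26| =", summary.set26_total, summary.set26_breakdown)
rec = evaluate_recovery(truth, res["labels"])
agg = rec["aggregates"]["Set26"]
print("Set26 recovery: precision %.3f recall %.3f" % (agg["precision"], agg["recall"]))
```

prints

```
Set1 (down/up): 207 / 6
|Set26| = 218 {'AA': 157, 'AB': 17, 'A/B': 12, 'A-B1': 3, 'A-B2': 12, 'A-B3': 2, 'A-B4': 13, 'A-B5': 2}
Set26 recovery: precision 1.000 recall 0.995
```

i.e. 207 genes are downregulated by the *atfA* deletion in this simulated
mycelial condition, 218 genes are called AtfA-dependent with the per-category
breakdown shown, and against the generator's designed truth the call set has
perfect precision and 99.5% recall.

## The analysis

Numbered drivers under `analysis/` run the whole study on synthetic
scenarios (mycelium single-batch, conidium two-batch) and write their
tables under `results/`:

```sh
python analysis/01_simulate_experiments.py     # counts, samples, truth, GMT
python analysis/02_differential_expression.py  # DE per condition
python analysis/03_dependence_classification.py  # sets, categories, recovery
python analysis/04_enrichment.py               # Fisher enrichment, MSB crosstabs
python analysis/05_summary_tables.py           # summaries, overlap tables
```

The same stages are available as a CLI (`atfdep simulate | de | sets |
enrich | report | recover | run-all`); `atfdep run-all --outdir out --seed 1`
chains them deterministically.

## Layout

- `src/atfdep/` — library: `simulate` (ground-truth generator), `io`
  (TSV/GMT/GFF3, RPKM), `diffexpr` (NB GLM engine), `sets` (the set
  algebra), `enrichment`, `report`, `cli`.
- `analysis/` — narrative drivers; `tests/` — pytest suite;
  `docs/methods.md` — modelling choices and limitations.
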