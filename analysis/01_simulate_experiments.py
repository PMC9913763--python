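#!/usr/bin/env python
"""Generate the two synthetic scenarios the analysis runs on.

Mycelium: single batch.  Conidium: two batches with per-gene multiplicative
batch factors, emulating samples pooled from two separate experiments.
Both scenarios share the factorial design (4 strains x 2 treatments x 3
replicates) and the default dependence-class mix; the designed truth table
is written alongside the counts so later stages can score themselves.

Writes results/data/<scenario>/{counts,samples,truth,lengths}.tsv and a
truth-derived GMT of gene groups for the enrichment stage.
"""

from pathlib import Path

import numpy as np

from atfdep import SimConfig, simulate_experiment
from atfdep.io import write_counts, write_gene_lengths, write_gmt, write_sample_sheet
from atfdep.simulate import truth_gene_groups

OUT = Path("results/data")
SEED = 42
N_GENES = 4000

SCENARIOS = {
    "mycelium": SimConfig(n_genes=N_GENES, cell_type="mycelium", n_batches=1,
                          seed=SEED),
    "conidium": SimConfig(n_genes=N_GENES, cell_type="conidium", n_batches=2,
                          seed=SEED + 1),
}


def main() -> None:
    for name, cfg in SCENARIOS.items():
        counts, sheet, truth = simulate_experiment(cfg)
        out = OUT / name
        out.mkdir(parents=True, exist_ok=True)
        write_counts(counts, out / "counts.tsv")
        write_sample_sheet(sheet, out / "samples.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_gene_lengths(dict(zip(truth["gene_id"], truth["length_bp"])),
                           out / "lengths.tsv")
        write_gmt(truth_gene_groups(truth, rng=np.random.default_rng(cfg.seed + 1)),
                  out / "groups.gmt")
        designed = (truth["category"] != "none").sum()
        print(f"{name}: {counts.shape[0]} genes x {counts.shape[1]} samples, "
              f"{designed} genes with a designed dependence category "
              f"-> {out}")


if __name__ == "__main__":
    main()
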