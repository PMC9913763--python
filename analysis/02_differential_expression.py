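#!/usr/bin/env python
"""Differential expression for every condition of both scenarios.

For each (cell type, treatment) condition the five strain comparisons
feeding the set algebra are tested, plus the MSB-vs-untreated comparison in
the control strain (feeding Set0/Set0+).  Conidial comparisons include the
additive batch term.

Writes results/de/<scenario>_<treatment>/<comparison>.tsv.
"""

from pathlib import Path

from atfdep import diffexpr
from atfdep.io import TREATMENTS, read_counts, read_sample_sheet

DATA = Path("results/data")
OUT = Path("results/de")


def main() -> None:
    for scenario in ("mycelium", "conidium"):
        counts = read_counts(DATA / scenario / "counts.tsv")
        sheet = read_sample_sheet(DATA / scenario / "samples.tsv", counts)
        batch_adjusted = sheet["batch"].nunique() > 1
        for treatment in TREATMENTS:
            comparisons = diffexpr.condition_comparisons(
                scenario, treatment, batch_adjusted=batch_adjusted)
            comparisons.append(diffexpr.msb_comparison(
                "control", scenario, batch_adjusted=batch_adjusted))
            out = OUT / f"{scenario}_{treatment}"
            out.mkdir(parents=True, exist_ok=True)
            for cmp in comparisons:
                table = diffexpr.de_test(counts, sheet, cmp)
                table.to_csv(out / f"{cmp.label}.tsv", sep="\t")
                tested = table.loc[table["status"] == "tested"]
                n_reg = int(((tested["log2fc"].abs() > 1)
                             & (tested["p"] < 0.05)).sum())
                print(f"{scenario}/{treatment} {cmp.label}: "
                      f"{len(tested)} tested, {n_reg} regulated"
                      + (" (batch-adjusted)" if batch_adjusted else ""))


if __name__ == "__main__":
    main()
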