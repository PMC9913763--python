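#!/usr/bin/env python
"""Condition summaries and cross-condition overlaps.

Produces the study-style summary for every condition (primary set sizes,
dependent-set totals with per-category breakdowns, MSB cross-tabulation)
plus two overlap tables: untreated vs MSB within each cell type, and
mycelium vs conidium within each treatment (with percentages relative to
the mycelial sets).

Writes results/summary/{summaries.json,<overlap tables>.tsv}.
"""

import json
from pathlib import Path

import pandas as pd

from atfdep.io import TREATMENTS
from atfdep.report import cross_condition_overlaps, summarize_condition

SETS = Path("results/sets")
DATA = Path("results/data")
OUT = Path("results/summary")


def load_condition(cond):
    members = pd.read_csv(SETS / cond / "sets.tsv", sep="\t")
    system = {name: frozenset(sub["gene_id"])
              for name, sub in members.groupby("set_name")}
    for name in [f"Set{i}{s}" for i in range(28) for s in ("", "+")]:
        system.setdefault(name, frozenset())
    labels = pd.read_csv(SETS / cond / "categories.tsv", sep="\t")
    if labels.empty:
        labels = pd.DataFrame(columns=["gene_id", "category"])
    return system, labels


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    systems, summaries = {}, {}
    for scenario in ("mycelium", "conidium"):
        truth = pd.read_csv(DATA / scenario / "truth.tsv", sep="\t")
        universe = frozenset(truth["gene_id"])
        for treatment in TREATMENTS:
            cond = f"{scenario}_{treatment}"
            system, labels = load_condition(cond)
            systems[cond] = system
            summary = summarize_condition(system, labels, universe=universe,
                                          condition=cond)
            summaries[cond] = summary.to_dict()
            bd = ", ".join(f"{v} {k}" for k, v in summary.set26_breakdown.items())
            print(f"{cond}: Set1 {summary.primary_counts['Set1'][1]} down / "
                  f"{summary.primary_counts['Set1'][0]} up; "
                  f"|Set26|={summary.set26_total} ({bd}); "
                  f"|Set27|={summary.set27_total}")

    for scenario in ("mycelium", "conidium"):
        table = cross_condition_overlaps(systems[f"{scenario}_untreated"],
                                         systems[f"{scenario}_MSB"])
        table.to_csv(OUT / f"{scenario}_treatment_overlap.tsv", sep="\t",
                     index=False)
        row = table.set_index("set_name").loc["Set26"]
        print(f"{scenario} untreated-vs-MSB Set26 overlap: {row['overlap']} of "
              f"{row['n_a']} untreated genes")
    for treatment in TREATMENTS:
        table = cross_condition_overlaps(systems[f"mycelium_{treatment}"],
                                         systems[f"conidium_{treatment}"],
                                         percentages=True)
        table.to_csv(OUT / f"celltype_overlap_{treatment}.tsv", sep="\t",
                     index=False)

    with open(OUT / "summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=1, default=float)
    print(f"wrote condition summaries -> {OUT / 'summaries.json'}")


if __name__ == "__main__":
    main()
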