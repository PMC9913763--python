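#!/usr/bin/env python
"""Fisher enrichment of gene groups within the dependent sets.

The truth-derived GMT contains one group per designed category, the
aggregate AtfA-/AtfB-dependent groups and random negative-control groups.
In a working pipeline the called Set26 must be massively enriched for the
true AtfA-dependent group and show nothing for the random groups; the MSB
cross-tabulation reports how the dependent sets intersect the
MSB-responsive genes of the control strain.

Writes results/enrichment/<scenario>_<treatment>_<set>.tsv and
results/enrichment/msb_crosstabs.json.
"""

import json
from pathlib import Path

import pandas as pd

from atfdep.enrichment import fisher_enrichment, msb_crosstab
from atfdep.io import TREATMENTS, read_gmt

SETS = Path("results/sets")
DATA = Path("results/data")
OUT = Path("results/enrichment")


def load_system(path):
    members = pd.read_csv(path / "sets.tsv", sep="\t")
    return {name: frozenset(sub["gene_id"])
            for name, sub in members.groupby("set_name")}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    crosstabs = {}
    for scenario in ("mycelium", "conidium"):
        groups = read_gmt(DATA / scenario / "groups.gmt")
        truth = pd.read_csv(DATA / scenario / "truth.tsv", sep="\t")
        universe = frozenset(truth["gene_id"])
        for treatment in TREATMENTS:
            cond = f"{scenario}_{treatment}"
            system = load_system(SETS / cond)
            for set_name in ("Set26", "Set27"):
                query = system.get(set_name, frozenset())
                if not query:
                    continue
                res = fisher_enrichment(query, groups, universe)
                res.to_csv(OUT / f"{cond}_{set_name}.tsv", sep="\t", index=False)
                top = res.nsmallest(2, "p")[["group_name", "overlap", "p"]]
                hits = ", ".join(f"{r.group_name} (k={r.overlap}, p={r.p:.2e})"
                                 for r in top.itertuples())
                n_random_sig = int(res.loc[
                    res["group_name"].str.startswith("random"), "p"].lt(0.05).sum())
                print(f"{cond} {set_name}: top {hits}; "
                      f"{n_random_sig} random groups with p<0.05")
            crosstabs[cond] = {
                name: msb_crosstab(system.get(name, frozenset()),
                                   system.get("Set0", frozenset()),
                                   system.get("Set0+", frozenset()), universe)
                for name in ("Set26", "Set27")
            }
    with open(OUT / "msb_crosstabs.json", "w") as fh:
        json.dump(crosstabs, fh, indent=1, default=float)
    print(f"wrote MSB cross-tabulations -> {OUT / 'msb_crosstabs.json'}")


if __name__ == "__main__":
    main()
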