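"""End-to-end orchestration and Table-style condition summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import diffexpr, sets
from .enrichment import msb_crosstab, overlap_stats
from .io import STRAINS


def run_condition(counts: pd.DataFrame, sample_sheet: pd.DataFrame,
                  cell_type: str, treatment: str,
                  lfc_threshold: float = 1.0, alpha: float = 0.05,
                  require_significance: bool = True, gate_on: str = "p",
                  batch_adjusted: bool | None = None,
                  msb_strains: tuple[str, ...] = ("control",)) -> dict:
    """Run DE, regulation calling and the set algebra for one condition.

    ``batch_adjusted`` defaults to True when the sheet shows more than one
    batch for the cell type.  Returns a dict with the per-comparison DE
    tables, the long regulation table, the full set system, Set26/Set27 and
    the per-gene category labels.
    """
    ct_sheet = sample_sheet.loc[sample_sheet["cell_type"] == cell_type]
    if batch_adjusted is None:
        batch_adjusted = ct_sheet["batch"].nunique() > 1
    comparisons = diffexpr.condition_comparisons(cell_type, treatment,
                                                 batch_adjusted=batch_adjusted)
    comparisons += [diffexpr.msb_comparison(s, cell_type, batch_adjusted=batch_adjusted)
                    for s in msb_strains]
    de_tables = {c.label: diffexpr.de_test(counts, sample_sheet, c) for c in comparisons}
    regulation = pd.concat(
        [diffexpr.classify_regulated(t, lfc_threshold=lfc_threshold, alpha=alpha,
                                     require_significance=require_significance,
                                     gate_on=gate_on)
         for t in de_tables.values()],
        ignore_index=True,
    )
    system = sets.derive_sets(sets.build_primary_sets(regulation))
    set26, set27, labels = sets.dependent_sets(system)
    _, _, labels_up = sets.dependent_sets(system, direction="+")
    msb_any_down, msb_any_up = msb_responsive_union(regulation, msb_strains)
    return {
        "condition": f"{cell_type},{treatment}",
        "de": de_tables,
        "regulation": regulation,
        "system": system,
        "set26": set26,
        "set27": set27,
        "labels": labels,
        "labels_up": labels_up,
        "msb_any_down": msb_any_down,
        "msb_any_up": msb_any_up,
        "universe": frozenset(regulation["gene_id"].unique()),
    }


def msb_responsive_union(regulation: pd.DataFrame,
                         strains=STRAINS) -> tuple[frozenset, frozenset]:
    """MSB stress-responsive genes as the union over strains (down, up)."""
    down: frozenset = frozenset()
    up: frozenset = frozenset()
    for strain in strains:
        label = f"MSB_vs_untreated@{strain}"
        sub = regulation.loc[regulation["comparison"] == label]
        down |= frozenset(sub.loc[sub["call"] == "down", "gene_id"])
        up |= frozenset(sub.loc[sub["call"] == "up", "gene_id"])
    return down, up


@dataclass
class ConditionSummary:
    """Counts for one condition, mirroring the study's summary tables."""

    condition: str
    primary_counts: dict = field(default_factory=dict)  # SetN -> (n_up, n_down)
    set26_total: int = 0
    set26_breakdown: dict = field(default_factory=dict)
    set27_total: int = 0
    set27_breakdown: dict = field(default_factory=dict)
    set0_size: int = 0
    set0_plus_size: int = 0
    msb_crosstab_set26: dict = field(default_factory=dict)
    msb_crosstab_set27: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "primary_counts": {k: list(v) for k, v in self.primary_counts.items()},
            "set26": {"total": self.set26_total, "breakdown": self.set26_breakdown,
                      "msb": self.msb_crosstab_set26},
            "set27": {"total": self.set27_total, "breakdown": self.set27_breakdown,
                      "msb": self.msb_crosstab_set27},
            "set0": {"down": self.set0_size, "up": self.set0_plus_size},
        }


def summarize_condition(system: Mapping[str, frozenset], labels: pd.DataFrame,
                        universe=None, condition: str = "") -> ConditionSummary:
    """Build a condition summary; enforces the partition invariants.

    ``labels`` is the per-gene category table from the downregulated
    direction.  The Set26/Set27 totals must equal the sum of their category
    breakdowns; a mismatch signals a corrupted set system and raises.
    """
    breakdown = labels["category"].value_counts().to_dict()
    set26_breakdown = {c: breakdown.get(c, 0) for c in sets.SET26_CATEGORIES
                       if breakdown.get(c, 0)}
    set27_breakdown = {c: breakdown.get(c, 0) for c in sets.SET27_CATEGORIES
                       if breakdown.get(c, 0)}
    summary = ConditionSummary(
        condition=condition,
        primary_counts={
            name: (len(system[name + "+"]), len(system[name]))
            for name in ("Set1", "Set2", "Set3", "Set11", "Set12")
        },
        set26_total=len(system["Set26"]),
        set26_breakdown=set26_breakdown,
        set27_total=len(system["Set27"]),
        set27_breakdown=set27_breakdown,
        set0_size=len(system["Set0"]),
        set0_plus_size=len(system["Set0+"]),
    )
    for name, bd, total in (("Set26", set26_breakdown, summary.set26_total),
                            ("Set27", set27_breakdown, summary.set27_total)):
        if sum(bd.values()) != total:
            raise ValueError(
                f"{name} breakdown sums to {sum(bd.values())} but the set has "
                f"{total} members; the category partition is corrupted"
            )
    ab_total = sum(set26_breakdown.get(c, 0) for c in sets.AB_SUBCATEGORIES)
    if ab_total != len(system["Set25"]):
        raise ValueError("A-B sub-category counts do not sum to |Set25|")
    if universe:
        summary.msb_crosstab_set26 = msb_crosstab(
            system["Set26"], system["Set0"], system["Set0+"], universe)
        summary.msb_crosstab_set27 = msb_crosstab(
            system["Set27"], system["Set0"], system["Set0+"], universe)
    return summary


def cross_condition_overlaps(system_a: Mapping[str, frozenset],
                             system_b: Mapping[str, frozenset],
                             set_names=None,
                             percentages: bool = False) -> pd.DataFrame:
    """Per-set overlap between two conditions' systems.

    With ``percentages`` the overlap is also expressed relative to the size
    of the first system's set (the convention used when comparing cell
    types against the mycelial sets).
    """
    if set_names is None:
        set_names = [n for n in ("Set1", "Set1+", "Set2", "Set2+", "Set3", "Set3+",
                                 "Set0", "Set0+", "Set26", "Set27")
                     if n in system_a and n in system_b]
    rows = []
    for name in set_names:
        a, b = system_a[name], system_b[name]
        n, pct = overlap_stats(a, b, a)
        row = {"set_name": name, "n_a": len(a), "n_b": len(b), "overlap": n}
        if percentages:
            row["pct_of_a"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
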