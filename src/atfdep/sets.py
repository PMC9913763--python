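"""Gene-set algebra for AtfA/AtfB dependence calling.

A gene's behaviour across the factorial knockout design is summarised by its
membership in the downregulated gene sets of five strain comparisons:

====== =============================== ==========================
flag   comparison (numerator vs ref)   primary set
====== =============================== ==========================
s1     ``atfA_del`` vs ``control``     Set1
s2     ``atfB_del`` vs ``control``     Set2
s3     ``double_del`` vs ``control``   Set3 (= Set13)
s11    ``double_del`` vs ``atfB_del``  Set11
s12    ``double_del`` vs ``atfA_del``  Set12
====== =============================== ==========================

Derived sets Set4–Set10 and Set14–Set20 are unions/intersections/differences
of the primary sets; the dependence categories are intersections of derived
sets (e.g. AA genes = Set8 ∩ Set18).  Set26 collects all AtfA-dependent
genes, Set27 all AtfB-dependent genes.  Every set has an upregulated mirror
(``Set1+`` … ``Set27+``) computed from the up-calls with identical algebra.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

#: strain comparison labels, fixed across the pipeline
CMP_A_VS_C = "atfA_del_vs_control"
CMP_B_VS_C = "atfB_del_vs_control"
CMP_AB_VS_C = "double_del_vs_control"
CMP_AB_VS_B = "double_del_vs_atfB_del"
CMP_AB_VS_A = "double_del_vs_atfA_del"
CMP_MSB_CONTROL = "MSB_vs_untreated@control"

#: the five strain comparisons, in (s1, s2, s3, s11, s12) order
STRAIN_COMPARISONS = (CMP_A_VS_C, CMP_B_VS_C, CMP_AB_VS_C, CMP_AB_VS_B, CMP_AB_VS_A)

#: primary set names matching STRAIN_COMPARISONS order
PRIMARY_SETS = ("Set1", "Set2", "Set3", "Set11", "Set12")

CATEGORIES = ("AA", "BB", "AB", "A/B", "A-B1", "A-B2", "A-B3", "A-B4", "A-B5")
AB_SUBCATEGORIES = ("A-B1", "A-B2", "A-B3", "A-B4", "A-B5")

#: categories whose genes are AtfA-dependent (members of Set26) / AtfB-dependent (Set27)
SET26_CATEGORIES = ("AA", "AB", "A/B") + AB_SUBCATEGORIES
SET27_CATEGORIES = ("BB", "AB", "A/B") + AB_SUBCATEGORIES

#: (s1, s2, s3, s11, s12) membership pattern forced by each category's formula
CATEGORY_BITS: dict[str, tuple[int, int, int, int, int]] = {
    "AA": (1, 0, 1, 1, 0),
    "BB": (0, 1, 1, 0, 1),
    "AB": (1, 1, 1, 0, 0),
    "A/B": (0, 0, 1, 1, 1),
    "A-B1": (1, 1, 1, 1, 1),
    "A-B2": (1, 0, 1, 1, 1),
    "A-B3": (0, 1, 1, 1, 1),
    "A-B4": (1, 1, 1, 1, 0),
    "A-B5": (1, 1, 1, 0, 1),
}

_BITS_TO_CATEGORY = {bits: cat for cat, bits in CATEGORY_BITS.items()}


def assign_category(bits: tuple[int, int, int, int, int]) -> str:
    """Map a (s1, s2, s3, s11, s12) down-membership pattern to its category.

    Returns ``"none"`` for the 23 patterns that satisfy no category formula.
    """
    bits = tuple(int(b) for b in bits)
    if len(bits) != 5 or any(b not in (0, 1) for b in bits):
        raise ValueError(f"membership pattern must be five binary flags, got {bits!r}")
    return _BITS_TO_CATEGORY.get(bits, "none")


def build_primary_sets(
    regulation: pd.DataFrame,
    msb_comparison: str = CMP_MSB_CONTROL,
    strain_comparisons: Iterable[str] = STRAIN_COMPARISONS,
) -> dict[str, frozenset]:
    """Build Set0/Set0+ and the primary Set1/2/3/11/12 (and mirrors) from calls.

    Parameters
    ----------
    regulation
        Long table with columns ``gene_id``, ``comparison``, ``call`` where
        ``call`` is ``up``/``down``/``none``.  Genes not tested in a
        comparison are simply absent and end up in no set.
    msb_comparison
        Label of the MSB-vs-untreated comparison in the control strain,
        feeding Set0 (down) and ``Set0+`` (up).
    """
    required = {"gene_id", "comparison", "call"}
    if not required.issubset(regulation.columns):
        raise ValueError(f"regulation table needs columns {sorted(required)}")
    strain_comparisons = tuple(strain_comparisons)
    if len(strain_comparisons) != 5:
        raise ValueError("exactly five strain comparisons are required")
    have = set(regulation["comparison"].unique())
    missing = [c for c in (*strain_comparisons, msb_comparison) if c not in have]
    if missing:
        raise ValueError(f"missing comparisons in regulation table: {missing}")

    def _genes(comparison: str, call: str) -> frozenset:
        mask = (regulation["comparison"] == comparison) & (regulation["call"] == call)
        return frozenset(regulation.loc[mask, "gene_id"])

    system: dict[str, frozenset] = {
        "Set0": _genes(msb_comparison, "down"),
        "Set0+": _genes(msb_comparison, "up"),
    }
    for name, cmp_label in zip(PRIMARY_SETS, strain_comparisons):
        system[name] = _genes(cmp_label, "down")
        system[name + "+"] = _genes(cmp_label, "up")
    return system


def _derive_one_direction(s1, s2, s3, s11, s12) -> dict[str, frozenset]:
    s13 = s3
    out = {
        "Set4": s1 - (s2 | s3),
        "Set5": s2 - (s1 | s3),
        "Set6": s3 - (s1 | s2),
        "Set7": (s1 & s2) - s3,
        "Set8": (s1 & s3) - s2,
        "Set9": (s2 & s3) - s1,
        "Set10": s1 & s2 & s3,
        "Set13": s13,
        "Set14": s11 - (s12 | s13),
        "Set15": s12 - (s11 | s13),
        "Set16": s13 - (s11 | s12),
        "Set17": (s11 & s12) - s13,
        "Set18": (s11 & s13) - s12,
        "Set19": (s12 & s13) - s11,
        "Set20": s11 & s12 & s13,
    }
    return {k: frozenset(v) for k, v in out.items()}


def _category_sets(d: Mapping[str, frozenset]) -> dict[str, frozenset]:
    return {
        "AA": d["Set8"] & d["Set18"],
        "BB": d["Set9"] & d["Set19"],
        "AB": d["Set10"] & d["Set16"],
        "A/B": d["Set20"] & d["Set6"],
        # the five A-B sub-sets, in the defining order
        "A-B1": d["Set10"] & d["Set20"],
        "A-B2": d["Set8"] & d["Set20"],
        "A-B3": d["Set9"] & d["Set20"],
        "A-B4": d["Set18"] & d["Set10"],
        "A-B5": d["Set19"] & d["Set10"],
    }


def derive_sets(primary: Mapping[str, frozenset]) -> dict[str, frozenset]:
    """Extend a primary set system to the full Set0–Set27 system (plus mirrors).

    Every derived set is evaluated from its literal defining formula; the
    up-mirrors apply the identical algebra to the ``+`` primary sets.
    """
    for name in PRIMARY_SETS:
        if name not in primary:
            raise ValueError(f"primary set system is missing {name}")
    system = dict(primary)
    system.setdefault("Set0", frozenset())
    system.setdefault("Set0+", frozenset())
    for suffix in ("", "+"):
        prim = [frozenset(primary.get(n + suffix, frozenset())) for n in PRIMARY_SETS]
        derived = _derive_one_direction(*prim)
        cats = _category_sets(derived)
        derived["Set21"] = cats["AA"]
        derived["Set22"] = cats["BB"]
        derived["Set23"] = cats["AB"]
        derived["Set24"] = cats["A/B"]
        ab_union: frozenset = frozenset()
        for sub in AB_SUBCATEGORIES:
            ab_union |= cats[sub]
        derived["Set25"] = ab_union
        derived["Set26"] = cats["AA"] | cats["AB"] | cats["A/B"] | ab_union
        derived["Set27"] = cats["BB"] | cats["AB"] | cats["A/B"] | ab_union
        system.update({k + suffix: v for k, v in derived.items()})
    return system


def dependent_sets(
    system: Mapping[str, frozenset], direction: str = ""
) -> tuple[frozenset, frozenset, pd.DataFrame]:
    """Return (Set26, Set27, per-gene category labels) for one direction.

    ``direction`` is ``""`` for the downregulated system or ``"+"`` for the
    upregulated mirror.  The label table has one row per categorised gene
    with columns ``gene_id`` and ``category``; partition invariants
    (pairwise-disjoint category sets, Set26/Set27 as the exact unions) are
    re-checked here so a corrupted system fails loudly.
    """
    if direction not in ("", "+"):
        raise ValueError("direction must be '' (down) or '+' (up)")
    d = {name: system[name + direction] for name in
         ("Set6", "Set8", "Set9", "Set10", "Set16", "Set18", "Set19", "Set20",
          "Set26", "Set27")}
    cats = _category_sets(d)
    labels: dict[str, str] = {}
    for cat in CATEGORIES:
        for gene in cats[cat]:
            if gene in labels:  # pragma: no cover - guarded by algebra
                raise RuntimeError(
                    f"gene {gene} assigned to both {labels[gene]} and {cat}; "
                    "category sets are not disjoint"
                )
            labels[gene] = cat
    set26 = frozenset(g for g, c in labels.items() if c in SET26_CATEGORIES)
    set27 = frozenset(g for g, c in labels.items() if c in SET27_CATEGORIES)
    if set26 != d["Set26"] or set27 != d["Set27"]:
        raise RuntimeError("Set26/Set27 do not match their category unions")
    table = pd.DataFrame(
        sorted(labels.items()), columns=["gene_id", "category"]
    )
    return set26, set27, table


def sets_from_membership(membership: pd.DataFrame) -> dict[str, frozenset]:
    """Build a primary set system from an explicit 5-bit membership table.

    ``membership`` has columns ``gene_id``, ``s1``, ``s2``, ``s3``, ``s11``,
    ``s12`` (binary).  Up-mirrors are left empty.  Convenience entry point
    for worked examples where only the pattern, not the counts, is known.
    """
    cols = ("s1", "s2", "s3", "s11", "s12")
    missing = [c for c in ("gene_id", *cols) if c not in membership.columns]
    if missing:
        raise ValueError(f"membership table is missing columns {missing}")
    system: dict[str, frozenset] = {"Set0": frozenset(), "Set0+": frozenset()}
    for name, col in zip(PRIMARY_SETS, cols):
        system[name] = frozenset(
            membership.loc[membership[col].astype(int) == 1, "gene_id"]
        )
        system[name + "+"] = frozenset()
    return system


def membership_table_from_category_counts(
    counts: Mapping[str, int]
) -> pd.DataFrame:
    """A membership table with ``counts[cat]`` genes on each canonical pattern.

    Used for worked examples where a per-category breakdown is known and the
    question is what the set algebra reconstructs from it.
    """
    rows = []
    i = 0
    for cat, n in counts.items():
        bits = CATEGORY_BITS[cat]  # KeyError for unknown categories
        for _ in range(n):
            rows.append({"gene_id": f"{cat.replace('/', '_')}_{i:05d}",
                         "s1": bits[0], "s2": bits[1], "s3": bits[2],
                         "s11": bits[3], "s12": bits[4]})
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "s1", "s2", "s3", "s11", "s12"])


def membership_bits(
    system: Mapping[str, frozenset], gene: str, direction: str = ""
) -> tuple[int, int, int, int, int]:
    """The (s1, s2, s3, s11, s12) pattern of one gene in a set system."""
    return tuple(int(gene in system[name + direction]) for name in PRIMARY_SETS)


def set_sizes(system: Mapping[str, frozenset]) -> dict[str, int]:
    return {name: len(genes) for name, genes in sorted(system.items())}


def serialize_set_system(system: Mapping[str, frozenset]) -> pd.DataFrame:
    """Long-format (gene_id, set_name, member) table of all non-empty sets."""
    rows = [
        (gene, name)
        for name, genes in sorted(system.items())
        for gene in sorted(genes)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "set_name"])
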