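"""Synthetic factorial knockout RNA-seq experiments with known ground truth.

The generator emulates the study design the pipeline targets: four strains
(control, single knockouts of two positively acting transcription factors,
and the double knockout) × two treatments (untreated, MSB oxidative stress)
× replicates, with negative-binomial counts.  Each gene is assigned a
dependence category whose canonical strain-mean pattern makes the designed
membership bits recoverable by the downstream set algebra, or an MSB
response, or neither.  Two marker genes mimic the knocked-out loci
themselves: the *atfA* marker is absent in ΔatfA backgrounds, the *atfB*
marker is absent in ΔatfB backgrounds and reduced (mid level) in the ΔatfA
single mutant, reproducing the observed downregulation of *atfB* upon *atfA*
deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import STRAINS, TREATMENTS
from .sets import CATEGORIES, CATEGORY_BITS, SET26_CATEGORIES, SET27_CATEGORIES

#: reference sequencing depth at which baseline means are expressed
REFERENCE_DEPTH = 1e6

#: default class mix; relative abundances follow the study's observed pattern
#: (the AtfA-only class dominates; categories defined by both single deletions
#: giving the stronger/weaker intermediate are rare)
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "AA": 0.08,
    "BB": 0.005,
    "AB": 0.008,
    "A/B": 0.01,
    "A-B1": 0.0012,
    "A-B2": 0.006,
    "A-B3": 0.0012,
    "A-B4": 0.012,
    "A-B5": 0.0004,
    "msb_up": 0.06,
    "msb_down": 0.08,
    "none": 0.7362,
}

#: strain multiplier level per category: control is always "high"; the level
#: pattern is the unique noiseless realisation of the category's 5-bit
#: membership pattern under the strict |log2FC| > 1 rule
CANONICAL_LEVELS: dict[str, dict[str, str]] = {
    "AA": {"control": "high", "atfA_del": "low", "atfB_del": "high", "double_del": "low"},
    "BB": {"control": "high", "atfA_del": "high", "atfB_del": "low", "double_del": "low"},
    "AB": {"control": "high", "atfA_del": "low", "atfB_del": "low", "double_del": "low"},
    "A/B": {"control": "high", "atfA_del": "high", "atfB_del": "high", "double_del": "low"},
    "A-B1": {"control": "high", "atfA_del": "mid", "atfB_del": "mid", "double_del": "low"},
    "A-B2": {"control": "high", "atfA_del": "mid", "atfB_del": "high", "double_del": "low"},
    "A-B3": {"control": "high", "atfA_del": "high", "atfB_del": "mid", "double_del": "low"},
    "A-B4": {"control": "high", "atfA_del": "low", "atfB_del": "mid", "double_del": "low"},
    "A-B5": {"control": "high", "atfA_del": "mid", "atfB_del": "low", "double_del": "low"},
}

ATFA_MARKER = "atfA"
ATFB_MARKER = "atfB"


@dataclass
class SimConfig:
    """Parameters of one simulated scenario (one cell type)."""

    n_genes: int = 2000
    replicates_per_group: int = 3
    mean_depth: float = REFERENCE_DEPTH
    baseline_mean_log_range: tuple[float, float] = (1.0, 4.0)  # log10 counts
    dispersion: float | None = None  # None -> per-gene gamma(shape 2, mean 0.05)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_multipliers: dict[str, float] = field(
        default_factory=lambda: {"high": 1.0, "mid": 0.25, "low": 0.0625}
    )
    msb_effect: float = 4.0  # fold applied to msb_up (1/x for msb_down) under MSB
    cell_type: str = "mycelium"
    n_batches: int = 1
    batch_sigma: float = 0.1  # log-normal sigma of per-gene batch factors
    length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.replicates_per_group < 2:
            raise ValueError("at least two replicates per group are required")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total!r}, not 1")
        unknown = set(self.class_proportions) - {*CATEGORIES, "msb_up", "msb_down", "none"}
        if unknown:
            raise ValueError(f"unknown class(es) in proportions: {sorted(unknown)}")
        m = self.effect_multipliers
        if not (0 < m["low"] < m["mid"] < m["high"]):
            raise ValueError("effect multipliers must satisfy 0 < low < mid < high")
        if np.log2(m["high"] / m["mid"]) <= 1 or np.log2(m["mid"] / m["low"]) <= 1:
            raise ValueError(
                "adjacent effect multipliers must differ by more than one log2 unit "
                "so designed patterns clear the regulation threshold"
            )
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def canonical_pattern(category: str) -> tuple[tuple[int, ...], dict[str, str]]:
    """The membership bits and strain multiplier levels a category forces.

    Returns ``((s1, s2, s3, s11, s12), {strain: "high"|"mid"|"low"})``.
    """
    if category not in CANONICAL_LEVELS:
        raise ValueError(f"unknown dependence category {category!r}")
    return CATEGORY_BITS[category], dict(CANONICAL_LEVELS[category])


def _sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for strain in STRAINS:
        for treatment in TREATMENTS:
            for rep in range(1, config.replicates_per_group + 1):
                batch = f"b{(rep - 1) % config.n_batches + 1}"
                rows.append(
                    {
                        "sample_id": f"{strain}_{treatment}_r{rep}",
                        "strain": strain,
                        "treatment": treatment,
                        "cell_type": config.cell_type,
                        "batch": batch,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one scenario; returns (counts, sample sheet, truth table).

    Draw order with the single generator seeded by ``config.seed``: class
    labels, baseline means, gene lengths, dispersions (if gamma), per-batch
    factors (if ``n_batches > 1``), then the count matrix row-block-wise
    (near-Poisson genes first as Poisson draws, the rest negative binomial).
    Identical configs give bitwise-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    assigned = rng.choice(len(classes), size=config.n_genes, p=probs)
    labels = np.array(classes, dtype=object)[assigned]

    lo, hi = config.baseline_mean_log_range
    baselines = 10.0 ** rng.uniform(lo, hi, size=config.n_genes)
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1,
                           size=config.n_genes)

    if config.dispersion is None:
        alphas = rng.gamma(shape=2.0, scale=0.05 / 2.0, size=config.n_genes)
    else:
        alphas = np.full(config.n_genes, float(config.dispersion))

    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    sheet = _sample_sheet(config)
    n_samples = len(sheet)

    if config.n_batches > 1:
        batch_names = sorted(sheet["batch"].unique())
        batch_factors = {
            b: rng.lognormal(mean=0.0, sigma=config.batch_sigma, size=config.n_genes)
            for b in batch_names
        }
    else:
        batch_factors = {}

    mult = config.effect_multipliers
    depth_factor = config.mean_depth / REFERENCE_DEPTH

    # per-gene strain multiplier matrix (genes x strains)
    strain_mult = np.ones((config.n_genes, len(STRAINS)))
    for j, strain in enumerate(STRAINS):
        for cat, levels in CANONICAL_LEVELS.items():
            strain_mult[labels == cat, j] = mult[levels[strain]]

    msb_mult = np.ones(config.n_genes)
    msb_mult[labels == "msb_up"] = config.msb_effect
    msb_mult[labels == "msb_down"] = 1.0 / config.msb_effect

    means = np.empty((config.n_genes, n_samples))
    for s_idx, row in enumerate(sheet.itertuples(index=False)):
        j = STRAINS.index(row.strain)
        mean = baselines * strain_mult[:, j] * depth_factor
        if row.treatment == "MSB":
            mean = mean * msb_mult
        if batch_factors:
            mean = mean * batch_factors[row.batch]
        means[:, s_idx] = mean

    counts = np.zeros((config.n_genes, n_samples), dtype=np.int64)
    near_poisson = alphas < 1e-10
    if near_poisson.any():
        counts[near_poisson] = rng.poisson(means[near_poisson])
    nb = ~near_poisson
    if nb.any():
        size = (1.0 / alphas[nb])[:, None]
        mu = means[nb]
        p = size / (size + mu)
        counts[nb] = rng.negative_binomial(size, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sheet["sample_id"].tolist())
    counts_df.columns.name = None

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": [c if c in CATEGORIES else "none" for c in labels],
            "msb_response": ["up" if c == "msb_up" else "down" if c == "msb_down"
                             else "none" for c in labels],
            "baseline_mean": baselines,
            "length_bp": lengths,
            "is_knockout_marker": False,
        }
    )

    counts_df, truth = _add_markers(counts_df, truth, sheet, config, rng)
    return counts_df, sheet, truth


def _add_markers(counts, truth, sheet, config, rng):
    """Append the two knockout marker genes."""
    mult = config.effect_multipliers
    depth_factor = config.mean_depth / REFERENCE_DEPTH
    marker_base = 500.0 * depth_factor
    rows = {}
    for marker in (ATFA_MARKER, ATFB_MARKER):
        mean = np.zeros(len(sheet))
        for s_idx, row in enumerate(sheet.itertuples(index=False)):
            if marker == ATFA_MARKER:
                level = 0.0 if row.strain in ("atfA_del", "double_del") else 1.0
            else:
                if row.strain in ("atfB_del", "double_del"):
                    level = 0.0
                elif row.strain == "atfA_del":  # atfB is downregulated without AtfA
                    level = mult["mid"]
                else:
                    level = 1.0
            mean[s_idx] = marker_base * level
        alpha = 0.05 if config.dispersion is None else max(config.dispersion, 1e-10)
        size = 1.0 / alpha
        p = size / (size + np.maximum(mean, 1e-300))
        draw = rng.negative_binomial(size, p)
        draw[mean == 0] = 0
        rows[marker] = draw
    marker_df = pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    marker_df.index.name = "gene_id"
    counts = pd.concat([counts, marker_df])
    marker_truth = pd.DataFrame(
        {
            "gene_id": [ATFA_MARKER, ATFB_MARKER],
            "category": "none",
            "msb_response": "none",
            "baseline_mean": marker_base,
            "length_bp": [2000, 2000],
            "is_knockout_marker": True,
        }
    )
    truth = pd.concat([truth, marker_truth], ignore_index=True)
    return counts, truth


def evaluate_recovery(truth: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Score recovered dependence categories against the designed truth.

    ``calls`` has columns ``gene_id`` and ``category`` (genes absent from the
    table count as ``none``).  Knockout-marker genes are excluded.  Returns a
    dict with a per-category precision/recall table, a confusion matrix and
    aggregate precision/recall for the AtfA-dependent (Set26) and
    AtfB-dependent (Set27) memberships.  Precision with zero predictions is
    reported as NaN.
    """
    truth = truth.loc[~truth["is_knockout_marker"]].copy()
    call_map = dict(zip(calls["gene_id"], calls["category"]))
    extra = set(calls["gene_id"]) - set(truth["gene_id"]) - {ATFA_MARKER, ATFB_MARKER}
    if extra:
        raise ValueError(f"calls contain genes outside the truth universe: {sorted(extra)[:5]}")
    truth["called"] = [call_map.get(g, "none") for g in truth["gene_id"]]

    confusion = pd.crosstab(truth["category"], truth["called"], dropna=False).reindex(
        index=[*CATEGORIES, "none"], columns=[*CATEGORIES, "none"], fill_value=0
    )

    rows = []
    for cat in CATEGORIES:
        n_true = int((truth["category"] == cat).sum())
        n_called = int((truth["called"] == cat).sum())
        tp = int(((truth["category"] == cat) & (truth["called"] == cat)).sum())
        rows.append(
            {
                "category": cat,
                "n_true": n_true,
                "n_called": n_called,
                "tp": tp,
                "precision": tp / n_called if n_called else float("nan"),
                "recall": tp / n_true if n_true else float("nan"),
            }
        )
    per_category = pd.DataFrame(rows)

    aggregates = {}
    for name, members in (("Set26", SET26_CATEGORIES), ("Set27", SET27_CATEGORIES)):
        true_in = truth["category"].isin(members)
        called_in = truth["called"].isin(members)
        tp = int((true_in & called_in).sum())
        aggregates[name] = {
            "n_true": int(true_in.sum()),
            "n_called": int(called_in.sum()),
            "precision": tp / called_in.sum() if called_in.any() else float("nan"),
            "recall": tp / true_in.sum() if true_in.any() else float("nan"),
        }

    return {"per_category": per_category, "confusion": confusion, "aggregates": aggregates}


def truth_gene_groups(truth: pd.DataFrame, rng: np.random.Generator | None = None,
                      n_random: int = 3, random_size: int = 50) -> dict[str, frozenset]:
    """Gene groups derived from the truth table, for enrichment demos.

    One group per designed category with members, aggregate AtfA-/AtfB-
    dependent groups, and ``n_random`` random groups as negative controls.
    """
    groups: dict[str, frozenset] = {}
    truth = truth.loc[~truth["is_knockout_marker"]]
    for cat in CATEGORIES:
        members = frozenset(truth.loc[truth["category"] == cat, "gene_id"])
        if members:
            groups[f"true_{cat.replace('/', '_')}"] = members
    for name, cats in (("true_AtfA_dependent", SET26_CATEGORIES),
                       ("true_AtfB_dependent", SET27_CATEGORIES)):
        members = frozenset(truth.loc[truth["category"].isin(cats), "gene_id"])
        if members:
            groups[name] = members
    if rng is not None:
        universe = truth["gene_id"].to_numpy()
        for i in range(n_random):
            size = min(random_size, len(universe))
            groups[f"random_{i + 1}"] = frozenset(
                rng.choice(universe, size=size, replace=False)
            )
    return groups
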