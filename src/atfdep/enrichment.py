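"""Fisher's-exact enrichment, MSB cross-tabulation and overlap statistics."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_enrichment_p(universe_size: int, group_size: int,
                           query_size: int, overlap: int) -> float:
    """One-sided (enrichment) Fisher p: P(X >= overlap), X hypergeometric."""
    if overlap > min(query_size, group_size):
        raise ValueError("overlap exceeds a margin of the 2x2 table")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, group_size, query_size))


def fisher_enrichment(query, groups: Mapping[str, frozenset], universe,
                      two_sided: bool = False) -> pd.DataFrame:
    """Enrichment of each gene group within a query set.

    Groups are intersected with the universe first; ``padj`` is BH across
    the groups tested in this call.  Raw p is retained alongside so either
    convention (raw p < 0.05, as in custom-group tests, or adjusted) can be
    applied downstream.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("universe is empty")
    if not query:
        raise ValueError("query set is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, genes in groups.items():
        group = frozenset(genes) & universe
        k = len(query & group)
        n, K, M = len(query), len(group), len(universe)
        if two_sided:
            table = [[k, n - k], [K - k, M - K - n + k]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = hypergeom_enrichment_p(M, K, n, k)
        denom = (K - k) * (n - k)
        odds = (k * (M - K - n + k)) / denom if denom else np.inf if k else np.nan
        rows.append(
            {
                "group_name": name, "overlap": k, "query_size": n,
                "group_size": K, "universe_size": M,
                "odds_ratio": odds, "p": p,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["padj"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        result["padj"] = []
    return result


def msb_crosstab(dependent, set0, set0_plus, universe) -> dict:
    """Cross-tabulate a dependent set against the MSB-responsive sets.

    Reports the overlap of ``dependent`` with the MSB-upregulated
    (``set0_plus``) and MSB-downregulated (``set0``) genes of the condition,
    each with a one-sided Fisher enrichment p.
    """
    universe = frozenset(universe)
    dependent = frozenset(dependent) & universe
    out = {}
    for key, msb_set in (("up", frozenset(set0_plus)), ("down", frozenset(set0))):
        msb_set &= universe
        k = len(dependent & msb_set)
        p = hypergeom_enrichment_p(len(universe), len(msb_set), len(dependent), k)
        out[f"{key}_overlap"] = k
        out[f"{key}_p"] = p
        out[f"{key}_enriched"] = bool(p < 0.05)
    return out


def overlap_stats(set_a, set_b, reference) -> tuple[int, float]:
    """Overlap count and percentage relative to a reference set.

    The percentage is rounded half-up to an integer, matching tabular
    reporting conventions; an empty reference yields NaN.
    """
    a, b, ref = frozenset(set_a), frozenset(set_b), frozenset(reference)
    n = len(a & b)
    if not ref:
        return n, float("nan")
    pct = float(Decimal(100 * n) / Decimal(len(ref)))
    pct = float(Decimal(pct).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return n, pct
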