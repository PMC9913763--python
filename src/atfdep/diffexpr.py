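"""Simplified negative-binomial differential expression.

For an ordered comparison "A vs B" (B the reference) the engine fits, per
gene, the log-link NB model

    count ~ NB(mean = sizefactor * exp(b0 + b_group [+ b_batch]), dispersion a)

with median-of-ratios size factors, method-of-moments dispersion pooled
across the two groups, and a Wald test on the group coefficient; log2
fold change is ``b_group / ln 2``.  BH adjustment is applied across the
tested genes of one comparison.

The per-gene fits share one design matrix, so the IRLS loop runs vectorised
over the whole gene axis; a weak ridge on the non-intercept coefficients
keeps estimates and standard errors finite when a group is entirely zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import sets as _sets

DISPERSION_FLOOR = 1e-8
RIDGE = 0.05  # penalty on non-intercept coefficients, in (log mean)^-2 units
PRIOR_DF = 10.0  # weight of the global dispersion in the moderated estimate


@dataclass(frozen=True)
class Comparison:
    """An ordered two-group comparison within one cell type."""

    numerator: tuple[str, str]  # (strain, treatment)
    reference: tuple[str, str]
    cell_type: str = "mycelium"
    batch_adjusted: bool = False
    label: str = ""

    def __post_init__(self):
        if self.numerator == self.reference:
            raise ValueError("numerator and reference groups must differ")
        if not self.label:
            object.__setattr__(self, "label", _default_label(self))


def _default_label(cmp: Comparison) -> str:
    (ns, nt), (rs, rt) = cmp.numerator, cmp.reference
    if nt == rt:
        return f"{ns}_vs_{rs}"
    if ns == rs:
        return f"{nt}_vs_{rt}@{ns}"
    return f"{ns}.{nt}_vs_{rs}.{rt}"


def condition_comparisons(cell_type: str, treatment: str,
                          batch_adjusted: bool = False) -> list[Comparison]:
    """The five strain comparisons of one (cell type, treatment) condition.

    Labels follow the set-algebra convention (Set1, Set2, Set3, Set11, Set12
    order).
    """
    pairs = [
        (("atfA_del", treatment), ("control", treatment)),
        (("atfB_del", treatment), ("control", treatment)),
        (("double_del", treatment), ("control", treatment)),
        (("double_del", treatment), ("atfB_del", treatment)),
        (("double_del", treatment), ("atfA_del", treatment)),
    ]
    return [
        Comparison(num, ref, cell_type=cell_type, batch_adjusted=batch_adjusted,
                   label=label)
        for (num, ref), label in zip(pairs, _sets.STRAIN_COMPARISONS)
    ]


def msb_comparison(strain: str, cell_type: str,
                   batch_adjusted: bool = False) -> Comparison:
    """MSB-treated vs untreated within one strain."""
    return Comparison((strain, "MSB"), (strain, "untreated"), cell_type=cell_type,
                      batch_adjusted=batch_adjusted,
                      label=f"MSB_vs_untreated@{strain}")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors, one per sample."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter empty genes "
            "or samples before normalising"
        )
    logs = np.log(mat[positive])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(norm_counts: pd.DataFrame, groups) -> pd.Series:
    """Method-of-moments NB dispersion, pooled across groups.

    ``alpha = max(floor, (pooled within-group variance - mean) / mean^2)``
    with the grand mean of the normalised counts; degenerate genes (zero
    mean or sub-Poisson variance) get the floor.
    """
    groups = np.asarray(groups)
    mat = norm_counts.to_numpy(dtype=float)
    n = mat.shape[1]
    uniq = np.unique(groups)
    if any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("every group needs at least two replicates")
    ss = np.zeros(mat.shape[0])
    for g in uniq:
        sub = mat[:, groups == g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (n - len(uniq))
    mean = mat.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(mean > 0, alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=norm_counts.index, name="dispersion")


def moderate_dispersion(alpha_hat: pd.Series, residual_df: int,
                        prior_df: float = PRIOR_DF) -> pd.Series:
    """Shrink per-gene dispersions toward a robust global estimate.

    With a handful of replicates the per-gene moment estimate carries only
    ``residual_df`` degrees of freedom and is far too noisy to plug into a
    Wald test directly (underestimates inflate type-I error, overestimates
    destroy power).  The moderated value is the df-weighted combination

        alpha = (residual_df * alpha_hat + prior_df * alpha_global)
                / (residual_df + prior_df)

    where ``alpha_global`` is the 10–90% trimmed mean of the per-gene
    estimates.  Downstream Wald statistics are referred to a t distribution
    on ``residual_df + prior_df`` degrees of freedom, mirroring the
    quasi-likelihood convention of adding the prior's degrees of freedom.
    """
    a = alpha_hat.to_numpy()
    lo, hi = np.quantile(a, [0.1, 0.9])
    body = a[(a >= lo) & (a <= hi)]
    global_alpha = float(body.mean()) if body.size else float(a.mean())
    moderated = (residual_df * a + prior_df * global_alpha) / (residual_df + prior_df)
    return pd.Series(np.maximum(moderated, DISPERSION_FLOOR),
                     index=alpha_hat.index, name="dispersion")


def _fit_nb_glm(Y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                alpha: np.ndarray, ridge: float = RIDGE,
                tol: float = 1e-12, maxiter: int = 200):
    """Vectorised IRLS for NB log-link GLMs sharing one design matrix.

    Returns (beta (G,p), cov (G,p,p), converged (G,)).  ``ridge`` penalises
    the non-intercept coefficients only.
    """
    G, n = Y.shape
    p = X.shape[1]
    pen = ridge * np.eye(p)
    pen[0, 0] = 0.0

    beta = np.linalg.lstsq(X, (np.log(Y + 0.5) - offset).T, rcond=None)[0].T
    converged = np.zeros(G, dtype=bool)
    a = alpha[:, None]
    for _ in range(maxiter):
        eta = np.clip(offset + beta @ X.T, -50.0, 50.0)
        mu = np.exp(eta)
        W = np.maximum(mu / (1.0 + a * mu), 1e-12)
        z = (eta - offset) + (Y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, W, X) + pen
        b = np.einsum("ni,gn->gi", X, W * z)
        new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        delta = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        converged = delta < tol
        if converged.all():
            break
    eta = np.clip(offset + beta @ X.T, -50.0, 50.0)
    mu = np.exp(eta)
    W = np.maximum(mu / (1.0 + a * mu), 1e-12)
    A = np.einsum("ni,gn,nj->gij", X, W, X) + pen
    cov = np.linalg.inv(A)
    return beta, cov, converged


def de_test(counts: pd.DataFrame, sample_sheet: pd.DataFrame,
            comparison: Comparison, alpha: float = 0.05) -> pd.DataFrame:
    """Differential-expression results for one comparison.

    Returns a table indexed by ``gene_id`` with columns ``base_mean``,
    ``log2fc``, ``se``, ``p``, ``padj``, ``status`` and ``comparison``.
    Genes with zero counts in all selected samples (or non-converging fits)
    carry ``status != "tested"`` and are excluded from the BH denominator.
    Dispersions are moderated (see :func:`moderate_dispersion`) and the Wald
    statistic is referred to a t distribution on the combined residual +
    prior degrees of freedom.
    """
    sel = sample_sheet.loc[sample_sheet["cell_type"] == comparison.cell_type]

    def _group(group_key):
        strain, treatment = group_key
        return sel.loc[(sel["strain"] == strain) & (sel["treatment"] == treatment)]

    num, ref = _group(comparison.numerator), _group(comparison.reference)
    for name, grp, group_key in (("numerator", num, comparison.numerator),
                                 ("reference", ref, comparison.reference)):
        if len(grp) < 2:
            raise ValueError(
                f"{name} group {group_key} has {len(grp)} sample(s) in cell type "
                f"{comparison.cell_type!r}; need at least two replicates"
            )
    chosen = pd.concat([ref, num])
    sub = counts[chosen["sample_id"].tolist()]
    is_num = np.concatenate([np.zeros(len(ref)), np.ones(len(num))])

    X_cols = [np.ones(len(chosen)), is_num]
    if comparison.batch_adjusted:
        batches = sorted(chosen["batch"].unique())
        if len(batches) < 2:
            raise ValueError(
                f"comparison {comparison.label!r} requests batch adjustment but "
                f"only batch(es) {batches} are present"
            )
        for b in batches[1:]:
            X_cols.append((chosen["batch"] == b).to_numpy(float))
    X = np.column_stack(X_cols)

    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    tested = sub.sum(axis=1) > 0

    result = pd.DataFrame(
        index=sub.index,
        data={
            "base_mean": norm.mean(axis=1),
            "log2fc": np.nan, "se": np.nan, "p": np.nan, "padj": np.nan,
            "status": "not_tested",
        },
    )
    result.index.name = "gene_id"
    result["comparison"] = comparison.label
    if tested.any():
        Y = sub.loc[tested].to_numpy(dtype=float)
        residual_df = max(X.shape[0] - X.shape[1], 1)
        disp = moderate_dispersion(
            estimate_dispersion(norm.loc[tested], is_num), residual_df
        ).to_numpy()
        beta, cov, conv = _fit_nb_glm(Y, X, np.log(sf.to_numpy()), disp)
        se = np.sqrt(cov[:, 1, 1])
        tstat = beta[:, 1] / se
        p = 2.0 * stats.t.sf(np.abs(tstat), residual_df + PRIOR_DF)
        idx = result.index[tested]
        result.loc[idx, "log2fc"] = beta[:, 1] / np.log(2.0)
        result.loc[idx, "se"] = se / np.log(2.0)
        result.loc[idx, "p"] = p
        result.loc[idx, "status"] = np.where(conv, "tested", "not_converged")
        ok = result["status"] == "tested"
        if ok.any():
            result.loc[ok, "padj"] = multipletests(
                result.loc[ok, "p"], method="fdr_bh"
            )[1]
    return result


def classify_regulated(de: pd.DataFrame, lfc_threshold: float = 1.0,
                       alpha: float = 0.05,
                       require_significance: bool = True,
                       gate_on: str = "p") -> pd.DataFrame:
    """Convert DE results into up/down/none regulation calls.

    A gene is ``up`` if ``log2fc > lfc_threshold`` and ``down`` if
    ``log2fc < -lfc_threshold`` (strict inequalities).  When
    ``require_significance`` the call is additionally gated by a
    significance criterion: ``gate_on="p"`` (default) requires the raw Wald
    p below ``alpha`` — a per-gene guard against low-information fold
    changes — while ``gate_on="padj"`` gates on the BH-adjusted value,
    tying each call to the comparison-wide FDR.  With
    ``require_significance=False`` the pure fold-change rule applies.
    Untested genes are omitted from the output.
    """
    if gate_on not in ("p", "padj"):
        raise ValueError("gate_on must be 'p' or 'padj'")
    tested = de.loc[de["status"] == "tested"].copy()
    call = np.full(len(tested), "none", dtype=object)
    up = tested["log2fc"] > lfc_threshold
    down = tested["log2fc"] < -lfc_threshold
    if require_significance:
        sig = tested[gate_on] < alpha
        up &= sig
        down &= sig
    call[up.to_numpy()] = "up"
    call[down.to_numpy()] = "down"
    out = pd.DataFrame(
        {
            "gene_id": tested.index,
            "comparison": tested["comparison"].to_numpy(),
            "call": call,
        }
    )
    return out.reset_index(drop=True)
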