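"""Differential expression: normalisation, dispersion, the NB Wald test."""

import numpy as np
import pandas as pd
import pytest

from atfdep import diffexpr
from atfdep.diffexpr import (Comparison, classify_regulated, de_test,
                             estimate_dispersion, size_factors)

CMP = Comparison(("atfA_del", "untreated"), ("control", "untreated"))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 9, 40], "s2": [5, 9, 40]}, index=list("abc"))
        assert np.allclose(size_factors(counts), 1.0)

    def test_two_sample_worked_example(self):
        counts = pd.DataFrame([[10, 20], [100, 200]], index=["g1", "g2"],
                              columns=["s1", "s2"])
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert sf["s2"] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_against_brute_force_on_3x3(self):
        mat = np.array([[12.0, 36.0, 12.0], [40.0, 120.0, 80.0], [9.0, 27.0, 9.0]])
        counts = pd.DataFrame(mat, index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"])
        # brute force: per-gene geometric means, then the median ratio per sample
        geo = np.exp(np.log(mat).mean(axis=1))
        expected = np.median(mat / geo[:, None], axis=0)
        assert np.allclose(size_factors(counts), expected)

    def test_error_without_an_everywhere_positive_gene(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], index=["g1", "g2"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="filter"):
            size_factors(counts)


class TestDispersion:
    def test_zero_variance_gives_floor(self):
        norm = pd.DataFrame([[7.0] * 6], index=["g1"],
                            columns=[f"s{i}" for i in range(6)])
        alpha = estimate_dispersion(norm, [0, 0, 0, 1, 1, 1])
        assert alpha["g1"] == diffexpr.DISPERSION_FLOOR

    def test_moment_formula_worked_example(self):
        # grand mean 100, pooled within-group variance 600 -> alpha 0.05
        rows = np.array([[80.0, 100.0, 120.0, 80.0, 100.0, 120.0]])
        norm = pd.DataFrame(rows, index=["g1"], columns=[f"s{i}" for i in range(6)])
        groups = [0, 0, 0, 1, 1, 1]
        var = 400.0  # per-group sample variance of (80, 100, 120)
        expected = (var - 100.0) / 100.0**2
        alpha = estimate_dispersion(norm, groups)
        assert alpha["g1"] == pytest.approx(expected)

    def test_poisson_data_has_small_estimates(self):
        rng = np.random.default_rng(11)
        G, n = 400, 100
        norm = pd.DataFrame(rng.poisson(500.0, size=(G, n)).astype(float),
                            index=[f"g{i}" for i in range(G)],
                            columns=[f"s{i}" for i in range(n)])
        alpha = estimate_dispersion(norm, [0] * 50 + [1] * 50)
        assert (alpha < 0.01).mean() >= 0.95

    def test_requires_replication(self):
        norm = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            estimate_dispersion(norm, [0, 1])


class TestDeTest:
    def test_noiseless_four_fold_change_recovered(self, two_group_sheet, make_counts):
        # a deterministic 4-fold gene embedded in a random null background
        rng = np.random.default_rng(3)
        background = 10 ** rng.uniform(1, 3, 300)
        counts = make_counts(background, two_group_sheet["sample_id"], seed=4,
                             dispersion=0.05)
        counts.loc["target"] = [100, 100, 100, 400, 400, 400]
        res = de_test(counts, two_group_sheet, CMP)
        assert res.loc["target", "log2fc"] == pytest.approx(2.0, abs=0.05)
        assert res.loc["target", "padj"] < 0.01

    def test_all_zero_gene_not_tested_and_out_of_bh(self, two_group_sheet, make_counts):
        counts = make_counts(np.full(50, 200.0), two_group_sheet["sample_id"], seed=5)
        counts.loc["empty"] = 0
        res = de_test(counts, two_group_sheet, CMP)
        assert res.loc["empty", "status"] == "not_tested"
        assert np.isnan(res.loc["empty", "p"])
        tested = res.loc[res["status"] == "tested"]
        # BH denominator excludes the untested gene: max padj equals max p
        assert tested["padj"].max() <= 1.0
        assert len(tested) == 50

    def test_swapping_groups_negates_log2fc_and_keeps_p(self, two_group_sheet,
                                                        make_counts):
        rng = np.random.default_rng(8)
        means = 10 ** rng.uniform(1, 3, 80)
        counts = make_counts(means, two_group_sheet["sample_id"], seed=9)
        counts.iloc[:20] = counts.iloc[:20] * 3  # some asymmetric signal
        fwd = de_test(counts, two_group_sheet, CMP)
        rev = de_test(counts, two_group_sheet,
                      Comparison(CMP.reference, CMP.numerator))
        both = (fwd["status"] == "tested") & (rev["status"] == "tested")
        assert np.abs(fwd.loc[both, "log2fc"] + rev.loc[both, "log2fc"]).max() < 1e-9
        assert np.allclose(fwd.loc[both, "p"], rev.loc[both, "p"], rtol=1e-6)

    def test_bh_is_monotone_and_dominates_p(self, two_group_sheet, make_counts):
        counts = make_counts(10 ** np.linspace(1, 3, 120),
                             two_group_sheet["sample_id"], seed=12)
        res = de_test(counts, two_group_sheet, CMP)
        tested = res.loc[res["status"] == "tested"].sort_values("p")
        assert (tested["padj"].to_numpy() >= tested["p"].to_numpy() - 1e-15).all()
        assert (np.diff(tested["padj"].to_numpy()) >= -1e-12).all()
        assert tested["padj"].between(0, 1).all()

    def test_missing_group_is_reported(self, two_group_sheet, make_counts):
        counts = make_counts([100.0], two_group_sheet["sample_id"], seed=1)
        bad = Comparison(("double_del", "untreated"), ("control", "untreated"))
        with pytest.raises(ValueError, match="double_del"):
            de_test(counts, two_group_sheet, bad)

    def test_batch_term_requires_two_batches(self, two_group_sheet, make_counts):
        counts = make_counts([100.0, 60.0], two_group_sheet["sample_id"], seed=2)
        cmp = Comparison(CMP.numerator, CMP.reference, batch_adjusted=True)
        with pytest.raises(ValueError, match="batch"):
            de_test(counts, two_group_sheet, cmp)

    def test_batch_adjustment_absorbs_batch_shift(self, two_group_sheet, make_counts):
        sheet = two_group_sheet.copy()
        sheet["batch"] = ["b1", "b2", "b1", "b2", "b1", "b2"]
        rng = np.random.default_rng(21)
        means = 10 ** rng.uniform(1.5, 3, 200)
        counts = make_counts(means, sheet["sample_id"], seed=22)
        b2 = sheet.loc[sheet["batch"] == "b2", "sample_id"]
        counts[b2] = (counts[b2] * 1.6).round().astype(int)
        res = de_test(counts, sheet, Comparison(CMP.numerator, CMP.reference,
                                                batch_adjusted=True))
        tested = res.loc[res["status"] == "tested"]
        # null comparison: batch shift must not produce wholesale calls
        assert (tested["p"] < 0.05).mean() < 0.10


class TestClassifyRegulated:
    def _de(self, rows):
        df = pd.DataFrame(rows)
        df["status"] = "tested"
        df["comparison"] = "atfA_del_vs_control"
        return df.set_index("gene_id")

    def test_threshold_rule_with_significance(self):
        de = self._de([
            {"gene_id": "down_sig", "log2fc": -1.2, "p": 0.001, "padj": 0.01},
            {"gene_id": "edge", "log2fc": -1.0, "p": 1e-6, "padj": 1e-5},
            {"gene_id": "up_sig", "log2fc": 2.4, "p": 0.001, "padj": 0.01},
        ])
        calls = classify_regulated(de).set_index("gene_id")["call"]
        assert calls["down_sig"] == "down"
        assert calls["edge"] == "none"  # strict inequality at the boundary
        assert calls["up_sig"] == "up"

    def test_padj_gate_mode_and_ungated_rule(self):
        de = self._de([
            {"gene_id": "g", "log2fc": 2.4, "p": 0.04, "padj": 0.30},
        ])
        gated = classify_regulated(de, gate_on="padj").set_index("gene_id")["call"]
        assert gated["g"] == "none"
        ungated = classify_regulated(de, require_significance=False)
        assert ungated.set_index("gene_id")["call"]["g"] == "up"

    def test_raw_p_gate_default(self):
        de = self._de([
            {"gene_id": "weak", "log2fc": 3.0, "p": 0.20, "padj": 0.50},
            {"gene_id": "strong", "log2fc": 3.0, "p": 0.01, "padj": 0.30},
        ])
        calls = classify_regulated(de).set_index("gene_id")["call"]
        assert calls["weak"] == "none"
        assert calls["strong"] == "up"

    def test_untested_genes_are_omitted(self):
        de = self._de([{"gene_id": "g", "log2fc": 3.0, "p": 0.001, "padj": 0.001}])
        de.loc["g", "status"] = "not_tested"
        assert classify_regulated(de).empty


def test_agreement_with_independent_nb_engine(two_group_sheet, make_counts):
    """Cross-check fold changes against an independent DESeq2-style
    implementation (pydeseq2) on a small simulated comparison."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(33)
    means = 10 ** rng.uniform(1.5, 3.5, 150)
    counts = make_counts(means, two_group_sheet["sample_id"], seed=34)
    signal = rng.choice([0.25, 1.0, 4.0], size=150, p=[0.2, 0.6, 0.2])
    num = two_group_sheet.loc[two_group_sheet.strain == "atfA_del", "sample_id"]
    counts[num] = (counts[num] * signal[:, None]).round().astype(int)

    ours = de_test(counts, two_group_sheet, CMP)

    meta = two_group_sheet.set_index("sample_id")[["strain"]]
    dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~strain", quiet=True)
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["strain", "atfA_del", "control"], quiet=True)
    stats.summary()
    theirs = stats.results_df

    both = ours.index.intersection(theirs.index)
    ok = ours.loc[both, "status"] == "tested"
    diff = ours.loc[both, "log2fc"][ok] - theirs.loc[both, "log2FoldChange"][ok]
    assert np.median(np.abs(diff)) < 0.1
    r = np.corrcoef(ours.loc[both, "log2fc"][ok], theirs.loc[both, "log2FoldChange"][ok])[0, 1]
    assert r > 0.98
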