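"""Tabular I/O and expression summaries.

All tables are plain TSV (UTF-8, ``#`` comment lines ignored, first column =
gene or sample ID); gene groups use the GMT convention (set name, description,
then member gene IDs, tab-separated).  Gene IDs are opaque strings.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

STRAINS = ("control", "atfA_del", "atfB_del", "double_del")
TREATMENTS = ("untreated", "MSB")
CELL_TYPES = ("mycelium", "conidium")

SAMPLE_SHEET_COLUMNS = ("sample_id", "strain", "treatment", "cell_type", "batch", "replicate")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene × sample count matrix; validates integrality and uniqueness."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample IDs in {path}")
    for sample in df.columns:
        col = pd.to_numeric(df[sample], errors="coerce")
        bad = df.index[col.isna() | (col < 0) | (col % 1 != 0)]
        if len(bad):
            raise ValueError(
                f"invalid count for gene {bad[0]!r}, sample {sample!r}: "
                f"{df.loc[bad[0], sample]!r} (counts must be non-negative integers)"
            )
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | os.PathLike, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a sample sheet; optionally cross-check against a matrix."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} is missing columns {missing}")
    df = df[list(SAMPLE_SHEET_COLUMNS)].copy()
    df["replicate"] = df["replicate"].astype(int)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample IDs in sample sheet {path}")
    for col, allowed in (("strain", STRAINS), ("treatment", TREATMENTS), ("cell_type", CELL_TYPES)):
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise ValueError(f"unknown {col} label(s) {bad} in {path}; allowed: {allowed}")
    if counts is not None:
        validate_design(counts, df)
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def validate_design(counts: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Require sample-sheet rows and count-matrix columns to match exactly."""
    sheet_ids = set(sheet["sample_id"])
    matrix_ids = set(counts.columns)
    only_sheet = sorted(sheet_ids - matrix_ids)
    only_matrix = sorted(matrix_ids - sheet_ids)
    if only_sheet:
        raise ValueError(f"sample(s) {only_sheet} in sample sheet but not in count matrix")
    if only_matrix:
        raise ValueError(f"sample(s) {only_matrix} in count matrix but not in sample sheet")


def read_gene_lengths(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    lengths = df.iloc[:, 0].astype(int)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r} in {path}")
    return dict(zip(lengths.index.astype(str), lengths))


def write_gene_lengths(lengths: Mapping[str, int], path: str | os.PathLike) -> None:
    pd.Series(dict(lengths), name="length_bp").rename_axis("gene_id").to_csv(path, sep="\t")


def gene_lengths_from_gff3(path: str | os.PathLike) -> dict[str, int]:
    """Summed exon length per gene from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        total = sum(
            exon.end - exon.start + 1 for exon in db.children(gene, featuretype="exon")
        )
        if total == 0:  # gene without annotated exons: span length
            total = gene.end - gene.start + 1
        lengths[gene.id] = total
    return lengths


def read_gmt(path: str | os.PathLike) -> dict[str, frozenset]:
    """Read gene groups from a GMT file: name <TAB> description <TAB> genes..."""
    groups: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and ≥1 gene"
                )
            name, genes = fields[0], frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: group {name!r} has an empty gene list")
            if name in groups:
                raise ValueError(f"{path}:{lineno}: duplicate group name {name!r}")
            groups[name] = genes
    return groups


def write_gmt(groups: Mapping[str, frozenset], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in groups.items():
            fh.write("\t".join([name, "", *sorted(genes)]) + "\n")


def rpkm(counts: pd.DataFrame, lengths_bp: Mapping[str, int]) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    rpkm[g, s] = count[g, s] / ((length_bp[g] / 1e3) * (libsize[s] / 1e6))
    with the library size taken as the column sum of the supplied matrix.
    """
    missing = [g for g in counts.index if g not in lengths_bp]
    if missing:
        raise ValueError(f"no length for gene(s) {missing[:5]}")
    lengths = pd.Series({g: lengths_bp[g] for g in counts.index}, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        empty = libsize.index[libsize <= 0].tolist()
        raise ValueError(f"empty sample(s): {empty}")
    return counts.div(lengths / 1e3, axis=0).div(libsize / 1e6, axis=1)
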