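"""Readers and writers for every table the pipeline touches.

Plain TSV throughout, with SEG-dialect column names accepted for copy-number
input and BED accepted for gene annotation.  Coordinates are normalised to
0-based half-open at this boundary: pass ``one_based=True`` for 1-based
inclusive input (the SEG convention of DNAcopy output) and the conversion
happens here, nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    DERTable,
    ExpressionMatrix,
    GeneAnnotation,
    MutationSet,
    RankedList,
    ScoreTable,
    SegmentProfile,
    ValidationError,
)

__all__ = [
    "read_gene_annotation",
    "write_gene_annotation",
    "read_expression",
    "write_expression",
    "read_segments",
    "write_segments",
    "read_der_table",
    "write_der_table",
    "read_mutations",
    "write_mutations",
    "write_score_table",
    "read_score_table",
    "write_ranked_list",
]

# SEG dialect headers (DNAcopy) mapped onto our canonical names
_SEG_SYNONYMS = {
    "id": "sample",
    "sample": "sample",
    "sample_id": "sample",
    "chrom": "chrom",
    "chromosome": "chrom",
    "loc.start": "start",
    "start": "start",
    "loc.end": "end",
    "end": "end",
    "seg.mean": "value",
    "value": "value",
    "cbs_value": "value",
}


def _check_exists(path: str | os.PathLike) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(path)


def read_gene_annotation(
    path: str | os.PathLike,
    *,
    dialect: str = "auto",
    one_based: bool = False,
) -> GeneAnnotation:
    """Read a gene annotation table (TSV with header, or headerless BED).

    TSV columns: gene_id, chrom, start, end.  BED columns: chrom, start,
    end, name.  BED is always 0-based half-open; ``one_based`` applies to
    the TSV dialect only.
    """
    _check_exists(path)
    if dialect == "auto":
        dialect = "bed" if str(path).endswith(".bed") else "tsv"
    if dialect == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"],
            usecols=[0, 1, 2, 3], dtype={"chrom": str, "gene_id": str},
        )
        one_based = False
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        required = {"gene_id", "chrom", "start", "end"}
        if not required <= set(df.columns):
            raise ValidationError(
                f"annotation needs columns {sorted(required)}, got "
                f"{df.columns.tolist()}"
            )
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if one_based:
        df["start"] -= 1  # 1-based inclusive -> 0-based half-open
    return GeneAnnotation(df.set_index("gene_id")[["chrom", "start", "end"]])


def write_gene_annotation(genes: GeneAnnotation, path: str | os.PathLike) -> None:
    genes.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(
    path: str | os.PathLike,
    *,
    log2_offset: float | None = None,
    impute: str = "error",
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (first column gene_id).

    The matrix is expected to be pre-logged.  Set ``log2_offset=c`` to apply
    log2(x + c) to a raw-intensity matrix (c=1 is the usual choice).
    Missing cells are an error by default; ``impute='row_mean'`` fills each
    gap with the gene's mean across the remaining samples.
    """
    _check_exists(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if impute == "row_mean":
        means = df.mean(axis=1)
        df = df.apply(lambda col: col.fillna(means))
    elif impute != "error":
        raise ValueError(f"unknown imputation mode: {impute!r}")
    if log2_offset is not None:
        if (df < -log2_offset).any().any():
            raise ValidationError("log2 transform would take log of a negative")
        df = np.log2(df + log2_offset)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_segments(
    path: str | os.PathLike, *, one_based: bool = False
) -> list[SegmentProfile]:
    """Read a SEG-dialect table into one profile per sample.

    Accepts canonical (sample, chrom, start, end, value) or DNAcopy
    (ID, chrom, loc.start, loc.end, seg.mean) headers.
    """
    _check_exists(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={1: str})
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _SEG_SYNONYMS:
            renames[col] = _SEG_SYNONYMS[key]
    df = df.rename(columns=renames)
    required = {"sample", "chrom", "start", "end", "value"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"segment table needs columns {sorted(required)} "
            f"(SEG synonyms accepted), got {df.columns.tolist()}"
        )
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if one_based:
        df["start"] -= 1
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        seg = grp[["chrom", "start", "end", "value"]].reset_index(drop=True)
        profiles.append(SegmentProfile(str(sample), seg))
    return profiles


def write_segments(
    profiles: Sequence[SegmentProfile], path: str | os.PathLike
) -> None:
    frames = []
    for p in profiles:
        df = p.segments.copy()
        df.insert(0, "sample", p.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_der_table(path: str | os.PathLike) -> DERTable:
    """Read a two-column gene_id / DER table."""
    _check_exists(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError("DER table needs gene_id and der columns")
    series = pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name="der",
    )
    return DERTable(series)


def write_der_table(der: DERTable, path: str | os.PathLike) -> None:
    der.values.rename("der").to_csv(path, sep="\t", index_label="gene_id")


def read_mutations(path: str | os.PathLike) -> MutationSet:
    """Read a mutated-gene list.

    Header comments carry the screen metadata, e.g.::

        # n_genes_sequenced=18000
        gene_id	n_samples
        TP53	4
        APC	2

    ``n_samples`` (samples carrying a mutation in the gene) is optional.
    """
    _check_exists(path)
    n_sequenced = None
    with open(path) as fh:
        header_comments = []
        for line in fh:
            if line.startswith("#"):
                header_comments.append(line[1:].strip())
            else:
                break
    for comment in header_comments:
        if "=" in comment:
            key, _, value = comment.partition("=")
            if key.strip() == "n_genes_sequenced":
                n_sequenced = int(value.strip())
    if n_sequenced is None:
        raise ValidationError(
            "mutation file must declare '# n_genes_sequenced=<int>'"
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = df.iloc[:, 0].astype(str)
    counts = None
    if "n_samples" in df.columns:
        counts = dict(zip(genes, df["n_samples"].astype(int)))
    return MutationSet(
        mutated_genes=frozenset(genes),
        n_genes_sequenced=n_sequenced,
        sample_counts=counts,
    )


def write_mutations(mut: MutationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_genes_sequenced={mut.n_genes_sequenced}\n")
        if mut.sample_counts:
            fh.write("gene_id\tn_samples\n")
            for g in sorted(mut.mutated_genes):
                fh.write(f"{g}\t{mut.sample_counts.get(g, 1)}\n")
        else:
            fh.write("gene_id\n")
            for g in sorted(mut.mutated_genes):
                fh.write(f"{g}\n")


def write_score_table(table: ScoreTable, path: str | os.PathLike) -> None:
    df = table.scores.rename("score").to_frame()
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_score_table(path: str | os.PathLike, strategy: str) -> ScoreTable:
    _check_exists(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    series = pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name="score",
    )
    return ScoreTable(strategy, series)


def write_ranked_list(ranked: RankedList, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for i, g in enumerate(ranked.genes, start=1):
            score = ""
            if ranked.scores is not None and g in ranked.scores.index:
                score = f"{ranked.scores[g]:.10g}"
            fh.write(f"{i}\t{g}\t{score}\n")


def write_cohort(cohort, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a cohort bundle to a directory in the formats the readers take.

    Returns the mapping of layer name to file path; absent layers are
    simply not written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        return os.path.join(out_dir, name)

    write_gene_annotation(cohort.genes, _p("annotation.tsv"))
    paths["annotation"] = _p("annotation.tsv")
    write_mutations(cohort.mutations, _p("mutations.tsv"))
    paths["mutations"] = _p("mutations.tsv")
    if cohort.expression is not None:
        write_expression(cohort.expression, _p("expression.tsv"))
        paths["expression"] = _p("expression.tsv")
    if cohort.segments is not None:
        write_segments(cohort.segments, _p("segments.seg"))
        paths["segments"] = _p("segments.seg")
    if cohort.der is not None:
        write_der_table(cohort.der, _p("der.tsv"))
        paths["der"] = _p("der.tsv")
    return paths


def read_ranked_list(path: str | os.PathLike, label: str = "") -> RankedList:
    _check_exists(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = tuple(df["gene_id"].astype(str))
    scores = None
    if "score" in df.columns and df["score"].notna().any():
        scores = pd.Series(df["score"].to_numpy(), index=list(genes), name="score")
    return RankedList(label or os.path.basename(str(path)), genes, scores)
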