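"""Readers and writers for the standard formats the pipeline touches.

Formats: 10x-style Matrix Market triplets (MTX + features + barcodes),
BED3+ peak intervals, TSV count tables, and a TSV gene-annotation table
(symbol, chrom, strand, start, end).  All genomic coordinates are
0-based half-open internally; BED is read natively.  The transcription
start site (TSS) is strand-resolved: ``gene_start`` for + genes and
``gene_end - 1`` for - genes, with the transcription termination site
(TTS) at the opposite terminus.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse as sp

from epilineage.expression_core import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "FormatError",
    "read_10x_triplet",
    "write_10x_triplet",
    "read_bed",
    "write_bed",
    "read_count_table",
    "write_count_table",
    "read_gene_annotation",
    "build_gene_annotation",
    "resolve_symbols",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


class Interval(NamedTuple):
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# 10x triplet (Matrix Market) I/O
# ---------------------------------------------------------------------------


def read_10x_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a sparse gene-by-cell matrix from 10x-style triplet files.

    ``features`` and ``barcodes`` are plain/TSV files with one entry per
    line; for multi-column feature files the second column is taken as
    the gene symbol.  Raises :class:`FormatError` on dimension mismatch
    or non-integer / negative entries.
    """
    try:
        mat = spio.mmread(str(matrix_path))
    except Exception as exc:  # malformed header or body
        raise FormatError(f"invalid Matrix Market file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and not np.issubdtype(mat.dtype, np.integer):
        data = mat.data
        if np.any(data != np.round(data)):
            raise FormatError("matrix contains non-integer entries")
        mat = mat.astype(np.int64)
    if mat.nnz and mat.data.min() < 0:
        raise FormatError("matrix contains negative entries")

    def _read_lines(path: str | Path) -> list[str]:
        with open(path) as fh:
            return [line.rstrip("\n") for line in fh if line.strip()]

    feat_lines = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    symbols = []
    for line in feat_lines:
        parts = line.split("\t")
        symbols.append(parts[1] if len(parts) > 1 else parts[0])
    if mat.shape != (len(symbols), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(symbols)} features "
            f"x {len(barcodes)} barcodes"
        )
    return CountMatrix(values=mat.astype(np.int64), genes=symbols, columns=barcodes)


def write_10x_triplet(counts: CountMatrix, out_dir: str | Path) -> None:
    """Write a :class:`CountMatrix` as matrix.mtx / features.tsv / barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values = counts.values
    if not sp.issparse(values):
        values = sp.coo_matrix(values)
    spio.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(values), field="integer")
    with open(out / "features.tsv", "w") as fh:
        for g in counts.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out / "barcodes.tsv", "w") as fh:
        for b in counts.columns:
            fh.write(f"{b}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ intervals (0-based half-open), preserving file order."""
    out: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{ln}: start >= end ({start} >= {end})")
            out.append(Interval(parts[0], start, end))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a genes-by-samples TSV count table (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.round(values)):
        raise FormatError(f"{path}: count table must be integer")
    if values.min() < 0:
        raise FormatError(f"{path}: negative counts")
    return CountMatrix(values=values.astype(np.int64), genes=df.index, columns=df.columns)


def write_count_table(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t")


def build_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene table and attach strand-resolved TSS/TTS columns.

    Expects columns ``symbol, chrom, strand, start, end`` with 0-based
    half-open gene bodies.  TSS = ``start`` for + genes, ``end - 1`` for
    - genes; TTS is the opposite terminus.
    """
    required = {"symbol", "chrom", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene annotation missing columns {sorted(missing)}")
    df = df.copy()
    if (df["start"] >= df["end"]).any():
        raise FormatError("gene annotation has start >= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    if df["symbol"].duplicated().any():
        raise FormatError("gene symbols must be unique")
    plus = df["strand"] == "+"
    df["tss"] = np.where(plus, df["start"], df["end"] - 1)
    df["tts"] = np.where(plus, df["end"] - 1, df["start"])
    return df


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    return build_gene_annotation(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# symbol resolution
# ---------------------------------------------------------------------------


def resolve_symbols(counts: CountMatrix, alias_map: Mapping[str, str]) -> CountMatrix:
    """Map raw gene identifiers to official symbols.

    Rows whose identifier is absent from ``alias_map`` are dropped.  When
    several rows map to the same official symbol, the row with the
    largest total read count is kept.  Output symbols are unique; drops
    are logged.
    """
    mapped = pd.Series([alias_map.get(g) for g in counts.genes], dtype=object)
    keep_mask = mapped.notna().to_numpy()
    n_unmapped = int((~keep_mask).sum())
    sub = counts.subset_genes(keep_mask)
    symbols = mapped[keep_mask].to_numpy()

    if sp.issparse(sub.values):
        totals = np.asarray(sub.values.sum(axis=1)).ravel()
    else:
        totals = sub.values.sum(axis=1)
    # winner per official symbol = row with largest total count; earlier row
    # wins exact ties (stable argmax over original order)
    order = pd.DataFrame({"symbol": symbols, "total": totals, "row": np.arange(len(symbols))})
    winners = (
        order.sort_values(["total", "row"], ascending=[False, True])
        .drop_duplicates("symbol")
        .sort_values("row")
    )
    n_collisions = len(symbols) - len(winners)
    result = sub.subset_genes(winners["row"].to_numpy())
    result = CountMatrix(
        values=result.values,
        genes=winners["symbol"].to_numpy(),
        columns=result.columns,
        norm_factors=result.norm_factors,
    )
    if n_unmapped or n_collisions:
        logger.info(
            "resolve_symbols dropped %d unmapped and %d collision rows",
            n_unmapped,
            n_collisions,
        )
    return result
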