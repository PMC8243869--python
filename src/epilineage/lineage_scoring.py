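"""Per-cell lineage statistics and structure-vs-structure DE.

The ternary statistic positions each cell on the basal/LP/ML simplex by
the *numbers* of positive signature genes it expresses (count above a
detection threshold, default > 0), normalised to sum to one.  Cells
expressing equal numbers of genes from all three sets land in the
centre; cells expressing no signature gene are undefined (NaN).

Signature scores are the per-cell mean log2-CPM over a lineage's
positive signature genes.  Heatmap preparation standardises each gene to
mean 0 / sd 1 (population sd) and clusters genes and cells by Ward's
minimum-variance method.  Structure DE compares, within a cluster, cells
from two tissue structures (terminal end bud vs duct) with a two-sided
Wilcoxon rank-sum test after a log-fold-change prefilter, with
Bonferroni correction over the post-QC gene universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy.cluster.hierarchy import linkage
from scipy.stats import mannwhitneyu

from epilineage.expression_core import CountMatrix
from epilineage.signature_derivation import LineageSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ternary_coordinates",
    "signature_scores",
    "standardize_for_heatmap",
    "structure_de",
    "HeatmapResult",
]


def _set_row_indices(genes: pd.Index, symbols: Sequence[str]) -> np.ndarray:
    return np.flatnonzero(genes.isin(set(symbols)))


def ternary_coordinates(
    counts: CountMatrix,
    signatures: LineageSignature,
    *,
    detection_threshold: int = 0,
) -> pd.DataFrame:
    """Simplex coordinates per cell from expressed signature-gene counts.

    For each cell, ``n_p`` = number of positive signature genes of
    population ``p`` with count > ``detection_threshold``; the coordinate
    is ``(n_basal, n_lp, n_ml) / sum``.  Cells with no expressed
    signature gene get NaN coordinates (their number is logged).  Raw
    numbers are used rather than fractions of set size, so a cell
    expressing equal *numbers* from each set sits at the centre even
    though the sets differ in size.
    """
    pops = signatures.populations
    if any(len(signatures.positive[p]) == 0 for p in pops):
        raise ValueError("empty positive signature set")
    present_frac = [
        counts.genes.isin(signatures.positive[p]).mean()
        * len(counts.genes)
        / max(len(signatures.positive[p]), 1)
        for p in pops
    ]
    if min(present_frac) < 0.5:
        warnings.warn("fewer than 50% of signature genes present in the matrix")
    detected = counts.values > detection_threshold
    ns = []
    for p in pops:
        rows = _set_row_indices(counts.genes, signatures.positive[p])
        if sp.issparse(detected):
            ns.append(np.asarray(detected[rows, :].sum(axis=0)).ravel())
        else:
            ns.append(detected[rows, :].sum(axis=0))
    n = np.vstack(ns).astype(float)  # (3, cells)
    total = n.sum(axis=0)
    undefined = total == 0
    if undefined.any():
        logger.info("%d cells express no signature gene", int(undefined.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        coords = np.where(total > 0, n / np.maximum(total, 1), np.nan)
    out = pd.DataFrame(coords.T, index=counts.columns, columns=pops)
    out["n_signature_genes"] = total.astype(int)
    return out


def signature_scores(
    log2cpm: pd.DataFrame,
    signatures: LineageSignature,
) -> pd.DataFrame:
    """Per-cell mean log2-CPM over each lineage's positive signature genes."""
    scores = {}
    for pop in signatures.populations:
        rows = log2cpm.index.isin(set(signatures.positive[pop]))
        if not rows.any():
            raise ValueError(f"no signature genes of {pop} present in matrix")
        frac = rows.sum() / len(signatures.positive[pop])
        if frac < 0.5:
            warnings.warn(f"fewer than 50% of {pop} signature genes present")
        scores[pop] = log2cpm.loc[rows].mean(axis=0)
    return pd.DataFrame(scores)


@dataclass
class HeatmapResult:
    z: pd.DataFrame
    gene_linkage: np.ndarray
    column_linkage: np.ndarray


def standardize_for_heatmap(log2cpm: pd.DataFrame) -> HeatmapResult:
    """Gene-wise z-scores (population sd) with Ward dendrograms.

    Zero-variance genes are emitted as all-zero rows with a warning
    rather than dropped.  Ward linkage uses Euclidean distance with the
    Lance-Williams squared-distance update (scipy's ``ward`` method); the
    reported merge heights are the square roots of the within-cluster
    variance increase criterion.
    """
    x = log2cpm.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("at least 2 columns required")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    zero_var = sd.ravel() == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance genes emitted as zeros")
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=log2cpm.index, columns=log2cpm.columns)
    gene_link = linkage(z, method="ward") if z.shape[0] > 1 else np.empty((0, 4))
    col_link = linkage(z.T, method="ward") if z.shape[1] > 1 else np.empty((0, 4))
    return HeatmapResult(z=zdf, gene_linkage=gene_link, column_linkage=col_link)


def structure_de(
    counts: CountMatrix,
    cluster_labels: Sequence,
    structure_labels: Sequence,
    *,
    logfc_threshold: float = 0.15,
    min_pct: float = 0.1,
    scale: float = 1e4,
    log_base: str = "e",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-cluster DE between two tissue structures.

    For each cluster containing both structures (>= 3 cells each),
    candidate genes must be detected in at least ``min_pct`` of either
    group and have ``|log((mean1 + 1)/(mean2 + 1))| >= logfc_threshold``
    on library-normalised expression (counts scaled to ``scale`` per
    cell; natural log by default, ``log_base="2"`` for the log2 dialect).
    Candidates are tested with a two-sided Wilcoxon rank-sum test and
    Bonferroni-adjusted over the full post-QC gene universe.

    Returns a table with columns
    ``cluster, gene, log_fc, p, p_adj, pct1, pct2, significant``.
    """
    clusters = np.asarray(cluster_labels)
    structures = np.asarray(structure_labels)
    if len(clusters) != counts.n_columns or len(structures) != counts.n_columns:
        raise ValueError("one cluster and structure label per cell required")
    struct_levels = pd.unique(structures)
    if len(struct_levels) != 2:
        raise ValueError("exactly two structure levels expected")
    n_universe = counts.n_genes
    dense = counts.to_dense().astype(float)
    libs = dense.sum(axis=0)
    norm = dense / np.maximum(libs, 1.0) * scale
    log_div = 1.0 if log_base == "e" else np.log(2.0)

    rows = []
    for cl in pd.unique(clusters):
        in_cl = clusters == cl
        g1 = in_cl & (structures == struct_levels[0])
        g2 = in_cl & (structures == struct_levels[1])
        if g1.sum() < 3 or g2.sum() < 3:
            warnings.warn(f"cluster {cl} lacks both structures (>=3 cells); skipped")
            continue
        x1, x2 = norm[:, g1], norm[:, g2]
        pct1 = (x1 > 0).mean(axis=1)
        pct2 = (x2 > 0).mean(axis=1)
        logfc = np.log((x1.mean(axis=1) + 1.0) / (x2.mean(axis=1) + 1.0)) / log_div
        cand = ((pct1 >= min_pct) | (pct2 >= min_pct)) & (
            np.abs(logfc) >= logfc_threshold
        )
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            continue
        pvals = np.empty(idx.size)
        for k, gi in enumerate(idx):
            res = mannwhitneyu(x1[gi], x2[gi], alternative="two-sided")
            pvals[k] = res.pvalue
        p_adj = np.minimum(pvals * n_universe, 1.0)
        for k, gi in enumerate(idx):
            rows.append(
                (
                    cl,
                    counts.genes[gi],
                    logfc[gi],
                    pvals[k],
                    p_adj[k],
                    pct1[gi],
                    pct2[gi],
                    p_adj[k] < alpha,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "gene", "log_fc", "p", "p_adj", "pct1", "pct2", "significant"],
    )
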