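"""Count containers, QC filtering and normalisation shared by the RNA branches.

The central container is :class:`CountMatrix`, a genes-by-columns integer
count matrix (columns are bulk samples or single cells) carrying gene
symbols, column identifiers, library sizes and optional TMM normalisation
factors.  Filtering follows the study's published rules: bulk genes must
reach 0.4 counts-per-million in at least three samples; single-cell genes
must be detected in at least 1% of cells of every sample; cells need at
least 500 reads and 500 detected genes, a bounded mitochondrial
percentage, and must not be upper outliers in reads or genes detected
(a doublet guard).

Normalisation is TMM (trimmed mean of M-values): a doubly trimmed,
precision-weighted mean of gene-wise log2 expression ratios against a
reference sample, rescaled so the factors have geometric mean one.
``log2_cpm`` computes log2 counts-per-million with a library-size-scaled
prior count so zero counts remain comparable across sequencing depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "EmptyFilterError",
    "filter_cells",
    "filter_genes_bulk",
    "filter_genes_sc",
    "tmm_factors",
    "log2_cpm",
]


class EmptyFilterError(ValueError):
    """Raised when a QC filter would remove every cell or sample."""


@dataclass
class CountMatrix:
    """Integer gene-by-column count matrix.

    Parameters
    ----------
    values
        ``(n_genes, n_columns)`` non-negative integer array, dense
        ``numpy.ndarray`` or ``scipy.sparse`` matrix.
    genes
        Gene symbols (unique).
    columns
        Sample or cell identifiers (unique).
    norm_factors
        Optional per-column TMM factors; geometric mean one.
    """

    values: np.ndarray | sp.spmatrix
    genes: pd.Index
    columns: pd.Index
    norm_factors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.columns = pd.Index(self.columns, name="column")
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.columns)} columns"
            )
        if self.norm_factors is not None:
            self.norm_factors = np.asarray(self.norm_factors, dtype=float)
            if self.norm_factors.shape != (len(self.columns),):
                raise ValueError("norm_factors length must equal number of columns")
            if np.any(self.norm_factors <= 0):
                raise ValueError("norm_factors must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def lib_sizes(self) -> np.ndarray:
        """Per-column library sizes (raw column sums)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel().astype(float)
        return self.values.sum(axis=0).astype(float)

    def effective_lib_sizes(self) -> np.ndarray:
        """Library sizes multiplied by TMM factors when present."""
        libs = self.lib_sizes
        if self.norm_factors is not None:
            libs = libs * self.norm_factors
        return libs

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.genes, columns=self.columns)

    # -- subsetting ------------------------------------------------------
    def subset_genes(self, keep: np.ndarray | Sequence[bool]) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            values=self.values[idx, :],
            genes=self.genes[idx],
            norm_factors=self.norm_factors,
        )

    def subset_columns(self, keep: np.ndarray | Sequence[bool]) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        nf = self.norm_factors[idx] if self.norm_factors is not None else None
        return replace(
            self, values=self.values[:, idx], columns=self.columns[idx], norm_factors=nf
        )

    def with_norm_factors(self, factors: np.ndarray) -> "CountMatrix":
        return replace(self, norm_factors=np.asarray(factors, dtype=float))


# ---------------------------------------------------------------------------
# cell-level QC
# ---------------------------------------------------------------------------


def filter_cells(
    counts: CountMatrix,
    *,
    min_reads: int = 500,
    min_genes: int = 500,
    max_mito_pct: float = 20.0,
    outlier_k: float = 3.0,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Filter single cells on reads, genes detected and mitochondrial content.

    Cells are removed when they have fewer than ``min_reads`` total reads,
    fewer than ``min_genes`` genes detected, a mitochondrial percentage
    above ``max_mito_pct``, or exceptionally high reads/genes detected
    (above median + ``outlier_k`` * MAD on the log10 scale, the doublet
    guard).  Returns the retained matrix and a per-cell QC report with
    pass flags and failure reasons.
    """
    dense = counts.values
    if sp.issparse(dense):
        reads = np.asarray(dense.sum(axis=0)).ravel().astype(float)
        genes_detected = np.asarray((dense > 0).sum(axis=0)).ravel().astype(float)
        mito_mask = counts.genes.str.lower().str.startswith(mito_prefix.lower())
        mito_reads = np.asarray(dense[np.flatnonzero(mito_mask), :].sum(axis=0)).ravel()
    else:
        reads = dense.sum(axis=0).astype(float)
        genes_detected = (dense > 0).sum(axis=0).astype(float)
        mito_mask = counts.genes.str.lower().str.startswith(mito_prefix.lower())
        mito_reads = dense[np.asarray(mito_mask), :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(reads > 0, 100.0 * mito_reads / np.maximum(reads, 1), 0.0)

    def _upper_cut(x: np.ndarray) -> float:
        lx = np.log10(np.maximum(x, 1.0))
        med = np.median(lx)
        mad = np.median(np.abs(lx - med))
        return float(med + outlier_k * mad)

    read_cut = _upper_cut(reads)
    gene_cut = _upper_cut(genes_detected)

    reasons: list[str] = []
    passed = np.ones(counts.n_columns, dtype=bool)
    for i in range(counts.n_columns):
        why = []
        if reads[i] < min_reads:
            why.append("min_reads")
        if genes_detected[i] < min_genes:
            why.append("min_genes")
        if mito_pct[i] > max_mito_pct:
            why.append("max_mito")
        if np.log10(max(reads[i], 1.0)) > read_cut:
            why.append("outlier_reads")
        if np.log10(max(genes_detected[i], 1.0)) > gene_cut:
            why.append("outlier_genes")
        passed[i] = not why
        reasons.append(";".join(why))

    report = pd.DataFrame(
        {
            "reads": reads,
            "genes_detected": genes_detected.astype(int),
            "mito_pct": mito_pct,
            "pass": passed,
            "reason": reasons,
        },
        index=counts.columns,
    )
    if not passed.any():
        raise EmptyFilterError("cell QC removed every cell")
    n_removed = int((~passed).sum())
    if n_removed:
        logger.info("filter_cells removed %d of %d cells", n_removed, counts.n_columns)
    return counts.subset_columns(passed), report


# ---------------------------------------------------------------------------
# gene-level filters
# ---------------------------------------------------------------------------


def filter_genes_sc(
    counts: CountMatrix,
    sample_labels: Sequence,
    *,
    min_cell_fraction: float = 0.01,
) -> CountMatrix:
    """Keep genes detected in at least ``min_cell_fraction`` of cells of
    *every* sample (genes below the fraction in any one sample are removed).
    """
    labels = np.asarray(sample_labels)
    if labels.shape[0] != counts.n_columns:
        raise ValueError("one sample label per cell required")
    detected = counts.values > 0
    keep = np.ones(counts.n_genes, dtype=bool)
    for lab in pd.unique(labels):
        cols = np.flatnonzero(labels == lab)
        if sp.issparse(detected):
            frac = np.asarray(detected[:, cols].sum(axis=1)).ravel() / len(cols)
        else:
            frac = detected[:, cols].mean(axis=1)
        keep &= frac >= min_cell_fraction
    return counts.subset_genes(keep)


def filter_genes_bulk(
    counts: CountMatrix,
    *,
    min_cpm: float = 0.4,
    min_samples: int = 3,
) -> CountMatrix:
    """Keep genes achieving ``min_cpm`` counts-per-million in at least
    ``min_samples`` samples (CPM on raw library sizes)."""
    if counts.n_columns < min_samples:
        raise ValueError("fewer columns than min_samples")
    libs = counts.lib_sizes
    if np.any(libs <= 0):
        raise ValueError("zero library size column present")
    cpm = counts.to_dense() / libs * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return counts.subset_genes(keep)


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------


def _quantile_factor(dense: np.ndarray, libs: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.percentile(dense, 100 * p, axis=0) / libs


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Single-pair TMM factor (log2 scale weighting, double trim)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.nansum(log_r[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    lib_sizes: np.ndarray | None = None,
    *,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_column: int | None = None,
) -> np.ndarray:
    """TMM normalisation factors, rescaled to geometric mean one.

    The reference column is the one whose upper-quartile CPM is closest to
    the mean upper quartile.  M-values (log2 ratios) are trimmed by
    ``trim_m`` on each side and A-values (mean log2 abundance) by
    ``trim_a``; the factor is the precision-weighted mean of the retained
    M-values, with weights the inverse asymptotic (delta-method) variance.
    """
    if isinstance(counts, CountMatrix):
        dense = counts.to_dense().astype(float)
        libs = counts.lib_sizes if lib_sizes is None else np.asarray(lib_sizes, float)
    else:
        dense = np.asarray(counts, dtype=float)
        libs = (
            dense.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
        )
    if np.any(libs <= 0):
        bad = np.flatnonzero(libs <= 0)
        raise ValueError(f"zero library size in column(s) {bad.tolist()}")
    n_col = dense.shape[1]
    if ref_column is None:
        f75 = _quantile_factor(dense, libs)
        if np.median(f75) < 1e-20:
            ref_column = int(np.argmax(dense.sum(axis=0)))
        else:
            ref_column = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(n_col)
    for j in range(n_col):
        factors[j] = _tmm_pair(
            dense[:, j], dense[:, ref_column], libs[j], libs[ref_column], trim_m, trim_a
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# log2 counts-per-million
# ---------------------------------------------------------------------------


def log2_cpm(
    counts: CountMatrix | np.ndarray,
    *,
    prior_count: float = 1.0,
    lib_sizes: np.ndarray | None = None,
    use_norm_factors: bool = True,
) -> pd.DataFrame | np.ndarray:
    """log2 counts-per-million with a depth-scaled prior count.

    For effective library sizes ``L'_j`` the per-column prior is
    ``p_j = prior_count * L'_j / mean(L')`` and

    ``log2cpm[g, j] = log2((c[g, j] + p_j) / (L'_j + 2 p_j) * 1e6)``.

    Scaling the prior with depth keeps zero-count genes comparable across
    columns of unequal depth.  Returns a DataFrame when given a
    :class:`CountMatrix` (dense output; single-cell matrices are
    densified).
    """
    if isinstance(counts, CountMatrix):
        dense = counts.to_dense().astype(float)
        libs = counts.effective_lib_sizes() if use_norm_factors else counts.lib_sizes
        if lib_sizes is not None:
            libs = np.asarray(lib_sizes, float)
        out = _log2_cpm_array(dense, libs, prior_count)
        return pd.DataFrame(out, index=counts.genes, columns=counts.columns)
    dense = np.asarray(counts, dtype=float)
    libs = dense.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    return _log2_cpm_array(dense, libs, prior_count)


def _log2_cpm_array(dense: np.ndarray, libs: np.ndarray, prior: float) -> np.ndarray:
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    pj = prior * libs / libs.mean()
    return np.log2((dense + pj) / (libs + 2.0 * pj) * 1e6)
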