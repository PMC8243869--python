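"""Peak processing, differential accessibility and expression integration.

Peaks called per cell population are merged (book-ended intervals merge
by default), peaks overlapping blacklisted regions are removed entirely,
and read counts per merged peak feed a negative-binomial exact-test
pipeline: library sizes are TMM-normalised, counts are quantile-adjusted
to a common library size ("pseudo-counts"), a common dispersion is
estimated by conditional maximum likelihood, and each peak is tested
with a two-sided conditional exact test on the group sums.  Peaks with
BH FDR < 0.05 are differentially accessible (DA).

TSS-centric summaries: descriptive intensities are log2(RPKM + 1); peaks
are annotated with their nearest transcription start site and binned at
0.5 / 2.5 / 10 kb; a metagene profile averages peak-restricted coverage
from 5 kb upstream of the TSS to 1 kb downstream of the transcription
termination site; TSS-neighbourhood accessibility sums peak counts
(clipped to the window) within +-10 kb of each TSS, ignoring reads
outside called peaks.  DA peaks are matched with the expression
fold-change of their nearest gene, summarised per distance bin as
quadrant counts with the regression slope and Pearson R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from epilineage.expression_core import CountMatrix, filter_genes_bulk, tmm_factors
from epilineage.io_formats import Interval

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "DIST_BIN_LABELS",
    "merge_peaks",
    "subtract_blacklist",
    "peak_intensity",
    "annotate_nearest_tss",
    "estimate_common_dispersion",
    "exact_test_da",
    "metagene_profile",
    "MetageneProfile",
    "tss_neighborhood_accessibility",
    "signature_accessibility_compare",
    "AccessibilityComparison",
    "integrate_da_expression",
    "expression_log2fc",
    "overlap_fraction",
]

DIST_BIN_LABELS = ("<=0.5kb", "0.5-2.5kb", "2.5-10kb", ">10kb")
_DIST_BIN_EDGES = (500, 2500, 10000)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PeakSet:
    """Merged peaks with per-sample read counts.

    ``peaks`` is indexed by peak id with columns ``chrom, start, end``
    (0-based half-open, sorted, pairwise non-overlapping); ``counts`` is
    peak-by-sample; ``lib_sizes`` are the per-sample sequencing depths
    (total reads in peaks unless supplied externally).
    """

    peaks: pd.DataFrame
    counts: pd.DataFrame
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.peaks.index.equals(self.counts.index):
            raise ValueError("peaks and counts must share an index")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("degenerate peak interval")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)

    @property
    def lengths(self) -> pd.Series:
        return (self.peaks["end"] - self.peaks["start"]).astype(float)

    def intervals(self) -> list[Interval]:
        return [
            Interval(c, int(s), int(e))
            for c, s, e in self.peaks[["chrom", "start", "end"]].itertuples(index=False)
        ]


# ---------------------------------------------------------------------------
# interval operations
# ---------------------------------------------------------------------------


def merge_peaks(
    interval_lists: Iterable[Iterable[Interval]],
    *,
    bookended: bool = True,
) -> list[Interval]:
    """Union of per-population peak calls with overlap merging.

    Book-ended intervals (gap 0) merge by default; pass
    ``bookended=False`` for the strict-overlap dialect.  Output is
    sorted by (chrom, start).
    """
    pool: list[Interval] = [iv for lst in interval_lists for iv in lst]
    if not pool:
        return []
    pool.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[Interval] = []
    cur = pool[0]
    for iv in pool[1:]:
        joins = iv.chrom == cur.chrom and (
            iv.start <= cur.end if bookended else iv.start < cur.end
        )
        if joins:
            cur = Interval(cur.chrom, cur.start, max(cur.end, iv.end))
        else:
            out.append(cur)
            cur = iv
    out.append(cur)
    return out


def _overlap_mask(
    intervals: Sequence[Interval], others: Sequence[Interval]
) -> np.ndarray:
    """Boolean mask: interval i overlaps (>= 1 bp) any interval in others."""
    mask = np.zeros(len(intervals), dtype=bool)
    by_chrom: dict[str, list[Interval]] = {}
    for iv in others:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    prepared = {}
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in lst])
        ends = np.array([iv.end for iv in lst])
        prepared[chrom] = (starts, np.maximum.accumulate(ends))
    for i, iv in enumerate(intervals):
        if iv.chrom not in prepared:
            continue
        starts, prefix_max_end = prepared[iv.chrom]
        j = np.searchsorted(starts, iv.end, side="left")  # others with start < end
        if j > 0 and prefix_max_end[j - 1] > iv.start:
            mask[i] = True
    return mask


def subtract_blacklist(
    intervals: Sequence[Interval], blacklist: Sequence[Interval]
) -> list[Interval]:
    """Remove (whole) peaks overlapping any blacklisted region by >= 1 bp."""
    if not blacklist:
        return list(intervals)
    mask = _overlap_mask(intervals, blacklist)
    removed = int(mask.sum())
    if removed:
        logger.info("blacklist removed %d of %d peaks", removed, len(intervals))
    return [iv for iv, hit in zip(intervals, mask) if not hit]


def overlap_fraction(
    intervals: Sequence[Interval], annotation: Sequence[Interval]
) -> float:
    """Fraction of intervals overlapping an annotation set (e.g. repeats)."""
    if not intervals:
        return float("nan")
    return float(_overlap_mask(intervals, annotation).mean())


# ---------------------------------------------------------------------------
# descriptive intensities
# ---------------------------------------------------------------------------


def peak_intensity(
    counts: pd.DataFrame,
    lengths: pd.Series | np.ndarray,
    lib_sizes: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """log2(RPKM + 1) per peak per sample."""
    lengths = np.asarray(lengths, float)
    libs = np.asarray(lib_sizes, float)
    if np.any(lengths <= 0):
        raise ValueError("zero-length peak")
    rpkm = counts.to_numpy(float) / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)
    return pd.DataFrame(np.log2(rpkm + 1.0), index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# nearest-TSS annotation
# ---------------------------------------------------------------------------


def _distance_bin(d: float) -> str:
    if d <= _DIST_BIN_EDGES[0]:
        return DIST_BIN_LABELS[0]
    if d <= _DIST_BIN_EDGES[1]:
        return DIST_BIN_LABELS[1]
    if d <= _DIST_BIN_EDGES[2]:
        return DIST_BIN_LABELS[2]
    return DIST_BIN_LABELS[3]


def annotate_nearest_tss(
    peaks: pd.DataFrame | Sequence[Interval],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate each peak with its nearest gene TSS and a distance bin.

    Distance is 0 when a TSS lies inside the (half-open) peak; otherwise
    the gap from the TSS to the nearest covered base.  Ties go to the
    lexicographically smallest gene symbol.  Peaks on chromosomes with
    no annotated genes get infinite distance (binned ">10kb").
    """
    if not isinstance(peaks, pd.DataFrame):
        peaks = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end) for iv in peaks],
            columns=["chrom", "start", "end"],
        )
    out_gene: list[object] = []
    out_dist: list[float] = []
    by_chrom = {}
    for chrom, grp in genes.groupby("chrom"):
        g = grp.sort_values(["tss", "symbol"])
        by_chrom[chrom] = (g["tss"].to_numpy(), g["symbol"].to_numpy())
    for chrom, start, end in peaks[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in by_chrom:
            out_gene.append(None)
            out_dist.append(np.inf)
            continue
        tss, syms = by_chrom[chrom]
        lo = np.searchsorted(tss, start, side="left")
        hi = np.searchsorted(tss, end, side="left")
        if hi > lo:  # at least one TSS inside the peak
            best = 0.0
            cands = syms[lo:hi]
        else:
            dists = []
            if lo > 0:
                dists.append(start - tss[lo - 1])
            if lo < len(tss):
                dists.append(tss[lo] - (end - 1))
            best = float(min(dists))
            cands = syms[np.abs(np.where(tss < start, start - tss, tss - (end - 1))) == best]
        out_gene.append(min(cands))
        out_dist.append(best)
    res = peaks[["chrom", "start", "end"]].copy()
    res["gene"] = out_gene
    res["distance"] = out_dist
    res["bin"] = [_distance_bin(d) for d in out_dist]
    return res


# ---------------------------------------------------------------------------
# quantile adjustment to a common library size
# ---------------------------------------------------------------------------


def _q2q_nbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, phi: float
) -> np.ndarray:
    """Quantile-match counts between library sizes under NB(mean, phi).

    Average of a normal and a gamma continuous approximation to the NB
    quantile function, matching each observation's tail probability at
    its own mean to the common-library mean.
    """
    x = np.asarray(x, float)
    in_mu = np.maximum(np.asarray(input_mean, float), 1e-4)
    out_mu = np.maximum(np.asarray(output_mean, float), 1e-4)
    ri = 1.0 + phi * in_mu
    vi = in_mu * ri
    ro = 1.0 + phi * out_mu
    vo = out_mu * ro
    upper = x >= in_mu
    q = np.empty_like(x)
    for mask, tail in ((upper, False), (~upper, True)):
        if not mask.any():
            continue
        xm, imu, omu = x[mask], in_mu[mask], out_mu[mask]
        vim, vom = vi[mask], vo[mask]
        rim, rom = ri[mask], ro[mask]
        if tail:
            p_norm = stats.norm.cdf(xm, loc=imu, scale=np.sqrt(vim))
            p_gam = stats.gamma.cdf(xm, a=imu / rim, scale=rim)
            q1 = stats.norm.ppf(p_norm, loc=omu, scale=np.sqrt(vom))
            q2 = stats.gamma.ppf(p_gam, a=omu / rom, scale=rom)
        else:
            p_norm = stats.norm.sf(xm, loc=imu, scale=np.sqrt(vim))
            p_gam = stats.gamma.sf(xm, a=imu / rim, scale=rim)
            q1 = stats.norm.isf(p_norm, loc=omu, scale=np.sqrt(vom))
            q2 = stats.gamma.isf(p_gam, a=omu / rom, scale=rom)
        q[mask] = (q1 + q2) / 2.0
    return np.maximum(q, 0.0)


def _equalize_lib_sizes(
    counts: np.ndarray, lib_eff: np.ndarray, phi: float
) -> tuple[np.ndarray, float]:
    """Pseudo-counts quantile-adjusted to the geometric-mean library size."""
    common = float(np.exp(np.mean(np.log(lib_eff))))
    lam = counts.sum(axis=1) / lib_eff.sum()
    input_mean = np.outer(lam, lib_eff)
    output_mean = np.outer(lam, np.full(counts.shape[1], common))
    pseudo = _q2q_nbinom(counts, input_mean, output_mean, phi)
    return pseudo, common


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood)
# ---------------------------------------------------------------------------


def _cond_log_lik(pseudo: np.ndarray, groups: np.ndarray, phi: float) -> float:
    """Summed conditional NB log-likelihood given per-group totals."""
    r = 1.0 / phi
    total = 0.0
    for lev in pd.unique(groups):
        y = pseudo[:, groups == lev]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(
                special.gammaln(y + r).sum(axis=1)
                - n * special.gammaln(r)
                + special.gammaln(n * r)
                - special.gammaln(z + n * r)
            )
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame | np.ndarray,
    groups: Sequence,
    *,
    lib_sizes: np.ndarray | None = None,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Library sizes are TMM-normalised and counts quantile-adjusted to the
    geometric-mean library; the dispersion maximises the conditional
    log-likelihood given per-group totals.  Two rounds of adjustment /
    maximisation are run (the pseudo-counts depend on the dispersion).
    Falls back to a moment estimate when the optimiser fails.  With a
    single sample per group the conditional likelihood carries no
    information and a user-supplied dispersion is required.
    """
    dense = counts.to_numpy(float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    if (sizes < 2).all():
        raise ValueError("dispersion cannot be estimated with one sample per group")
    libs = dense.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    factors = tmm_factors(dense, libs)
    lib_eff = libs * factors
    keep = dense.sum(axis=1) > 0
    dense = dense[keep]

    phi = 0.01
    for _ in range(2):
        pseudo, _common = _equalize_lib_sizes(dense, lib_eff, phi)
        try:
            res = optimize.minimize_scalar(
                lambda delta: -_cond_log_lik(pseudo, groups, delta / (1.0 - delta)),
                bounds=(1e-4, 0.95),
                method="bounded",
                options={"xatol": 1e-6},
            )
            delta = float(res.x)
            phi = delta / (1.0 - delta)
        except Exception:  # numerical failure: method-of-moments fallback
            logger.warning("conditional ML failed; using moment estimate")
            mu = pseudo.mean(axis=1)
            v = pseudo.var(axis=1, ddof=1)
            ratio = (v - mu) / np.maximum(mu**2, 1e-8)
            phi = float(np.clip(np.median(ratio), 1e-4, 10.0))
    return float(phi)


# ---------------------------------------------------------------------------
# conditional exact test
# ---------------------------------------------------------------------------


def _double_tail_p(s1: int, total: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p for the split (s1, total - s1).

    Under a common NB mean and equalised library sizes, the group-1 sum
    conditional on the total follows the NB-split distribution
    ``P(k) ~ C(k + n1/phi - 1, k) * C(total - k + n2/phi - 1, total - k)``
    (binomial split in the Poisson limit).  The p-value sums the
    probability of every outcome at most as probable as the observed one.
    """
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if phi < 1e-10:
        logw = (
            special.gammaln(total + 1)
            - special.gammaln(k + 1)
            - special.gammaln(total - k + 1)
            + k * np.log(n1 / (n1 + n2))
            + (total - k) * np.log(n2 / (n1 + n2))
        )
    else:
        r1, r2 = n1 / phi, n2 / phi
        logw = (
            special.gammaln(k + r1)
            - special.gammaln(k + 1)
            + special.gammaln(total - k + r2)
            - special.gammaln(total - k + 1)
        )
    logw = logw - special.logsumexp(logw)
    obs = logw[s1]
    keep = logw <= obs + 1e-10
    return float(min(np.exp(special.logsumexp(logw[keep])), 1.0))


def exact_test_da(
    peakset: PeakSet | pd.DataFrame,
    groups: Sequence,
    phi: float,
    *,
    lib_sizes: np.ndarray | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Conditional NB exact test per peak between two groups.

    Library sizes are TMM-normalised, counts are quantile-adjusted to the
    common library size, and group sums are compared with the two-sided
    conditional exact test at dispersion ``phi``.  log2FC sign is
    first group minus second; BH FDR across peaks; ``da`` flags
    FDR < ``fdr``.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    if isinstance(peakset, PeakSet):
        counts = peakset.counts
        libs = peakset.lib_sizes.to_numpy(float)
    else:
        counts = peakset
        libs = (
            counts.sum(axis=0).to_numpy(float)
            if lib_sizes is None
            else np.asarray(lib_sizes, float)
        )
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1 = groups == levels[0]
    g2 = groups == levels[1]
    n1, n2 = int(g1.sum()), int(g2.sum())

    dense = counts.to_numpy(float)
    factors = tmm_factors(dense, libs)
    lib_eff = libs * factors
    pseudo, _common = _equalize_lib_sizes(dense, lib_eff, phi)
    s1 = np.round(pseudo[:, g1].sum(axis=1)).astype(np.int64)
    s2 = np.round(pseudo[:, g2].sum(axis=1)).astype(np.int64)

    pvals = np.array(
        [_double_tail_p(a, a + b, n1, n2, phi) for a, b in zip(s1, s2)]
    )
    log2fc = np.log2((s1 / n1 + 0.5) / (s2 / n2 + 0.5))
    padj = _bh(pvals)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "fdr": padj,
            "da": padj < fdr,
        },
        index=counts.index,
    )


def _bh(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Average peak-restricted accessibility across gene bodies.

    ``values`` runs from ``upstream`` bp before the TSS (fixed-width
    flank bins), across a length-scaled gene body, to ``downstream`` bp
    past the TTS; minus-strand genes are flipped so the TSS is on the
    left.
    """

    values: np.ndarray
    section: np.ndarray  # "upstream" / "body" / "downstream" per bin
    n_genes: int
    n_skipped: int


def metagene_profile(
    peaks: pd.DataFrame,
    peak_values: np.ndarray | pd.Series,
    genes: pd.DataFrame,
    *,
    upstream: int = 5000,
    downstream: int = 1000,
    body_bins: int = 100,
    flank_bin: int = 100,
) -> MetageneProfile:
    """Metagene accessibility from TSS - upstream to TTS + downstream.

    ``peak_values`` is one scalar per peak (e.g. mean RPKM); base pairs
    outside peaks contribute zero.  Genes shorter than one base per body
    bin are skipped with a warning count.
    """
    vals = np.asarray(peak_values, float)
    by_chrom = {}
    for chrom, grp in peaks.reset_index(drop=True).groupby("chrom"):
        order = grp.sort_values("start")
        ends = order["end"].to_numpy(float)
        by_chrom[chrom] = (
            order["start"].to_numpy(float),
            ends,
            np.maximum.accumulate(ends),  # handles overlapping peaks
            vals[order.index.to_numpy()],
        )

    def interval_mean(chrom: str, lo: float, hi: float) -> float:
        if hi <= lo or chrom not in by_chrom:
            return 0.0
        starts, ends, ends_cummax, v = by_chrom[chrom]
        i = np.searchsorted(ends_cummax, lo, side="right")
        j = np.searchsorted(starts, hi, side="left")
        if j <= i:
            return 0.0
        ov = np.minimum(ends[i:j], hi) - np.maximum(starts[i:j], lo)
        return float((np.maximum(ov, 0.0) * v[i:j]).sum() / (hi - lo))

    n_up = upstream // flank_bin
    n_down = downstream // flank_bin
    n_bins = n_up + body_bins + n_down
    acc = np.zeros(n_bins)
    n_genes = 0
    n_skipped = 0
    for row in genes.itertuples(index=False):
        body_len = row.end - row.start
        if body_len < body_bins:
            n_skipped += 1
            continue
        plus = row.strand == "+"
        # profile coordinate u in [-upstream, body_len + downstream);
        # genome position = tss + u for '+', tss - u for '-'
        tss = float(row.tss)
        edges = np.concatenate(
            [
                np.arange(-upstream, 0 + 1, flank_bin, dtype=float),
                np.linspace(0, body_len, body_bins + 1)[1:],
                body_len + np.arange(flank_bin, downstream + 1, flank_bin, dtype=float),
            ]
        )
        prof = np.empty(n_bins)
        for b in range(n_bins):
            u0, u1 = edges[b], edges[b + 1]
            if plus:
                lo, hi = tss + u0, tss + u1
            else:
                lo, hi = tss - u1 + 1, tss - u0 + 1
            prof[b] = interval_mean(row.chrom, lo, hi)
        acc += prof
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no gene long enough for the requested body bins")
    section = np.array(
        ["upstream"] * n_up + ["body"] * body_bins + ["downstream"] * n_down
    )
    return MetageneProfile(
        values=acc / n_genes, section=section, n_genes=n_genes, n_skipped=n_skipped
    )


# ---------------------------------------------------------------------------
# TSS-neighbourhood accessibility
# ---------------------------------------------------------------------------


def tss_neighborhood_accessibility(
    peakset: PeakSet,
    genes: pd.DataFrame,
    *,
    flank: int = 10000,
    clip: bool = True,
) -> pd.DataFrame:
    """Peak-restricted log2(RPKM + 1) in the +-``flank`` TSS window.

    Counts of peaks intersecting ``[TSS - flank, TSS + flank)`` are
    summed per sample (scaled by the overlapping fraction of the peak
    when ``clip`` is true, assuming length-uniform reads within a peak;
    reads outside called peaks are ignored by construction).  RPKM uses
    the full window length.
    """
    window_kb = 2.0 * flank / 1e3
    libs = peakset.lib_sizes.to_numpy(float)
    counts = peakset.counts.to_numpy(float)
    lengths = peakset.lengths.to_numpy()
    by_chrom = {}
    for chrom, grp in peakset.peaks.reset_index().groupby("chrom"):
        order = grp.sort_values("start")
        ends = order["end"].to_numpy(float)
        by_chrom[chrom] = (
            order["start"].to_numpy(float),
            ends,
            np.maximum.accumulate(ends),
            order.index.to_numpy(),
        )
    rows = np.zeros((len(genes), counts.shape[1]))
    for gi, row in enumerate(genes.itertuples(index=False)):
        lo, hi = row.tss - flank, row.tss + flank
        if row.chrom not in by_chrom:
            continue
        starts, ends, ends_cummax, ridx = by_chrom[row.chrom]
        i = np.searchsorted(ends_cummax, lo, side="right")
        j = np.searchsorted(starts, hi, side="left")
        if j <= i:
            continue
        sel = ridx[i:j]
        ov = np.maximum(
            np.minimum(ends[i:j], hi) - np.maximum(starts[i:j], lo), 0.0
        )
        w = ov / lengths[sel] if clip else (ov > 0).astype(float)
        rows[gi] = w @ counts[sel]
    rpkm = rows / window_kb / (libs[None, :] / 1e6)
    return pd.DataFrame(
        np.log2(rpkm + 1.0), index=genes["symbol"].to_numpy(), columns=peakset.counts.columns
    )


# ---------------------------------------------------------------------------
# signature accessibility comparison
# ---------------------------------------------------------------------------


@dataclass
class AccessibilityComparison:
    coefficient: float
    tstat: float
    p: float
    n_genes: int


def signature_accessibility_compare(
    intensities: pd.DataFrame,
    gene_set: Sequence[str],
    sample_groups: Sequence,
) -> AccessibilityComparison:
    """Linear-model comparison of signature-gene accessibility.

    Observations are gene-level mean intensities per population (two
    populations); the model regresses intensity on the population
    indicator.  The coefficient is first-population minus second;
    swapping labels negates it with identical p.
    """
    groups = np.asarray(sample_groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two populations required")
    present = intensities.index.isin(set(gene_set))
    if present.sum() < 3:
        raise ValueError("fewer than 3 signature genes present")
    sub = intensities.loc[present]
    m1 = sub.loc[:, groups == levels[0]].mean(axis=1).to_numpy()
    m2 = sub.loc[:, groups == levels[1]].mean(axis=1).to_numpy()
    y = np.concatenate([m1, m2])
    x = np.concatenate([np.ones_like(m1), np.zeros_like(m2)])
    if np.var(y) == 0:
        return AccessibilityComparison(0.0, 0.0, 1.0, int(present.sum()))
    res = stats.linregress(x, y)
    return AccessibilityComparison(
        coefficient=float(res.slope),
        tstat=float(res.slope / res.stderr) if res.stderr > 0 else 0.0,
        p=float(res.pvalue),
        n_genes=int(present.sum()),
    )


# ---------------------------------------------------------------------------
# DA-expression integration
# ---------------------------------------------------------------------------


def expression_log2fc(
    counts: CountMatrix,
    groups: Sequence,
    *,
    min_cpm: float = 0.4,
    min_samples: int = 3,
) -> pd.Series:
    """Gene-wise log2 fold-changes between two groups from bulk counts.

    Filter (CPM) -> TMM -> group-pooled means on effective library sizes
    with a 0.5-count offset (the NB GLM group-mean MLE with library-size
    offsets reduces to pooled means for a two-group design).  Sign is
    first group minus second.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    filtered = filter_genes_bulk(counts, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    lib_eff = filtered.lib_sizes * factors
    dense = filtered.to_dense().astype(float)
    g1, g2 = groups == levels[0], groups == levels[1]
    mu1 = (dense[:, g1].sum(axis=1) + 0.5) / lib_eff[g1].sum()
    mu2 = (dense[:, g2].sum(axis=1) + 0.5) / lib_eff[g2].sum()
    return pd.Series(np.log2(mu1 / mu2), index=filtered.genes, name="log2fc")


def integrate_da_expression(
    da: pd.DataFrame,
    annotation: pd.DataFrame,
    expr_log2fc: pd.Series,
) -> pd.DataFrame:
    """Quadrant counts, slope and Pearson R per TSS-distance bin.

    Restricts to DA peaks, matches each with the expression fold-change
    of its nearest gene, and per distance bin reports the counts of the
    four (accessibility change, expression change) sign quadrants, the
    OLS slope of expression change on accessibility change, and the
    Pearson correlation.  Bins without DA peaks yield an empty (NaN)
    row.
    """
    merged = da.join(annotation[["gene", "bin"]], how="inner")
    merged = merged[merged["da"] & merged["gene"].notna()]
    merged["expr_log2fc"] = merged["gene"].map(expr_log2fc)
    merged = merged[merged["expr_log2fc"].notna()]
    rows = []
    for label in DIST_BIN_LABELS:
        sub = merged[merged["bin"] == label]
        dA = sub["log2fc"].to_numpy()
        dE = sub["expr_log2fc"].to_numpy()
        nz = dE != 0
        q_pp = int(((dA > 0) & (dE > 0))[nz].sum())
        q_pm = int(((dA > 0) & (dE < 0))[nz].sum())
        q_mp = int(((dA < 0) & (dE > 0))[nz].sum())
        q_mm = int(((dA < 0) & (dE < 0))[nz].sum())
        if len(sub) >= 2 and np.std(dA) > 0 and np.std(dE) > 0:
            slope = float(np.cov(dA, dE)[0, 1] / np.var(dA, ddof=1))
            r = float(np.corrcoef(dA, dE)[0, 1])
        else:
            slope, r = float("nan"), float("nan")
        rows.append((label, len(sub), q_pp, q_pm, q_mp, q_mm, slope, r))
    return pd.DataFrame(
        rows,
        columns=["bin", "n_da_peaks", "up_up", "up_down", "down_up", "down_down", "slope", "r"],
    ).set_index("bin")
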