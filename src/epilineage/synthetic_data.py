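"""Synthetic bulk RNA-seq, scRNA-seq and ATAC-seq data with planted truth.

The generator emulates the statistical structure the analysis assumes:

* **Bulk** counts are negative binomial with mean
  ``library x relative-abundance x fold-change^membership`` where
  membership is +1 for a population's planted "up" genes and -1 for its
  "down" genes; sequencing lane adds a common multiplicative log-normal
  offset per lane.
* **Single cells** draw a log-normal library size, NB counts around a
  population mean profile, a Beta-sampled mitochondrial fraction and
  optional doublets (sums of two cells).  Planted positive markers are
  expressed at ``effect_size`` times baseline in their own lineage and
  near-silenced (``marker_off_scale`` times baseline) in the others —
  lineage markers in real epithelium are actively repressed off-lineage,
  which is what makes the ternary statistic place pure cells near the
  simplex vertices.  Intermediate cells interpolate two populations'
  log-mean profiles.
* **ATAC** peaks are placed near TSSs (promoter fraction) or uniformly
  (distal); per-peak accessibility log2 effects are drawn jointly with
  per-gene expression log2 effects from a bivariate normal with
  correlation ``rho``, so the planted accessibility-expression coupling
  is directly checkable.

Everything is deterministic given ``SimConfig.seed`` (numpy PCG64,
integer state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp

from epilineage.expression_core import CountMatrix
from epilineage.io_formats import Interval, build_gene_annotation
from epilineage.signature_derivation import LineageSignature

__all__ = [
    "SimConfig",
    "AtacConfig",
    "PlantedCounts",
    "SimConfigError",
    "SyntheticTruth",
    "AtacSim",
    "generate_bulk",
    "generate_sc",
    "generate_atac",
    "generate_structure_de",
    "signature_from_truth",
    "simulate_gene_annotation",
]


class SimConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class PlantedCounts:
    """Numbers of planted signature genes per set."""

    basal_up: int = 150
    lp_up: int = 100
    ml_up: int = 100
    basal_down: int = 100
    lp_down: int = 60
    ml_down: int = 60

    def total(self) -> int:
        return (
            self.basal_up
            + self.lp_up
            + self.ml_up
            + self.basal_down
            + self.lp_down
            + self.ml_down
        )


@dataclass(frozen=True)
class AtacConfig:
    """ATAC branch of the simulation.

    ``rho`` couples per-peak accessibility log2 effects to the nearest
    gene's expression log2 effect; ``effect_sd`` / ``expr_sd`` are the
    marginal standard deviations of those effects.
    """

    n_peaks: int = 5000
    promoter_fraction: float = 0.4
    rho: float = 0.6
    n_reps: int = 4
    dispersion: float = 0.2
    peak_mean: float = 100.0
    # accessibility effects between the structures are large (most peaks
    # reach significance); with small effects the DA selection would
    # truncate the effect distribution and distort the planted coupling
    effect_sd: float = 1.75
    expr_sd: float = 1.0
    blacklist_fraction: float = 0.02
    n_genes: int = 600
    expr_mean: float = 300.0
    expr_dispersion: float = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults: three populations (basal, LP, ML) with 4 bulk replicates
    each at ~2e6 reads, 300 cells per population at ~1e4 reads, planted
    fold-change 4, NB dispersion 0.1 (bulk) / 0.5 (single cell),
    mitochondrial fraction Beta(2, 38) (~5%), two sequencing lanes.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_population: int = 4
    n_cells_per_population: int = 300
    populations: tuple[str, ...] = ("basal", "lp", "ml")
    planted: PlantedCounts = field(default_factory=PlantedCounts)
    effect_size: float = 4.0
    dispersion_bulk: float = 0.1
    dispersion_sc: float = 0.5
    bulk_lib_lognormal: tuple[float, float] = (14.5, 0.1)
    sc_lib_lognormal: tuple[float, float] = (9.2, 0.2)
    baseline_sd: float = 1.25
    mito_beta: tuple[float, float] = (2.0, 38.0)
    n_mito_genes: int = 10
    doublet_rate: float = 0.0
    marker_off_scale: float = 0.01
    intermediates: tuple[tuple[str, str, float, int], ...] = ()
    planted_abundance_quantile: float = 0.0
    n_lanes: int = 2
    lane_sd: float = 0.1
    atac: AtacConfig = field(default_factory=AtacConfig)

    def validate(self) -> None:
        if self.planted.total() > self.n_genes:
            raise SimConfigError("more planted genes than genes")
        if self.effect_size <= 1 and self.planted.total() > 0:
            raise SimConfigError("effect_size must exceed 1 for planted genes")
        if not 0 <= self.doublet_rate < 0.5:
            raise SimConfigError("doublet_rate must lie in [0, 0.5)")
        if not 0 <= self.atac.rho <= 1:
            raise SimConfigError("rho must lie in [0, 1]")
        if self.n_samples_per_population < 3:
            raise SimConfigError("at least 3 replicates per population required")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset."""

    gene_sets: dict[str, list[str]] | None = None
    samples: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    pop_log2_expression: pd.DataFrame | None = None
    peak_log2fc: pd.Series | None = None
    expr_log2fc: pd.Series | None = None
    peak_gene: pd.Series | None = None


_SET_NAMES = ("basal_up", "lp_up", "ml_up", "basal_down", "lp_down", "ml_down")


def _plant_genes(
    config: SimConfig, rng: np.random.Generator, baseline: np.ndarray | None = None
) -> dict[str, list[str]]:
    """Assign planted membership; ``planted_abundance_quantile`` restricts
    planting to genes above that baseline-abundance quantile (signature
    genes derived from real data are detectably expressed by
    construction)."""
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    if baseline is not None and config.planted_abundance_quantile > 0:
        cut = np.quantile(baseline, config.planted_abundance_quantile)
        pool = np.flatnonzero(baseline >= cut)
    else:
        pool = np.arange(config.n_genes)
    if config.planted.total() > pool.size:
        raise SimConfigError("planted genes exceed the eligible pool")
    perm = pool[rng.permutation(pool.size)]
    sizes = [getattr(config.planted, name) for name in _SET_NAMES]
    sets: dict[str, list[str]] = {}
    offset = 0
    for name, size in zip(_SET_NAMES, sizes):
        sets[name] = [genes[i] for i in sorted(perm[offset : offset + size])]
        offset += size
    return sets


def _membership_matrix(
    genes: Sequence[str], gene_sets: dict[str, list[str]], populations: Sequence[str]
) -> np.ndarray:
    """Exponent matrix (genes x populations): +1 up, -1 down, 0 otherwise."""
    idx = {g: i for i, g in enumerate(genes)}
    M = np.zeros((len(genes), len(populations)))
    for p_i, pop in enumerate(populations):
        for g in gene_sets[f"{pop}_up"]:
            M[idx[g], p_i] = 1.0
        for g in gene_sets[f"{pop}_down"]:
            M[idx[g], p_i] = -1.0
    return M


def _rnb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with variance mu + phi*mu^2 (Poisson when phi ~ 0)."""
    mean = np.maximum(mean, 1e-12)
    if phi < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


# ---------------------------------------------------------------------------
# bulk RNA-seq
# ---------------------------------------------------------------------------


def generate_bulk(config: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Sorted-population bulk RNA-seq counts with planted signature genes.

    Returns the count matrix (genes x samples) and the truth: planted
    set membership, the sample table (population, lane) and each gene's
    log2 relative expression per population.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    baseline = rng.lognormal(0.0, config.baseline_sd, config.n_genes)
    gene_sets = _plant_genes(config, rng, baseline)
    M = _membership_matrix(genes, gene_sets, config.populations)

    samples = []
    for pop in config.populations:
        for rep in range(config.n_samples_per_population):
            samples.append((f"{pop}_{rep + 1}", pop, rep % config.n_lanes))
    sample_df = pd.DataFrame(samples, columns=["sample", "population", "lane"]).set_index(
        "sample"
    )
    lane_offsets = rng.normal(0.0, config.lane_sd, config.n_lanes)
    libs = rng.lognormal(*config.bulk_lib_lognormal, len(sample_df))

    counts = np.empty((config.n_genes, len(sample_df)), dtype=np.int64)
    for j, (pop, lane) in enumerate(zip(sample_df["population"], sample_df["lane"])):
        p_i = config.populations.index(pop)
        w = baseline * config.effect_size ** M[:, p_i]
        mu = libs[j] * (w / w.sum()) * np.exp(lane_offsets[lane])
        counts[:, j] = _rnb(rng, mu, config.dispersion_bulk)

    pop_log2 = pd.DataFrame(
        M * np.log2(config.effect_size), index=genes, columns=list(config.populations)
    )
    truth = SyntheticTruth(
        gene_sets=gene_sets, samples=sample_df, pop_log2_expression=pop_log2
    )
    return (
        CountMatrix(values=counts, genes=genes, columns=sample_df.index),
        truth,
    )


def signature_from_truth(truth: SyntheticTruth) -> LineageSignature:
    """Build a :class:`LineageSignature` from planted gene sets."""
    assert truth.gene_sets is not None
    pops = sorted({name.rsplit("_", 1)[0] for name in truth.gene_sets})
    # preserve canonical order basal, lp, ml when present
    canonical = [p for p in ("basal", "lp", "ml") if p in pops] + [
        p for p in pops if p not in ("basal", "lp", "ml")
    ]
    return LineageSignature(
        positive={p: list(truth.gene_sets[f"{p}_up"]) for p in canonical},
        negative={p: list(truth.gene_sets[f"{p}_down"]) for p in canonical},
    )


# ---------------------------------------------------------------------------
# single-cell RNA-seq
# ---------------------------------------------------------------------------


def _sc_profiles(
    config: SimConfig,
    genes: list[str],
    signatures: LineageSignature,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    base = rng.lognormal(0.0, config.baseline_sd, len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    profiles: dict[str, np.ndarray] = {}
    pops = signatures.populations
    for pop in pops:
        w = base.copy()
        for g in signatures.positive[pop]:
            if g in idx:
                w[idx[g]] *= config.effect_size
        for other in pops:
            if other == pop:
                continue
            for g in signatures.positive[other]:
                if g in idx:
                    w[idx[g]] *= config.marker_off_scale
        for g in signatures.negative.get(pop, []):
            if g in idx:
                w[idx[g]] /= config.effect_size
        profiles[pop] = w
    return profiles


def generate_sc(
    config: SimConfig, signatures: LineageSignature
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Single-cell counts for pure populations, intermediates and doublets.

    Intermediate groups (``config.intermediates`` entries
    ``(pop_a, pop_b, weight, n_cells)``) interpolate the two populations'
    log-mean profiles at the stated weight.  Doublets are sums of two
    sampled cells, flagged in the cell table.  The matrix includes
    ``n_mito_genes`` mitochondrial genes (``mt-*``) receiving a
    Beta-sampled fraction of each cell's library.
    """
    config.validate()
    if not signatures.populations:
        raise SimConfigError("signatures must be non-empty")
    rng = np.random.default_rng([config.seed, 1])
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    mito = [f"mt-{i + 1}" for i in range(config.n_mito_genes)]
    profiles = _sc_profiles(config, genes, signatures, rng)

    groups: list[tuple[str, np.ndarray, bool]] = []
    for pop in signatures.populations:
        groups.append((pop, profiles[pop], False))
    for pop_a, pop_b, weight, n_cells in config.intermediates:
        w = np.exp(
            weight * np.log(profiles[pop_a]) + (1.0 - weight) * np.log(profiles[pop_b])
        )
        groups.append((f"{pop_a}-{pop_b}-int", w, True))

    blocks = []
    labels = []
    inter_flags = []
    for name, w, is_int in groups:
        n_cells = (
            config.n_cells_per_population
            if not is_int
            else next(
                n for a, b, wt, n in config.intermediates if f"{a}-{b}-int" == name
            )
        )
        libs = rng.lognormal(*config.sc_lib_lognormal, n_cells)
        fmito = rng.beta(*config.mito_beta, n_cells)
        p = w / w.sum()
        mu_main = (1.0 - fmito)[None, :] * libs[None, :] * p[:, None]
        mu_mito = np.tile(
            (fmito * libs / config.n_mito_genes)[None, :], (config.n_mito_genes, 1)
        )
        mu = np.vstack([mu_main, mu_mito])
        blocks.append(_rnb(rng, mu, config.dispersion_sc))
        labels += [name] * n_cells
        inter_flags += [is_int] * n_cells

    counts = np.hstack(blocks)
    n_total = counts.shape[1]
    is_doublet = np.zeros(n_total, dtype=bool)
    n_doub = int(round(config.doublet_rate * n_total))
    if n_doub:
        targets = rng.choice(n_total, size=n_doub, replace=False)
        for t in targets:
            partner_pop = signatures.populations[
                rng.integers(len(signatures.populations))
            ]
            w = profiles[partner_pop]
            lib = rng.lognormal(*config.sc_lib_lognormal)
            mu = lib * w / w.sum()
            extra = _rnb(rng, mu, config.dispersion_sc)
            counts[: config.n_genes, t] += extra
            is_doublet[t] = True

    barcodes = [f"cell_{i:05d}" for i in range(n_total)]
    cell_df = pd.DataFrame(
        {
            "population": labels,
            "is_intermediate": inter_flags,
            "is_doublet": is_doublet,
        },
        index=pd.Index(barcodes, name="cell"),
    )
    cm = CountMatrix(
        values=sp.csr_matrix(counts), genes=genes + mito, columns=barcodes
    )
    truth = SyntheticTruth(
        gene_sets={f"{p}_up": list(signatures.positive[p]) for p in signatures.populations},
        cells=cell_df,
    )
    return cm, cell_df, truth


def generate_structure_de(
    seed: int,
    *,
    n_genes: int = 2000,
    n_de: int = 150,
    fold_change: float = 2.0,
    n_cells_per_group: int = 300,
    dispersion: float = 0.5,
    lib_lognormal: tuple[float, float] = (9.2, 0.2),
) -> tuple[CountMatrix, pd.DataFrame, list[str]]:
    """Two-structure (TEB vs duct) single-cluster DE simulation.

    The first ``n_de`` genes are up in the TEB group by ``fold_change``.
    Returns counts, a cell table (cluster, structure) and the planted DE
    gene list.
    """
    rng = np.random.default_rng([seed, 3])
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(0.0, 1.25, n_genes)
    de_genes = genes[:n_de]
    blocks = []
    labels = []
    for structure, boost in (("teb", fold_change), ("duct", 1.0)):
        w = base.copy()
        w[:n_de] *= boost
        p = w / w.sum()
        libs = rng.lognormal(*lib_lognormal, n_cells_per_group)
        mu = libs[None, :] * p[:, None]
        blocks.append(_rnb(rng, mu, dispersion))
        labels += [structure] * n_cells_per_group
    counts = np.hstack(blocks)
    barcodes = [f"cell_{i:05d}" for i in range(counts.shape[1])]
    cells = pd.DataFrame(
        {"cluster": "basal", "structure": labels},
        index=pd.Index(barcodes, name="cell"),
    )
    cm = CountMatrix(values=counts, genes=genes, columns=barcodes)
    return cm, cells, de_genes


# ---------------------------------------------------------------------------
# ATAC-seq
# ---------------------------------------------------------------------------


@dataclass
class AtacSim:
    """Simulated ATAC inputs: per-population peak calls, merged-peak
    counts, a blacklist, matched bulk expression counts and the truth."""

    peaks: pd.DataFrame
    peaks_by_population: dict[str, list[Interval]]
    counts: pd.DataFrame
    sample_groups: pd.Series
    blacklist: list[Interval]
    genes: pd.DataFrame
    expr_counts: CountMatrix
    expr_groups: pd.Series
    truth: SyntheticTruth


def simulate_gene_annotation(
    n_genes: int, rng: np.random.Generator, *, n_chroms: int = 3
) -> pd.DataFrame:
    """Lay genes with random lengths/strands along synthetic chromosomes."""
    rows = []
    per_chrom = int(np.ceil(n_genes / n_chroms))
    g = 0
    for c in range(n_chroms):
        pos = int(rng.integers(10_000, 30_000))
        for _ in range(per_chrom):
            if g >= n_genes:
                break
            length = int(rng.integers(2_000, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{g:04d}", f"chr{c + 1}", strand, pos, pos + length))
            pos += length + int(rng.integers(5_000, 40_000))
            g += 1
    df = pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "start", "end"])
    return build_gene_annotation(df)


def _nearest_gene_brute(
    peaks: list[tuple[str, int, int]], genes: pd.DataFrame
) -> tuple[list[str], np.ndarray]:
    """All-pairs nearest-TSS scan (generator-internal; small n)."""
    symbols = genes["symbol"].to_numpy()
    tss = genes["tss"].to_numpy()
    chroms = genes["chrom"].to_numpy()
    out_sym, out_d = [], []
    for chrom, start, end in peaks:
        on = chroms == chrom
        d = np.where(
            (tss >= start) & (tss < end),
            0,
            np.where(tss < start, start - tss, tss - (end - 1)),
        ).astype(float)
        d[~on] = np.inf
        best = d.min()
        cands = symbols[(d == best)]
        out_sym.append(min(cands))
        out_d.append(best)
    return out_sym, np.asarray(out_d)


def generate_atac(
    config: SimConfig, genes: pd.DataFrame | None = None
) -> AtacSim:
    """ATAC peaks, counts and matched expression with planted coupling.

    Two cell populations ("teb", "duct") with ``atac.n_reps`` replicates
    each.  A fraction ``promoter_fraction`` of peaks is placed within
    +-250 bp of a TSS, the rest uniformly.  Per-peak accessibility log2
    effects are ``rho``-correlated with the nearest gene's expression
    log2 effect; group means are ``base * 2^(+-effect/2)``.  Candidate
    peaks that would overlap are dropped, so the realised peak number can
    be slightly below ``atac.n_peaks``.
    """
    config.validate()
    ac = config.atac
    rng = np.random.default_rng([config.seed, 2])
    if genes is None:
        genes = simulate_gene_annotation(ac.n_genes, rng)
    chrom_ends = genes.groupby("chrom")["end"].max() + 20_000

    n_prom = int(round(ac.promoter_fraction * ac.n_peaks))
    cand: list[tuple[str, int, int]] = []
    gidx = rng.integers(0, len(genes), n_prom)
    for gi in gidx:
        row = genes.iloc[int(gi)]
        width = int(rng.integers(200, 600))
        center = int(row["tss"] + rng.integers(-250, 251))
        cand.append((row["chrom"], center - width // 2, center + (width + 1) // 2))
    chrom_names = list(chrom_ends.index)
    for _ in range(ac.n_peaks - n_prom):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        width = int(rng.integers(200, 600))
        start = int(rng.integers(0, max(int(chrom_ends[chrom]) - width, 1)))
        cand.append((chrom, start, start + width))
    cand.sort()
    peaks: list[tuple[str, int, int]] = []
    for chrom, start, end in cand:
        if peaks and peaks[-1][0] == chrom and start <= peaks[-1][2] + 1:
            continue
        peaks.append((chrom, max(start, 0), end))
    n_peaks = len(peaks)
    peak_ids = [f"peak_{i:05d}" for i in range(n_peaks)]
    peak_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"], index=peak_ids)

    # planted effects: expression per gene, accessibility per peak
    e = pd.Series(rng.normal(0.0, ac.expr_sd, len(genes)), index=genes["symbol"].to_numpy())
    nearest, _dist = _nearest_gene_brute(peaks, genes)
    z = rng.normal(0.0, 1.0, n_peaks)
    a = (
        ac.rho * (ac.effect_sd / ac.expr_sd) * e.loc[nearest].to_numpy()
        + np.sqrt(max(1.0 - ac.rho**2, 0.0)) * ac.effect_sd * z
    )

    group_names = ["teb", "duct"]
    sample_names = [f"{g}_{r + 1}" for g in group_names for r in range(ac.n_reps)]
    sample_groups = pd.Series(
        [g for g in group_names for _ in range(ac.n_reps)], index=sample_names
    )
    lib_factors = rng.lognormal(0.0, 0.1, len(sample_names))
    base = rng.lognormal(np.log(ac.peak_mean), 0.5, n_peaks)
    signs = np.where(sample_groups.to_numpy() == "teb", 0.5, -0.5)
    mu = base[:, None] * 2.0 ** (np.outer(a, signs)) * lib_factors[None, :]
    counts = pd.DataFrame(
        _rnb(rng, mu, ac.dispersion), index=peak_ids, columns=sample_names
    )

    # per-population "called" peaks: accessible-enough peaks in each group
    ivs = [Interval(c, s, ee) for c, s, ee in peaks]
    peaks_by_population = {
        "teb": [iv for iv, ai in zip(ivs, a) if ai >= -0.3],
        "duct": [iv for iv, ai in zip(ivs, a) if ai <= 0.3],
    }

    n_black = int(round(ac.blacklist_fraction * n_peaks))
    blk_idx = rng.choice(n_peaks, size=n_black, replace=False) if n_black else []
    blacklist = [
        Interval(ivs[i].chrom, ivs[i].start + 5, ivs[i].start + 15) for i in blk_idx
    ]

    expr_base = rng.lognormal(np.log(ac.expr_mean), 1.0, len(genes))
    expr_mu = (
        expr_base[:, None] * 2.0 ** (np.outer(e.to_numpy(), signs)) * lib_factors[None, :]
    )
    expr_counts = CountMatrix(
        values=_rnb(rng, expr_mu, ac.expr_dispersion),
        genes=genes["symbol"].to_numpy(),
        columns=sample_names,
    )

    truth = SyntheticTruth(
        peak_log2fc=pd.Series(a, index=peak_ids),
        expr_log2fc=e,
        peak_gene=pd.Series(nearest, index=peak_ids),
    )
    return AtacSim(
        peaks=peak_df,
        peaks_by_population=peaks_by_population,
        counts=counts,
        sample_groups=sample_groups,
        blacklist=blacklist,
        genes=genes,
        expr_counts=expr_counts,
        expr_groups=sample_groups.copy(),
        truth=truth,
    )
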