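"""Derivation of lineage signature gene sets from sorted bulk RNA-seq.

The model is a precision-weighted gene-wise linear model of log2-CPM on
cell population with sequencing lane as an additive blocking factor.
Observation weights follow the mean-variance trend: a lowess curve of
sqrt(residual standard deviation) against average log2 count is fitted
across genes (span 0.5) and each observation receives weight
``predicted(sqrt(sd))**-4`` evaluated at its fitted log2 count.

Residual variances are moderated by empirical Bayes: the marginal
distribution of the gene-wise variances is matched to a scaled F
distribution by moment-matching on the log scale (digamma/trigamma
inversion), yielding a prior ``(d0, s0^2)`` and posterior variances
``s~^2 = (d0*s0^2 + df*s^2) / (d0 + df)``.

Differential expression between populations is tested relative to a
fold-change threshold tau (a TREAT-style test): with
``t_r = (|b| - log2(tau))/se`` and ``t_l = (|b| + log2(tau))/se`` on the
moderated degrees of freedom, ``p = P(T <= -t_r) + P(T <= -t_l)``.
``tau = 1`` reduces to the ordinary two-sided moderated t-test.

A gene enters a population's positive signature when it is up-regulated
versus *both* other populations at BH FDR < 0.05 (per comparison);
negative signatures are the genes down-regulated versus both other
populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from epilineage.expression_core import (
    CountMatrix,
    filter_genes_bulk,
    tmm_factors,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LineageSignature",
    "LinearFit",
    "Moderation",
    "make_design",
    "voom_weights",
    "fit_weighted_lm",
    "moderate_variances",
    "treat_test",
    "bh_adjust",
    "assemble_signatures",
    "derive_signatures",
    "SignatureDerivation",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class LineageSignature:
    """Positive and negative signature gene sets for each population."""

    positive: dict[str, list[str]]
    negative: dict[str, list[str]]
    thresholds: dict[str, float] = field(default_factory=dict)
    fdr: float = 0.05

    def __post_init__(self) -> None:
        for sets in (self.positive, self.negative):
            pops = list(sets)
            for i, a in enumerate(pops):
                for b in pops[i + 1 :]:
                    overlap = set(sets[a]) & set(sets[b])
                    if overlap:
                        raise ValueError(
                            f"signature sets {a} and {b} overlap: {sorted(overlap)[:5]}"
                        )

    @property
    def populations(self) -> list[str]:
        return list(self.positive)

    def sizes(self) -> dict[str, int]:
        out = {f"{p}_pos": len(g) for p, g in self.positive.items()}
        out.update({f"{p}_neg": len(g) for p, g in self.negative.items()})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop, genes in self.positive.items():
            rows += [(f"{pop}_pos", g) for g in genes]
        for pop, genes in self.negative.items():
            rows += [(f"{pop}_neg", g) for g in genes]
        return pd.DataFrame(rows, columns=["set", "symbol"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LineageSignature":
        positive: dict[str, list[str]] = {}
        negative: dict[str, list[str]] = {}
        for name, grp in df.groupby("set", sort=False):
            if name.endswith("_pos"):
                positive[name[:-4]] = grp["symbol"].tolist()
            elif name.endswith("_neg"):
                negative[name[:-4]] = grp["symbol"].tolist()
        return cls(positive=positive, negative=negative)


@dataclass
class LinearFit:
    """Gene-wise weighted least-squares fit on a shared design."""

    coefficients: np.ndarray  # (G, p)
    cov_unscaled: np.ndarray  # (G, p, p)
    sigma2: np.ndarray  # (G,) residual variances
    df_residual: int
    design: np.ndarray
    colnames: list[str]
    genes: pd.Index

    def contrast(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (coefficient, unscaled stdev) for contrast vector ``c``."""
        c = np.asarray(c, dtype=float)
        beta = self.coefficients @ c
        u = np.einsum("gpq,p,q->g", self.cov_unscaled, c, c)
        return beta, np.sqrt(u)


@dataclass
class Moderation:
    """Empirical-Bayes variance moderation result."""

    d0: float
    s02: float
    s2_post: np.ndarray

    def total_df(self, df_residual: float) -> float:
        return df_residual + self.d0


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def make_design(
    populations: Sequence[str],
    lanes: Sequence | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Cell-means design on population, with additive lane blocking.

    One indicator column per population plus ``n_lanes - 1`` lane
    indicators (the first lane observed is the baseline).  Raises if the
    design is rank deficient or any population has < 3 replicates.
    """
    populations = list(populations)
    pop_levels = list(pd.unique(np.asarray(populations, dtype=object)))
    cols = [np.asarray([p == lev for p in populations], float) for lev in pop_levels]
    names = [f"pop_{lev}" for lev in pop_levels]
    for lev, col in zip(pop_levels, cols):
        if col.sum() < 3:
            raise ValueError(f"population {lev} has fewer than 3 replicates")
    if lanes is not None:
        lane_levels = list(pd.unique(np.asarray(list(lanes), dtype=object)))
        for lev in lane_levels[1:]:
            cols.append(np.asarray([l == lev for l in lanes], float))
            names.append(f"lane_{lev}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def population_contrast(
    colnames: Sequence[str], pop_a: str, pop_b: str
) -> np.ndarray:
    c = np.zeros(len(colnames))
    c[list(colnames).index(f"pop_{pop_a}")] = 1.0
    c[list(colnames).index(f"pop_{pop_b}")] = -1.0
    return c


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------


def voom_weights(
    counts: CountMatrix,
    design: np.ndarray,
    *,
    lib_sizes: np.ndarray | None = None,
    span: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-variance trend precision weights.

    Computes ``y = log2((counts + 0.5)/(L' + 1) * 1e6)`` on TMM-effective
    library sizes, fits OLS per gene, lowess-smooths sqrt(residual sd)
    against average log2 count, and returns per-observation weights
    ``trend(fitted log2 count)**-4`` together with ``y``.
    """
    dense = counts.to_dense().astype(float)
    libs = counts.effective_lib_sizes() if lib_sizes is None else np.asarray(lib_sizes)
    n, p = design.shape
    if n - p < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")
    y = np.log2((dense + 0.5) / (libs + 1.0) * 1e6)

    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T  # (G, p)
    fitted = beta @ design.T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))

    sx = y.mean(axis=1) + np.mean(np.log2(libs + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    if np.ptp(sx) < 1e-10:  # all genes at one abundance: flat trend
        lx, ly = np.array([sx[0]]), np.array([sy.mean()])
    else:
        smoothed = sm_lowess(sy, sx, frac=span, it=3, return_sorted=True)
        lx, ly = smoothed[:, 0], smoothed[:, 1]
    # collapse duplicate x for interpolation
    lx_u, first = np.unique(lx, return_index=True)
    ly_u = np.array([ly[lx == v].mean() for v in lx_u]) if len(lx_u) < len(lx) else ly[first]

    fitted_logcount = fitted + (np.log2(libs + 1.0) - np.log2(1e6))[None, :]
    trend = np.interp(fitted_logcount, lx_u, ly_u)  # constant beyond range
    trend = np.maximum(trend, 1e-6)
    weights = trend**-4
    return y, weights


# ---------------------------------------------------------------------------
# weighted linear model
# ---------------------------------------------------------------------------


def fit_weighted_lm(
    y: np.ndarray,
    weights: np.ndarray,
    design: np.ndarray,
    genes: Sequence | None = None,
    colnames: Sequence[str] | None = None,
) -> LinearFit:
    """Gene-wise weighted least squares with a common design matrix."""
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    X = np.asarray(design, float)
    n, p = X.shape
    if y.shape != w.shape or y.shape[1] != n:
        raise ValueError("y, weights and design are inconsistent")
    A = np.einsum("jp,gj,jq->gpq", X, w, X)
    b = np.einsum("jp,gj->gp", X, w * y)
    Ainv = np.linalg.inv(A)
    beta = np.einsum("gpq,gq->gp", Ainv, b)
    fitted = beta @ X.T
    df = n - p
    sigma2 = (w * (y - fitted) ** 2).sum(axis=1) / df
    return LinearFit(
        coefficients=beta,
        cov_unscaled=Ainv,
        sigma2=sigma2,
        df_residual=df,
        design=X,
        colnames=list(colnames) if colnames is not None else [f"x{i}" for i in range(p)],
        genes=pd.Index(genes if genes is not None else np.arange(y.shape[0])),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def moderate_variances(sigma2: np.ndarray, df: float) -> Moderation:
    """Moment-matching of log variances to estimate the variance prior.

    Fits the scaled-F marginal model of gene-wise residual variances:
    ``e = log(s^2) - digamma(df/2) + log(df/2)`` has mean ``log(s0^2)``
    and excess variance ``trigamma(d0/2)`` beyond ``trigamma(df/2)``.
    When the excess is non-positive every variance is shrunk to the
    common value (``d0 = inf``, ``s0^2`` = geometric mean of ``s^2``).
    """
    s2 = np.asarray(sigma2, float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if e.size > 1 else 0.0
    evar -= special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s02 = float(np.exp(np.mean(z)))
        s2_post = np.full_like(s2, s02)
    return Moderation(d0=float(d0), s02=s02, s2_post=s2_post)


# ---------------------------------------------------------------------------
# fold-change-thresholded moderated t-test
# ---------------------------------------------------------------------------


def treat_test(
    beta: np.ndarray,
    stdev_unscaled: np.ndarray,
    moderation: Moderation,
    df_residual: float,
    tau_fc: float,
) -> np.ndarray:
    """p-values for |log2FC| exceeding a fold-change threshold.

    ``tau_fc`` is expressed as a fold change (>= 1); internally
    ``tau = log2(tau_fc)``.  ``tau_fc = 1`` reduces exactly to the
    two-sided moderated t-test.
    """
    if tau_fc < 1:
        raise ValueError("fold-change threshold must be >= 1")
    tau = np.log2(tau_fc)
    se = stdev_unscaled * np.sqrt(moderation.s2_post)
    df_total = min(moderation.total_df(df_residual), 1e8)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_right = (np.abs(beta) - tau) / se
        t_left = (np.abs(beta) + tau) / se
    p = stats.t.cdf(-t_right, df_total) + stats.t.cdf(-t_left, df_total)
    return np.minimum(p, 1.0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# signature assembly and the end-to-end pipeline
# ---------------------------------------------------------------------------


def assemble_signatures(
    tables: Mapping[tuple[str, str], pd.DataFrame],
    populations: Sequence[str],
    *,
    fdr: float = 0.05,
    coding_genes: Sequence[str] | None = None,
) -> LineageSignature:
    """Build positive/negative signature sets from per-contrast tables.

    ``tables`` maps ordered population pairs ``(a, b)`` to DataFrames
    indexed by gene with columns ``log2fc`` (sign = a - b) and ``p_adj``.
    A gene is positive for population P when it is up in P versus both
    other populations at ``p_adj < fdr``; negative sets are symmetric for
    down-regulation.  ``coding_genes``, when given, restricts the
    universe to that list.
    """
    populations = list(populations)
    if len(populations) != 3:
        raise ValueError("exactly three populations expected")

    def signed(pop: str, other: str) -> pd.DataFrame:
        if (pop, other) in tables:
            return tables[(pop, other)]
        if (other, pop) in tables:
            t = tables[(other, pop)].copy()
            t["log2fc"] = -t["log2fc"]
            return t
        raise ValueError(f"missing contrast between {pop} and {other}")

    positive: dict[str, list[str]] = {}
    negative: dict[str, list[str]] = {}
    for pop in populations:
        others = [q for q in populations if q != pop]
        t1, t2 = (signed(pop, q) for q in others)
        up = (
            (t1["log2fc"] > 0)
            & (t1["p_adj"] < fdr)
            & (t2["log2fc"] > 0)
            & (t2["p_adj"] < fdr)
        )
        down = (
            (t1["log2fc"] < 0)
            & (t1["p_adj"] < fdr)
            & (t2["log2fc"] < 0)
            & (t2["p_adj"] < fdr)
        )
        pos_genes = t1.index[up]
        neg_genes = t1.index[down]
        if coding_genes is not None:
            coding = set(coding_genes)
            pos_genes = [g for g in pos_genes if g in coding]
            neg_genes = [g for g in neg_genes if g in coding]
        positive[pop] = list(pos_genes)
        negative[pop] = list(neg_genes)
    return LineageSignature(positive=positive, negative=negative, fdr=fdr)


@dataclass
class SignatureDerivation:
    """End-to-end result: signature sets plus the per-contrast tables."""

    signature: LineageSignature
    tables: dict[tuple[str, str], pd.DataFrame]
    moderation: Moderation
    n_genes_tested: int


def derive_signatures(
    counts: CountMatrix,
    populations: Sequence[str],
    lanes: Sequence | None = None,
    *,
    taus: Mapping[tuple[str, str], float] | None = None,
    fdr: float = 0.05,
    min_cpm: float = 0.4,
    min_samples: int = 3,
    span: float = 0.5,
    coding_genes: Sequence[str] | None = None,
) -> SignatureDerivation:
    """Full signature-derivation pipeline on sorted bulk counts.

    Steps: CPM filter -> TMM -> precision weights -> weighted linear
    model with lane blocking -> variance moderation -> fold-change
    thresholded tests per contrast -> BH within each contrast ->
    up/down-versus-both-others assembly.

    By default, contrasts involving the first population use a fold-change
    threshold of 2 and the remaining contrast uses 1.3 (the first
    population is the basal-like reference, which separates more strongly
    from the two luminal populations than they do from each other).
    """
    pop_levels = list(pd.unique(np.asarray(list(populations), dtype=object)))
    if len(pop_levels) != 3:
        raise ValueError("exactly three populations expected")
    pairs = [
        (pop_levels[0], pop_levels[1]),
        (pop_levels[0], pop_levels[2]),
        (pop_levels[1], pop_levels[2]),
    ]
    if taus is None:
        taus = {pairs[0]: 2.0, pairs[1]: 2.0, pairs[2]: 1.3}

    filtered = filter_genes_bulk(counts, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    filtered = filtered.with_norm_factors(factors)

    X, names = make_design(populations, lanes)
    y, w = voom_weights(filtered, X, span=span)
    fit = fit_weighted_lm(y, w, X, genes=filtered.genes, colnames=names)
    mod = moderate_variances(fit.sigma2, fit.df_residual)

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for pair in pairs:
        c = population_contrast(names, *pair)
        beta, su = fit.contrast(c)
        p = treat_test(beta, su, mod, fit.df_residual, taus[pair])
        tables[pair] = pd.DataFrame(
            {
                "log2fc": beta,
                "se": su * np.sqrt(mod.s2_post),
                "p": p,
                "p_adj": bh_adjust(p),
            },
            index=filtered.genes,
        )
    sig = assemble_signatures(
        tables, pop_levels, fdr=fdr, coding_genes=coding_genes
    )
    sig.thresholds = {f"{a}_vs_{b}": taus[(a, b)] for a, b in pairs}
    logger.info("signature sizes: %s", sig.sizes())
    return SignatureDerivation(
        signature=sig,
        tables=tables,
        moderation=mod,
        n_genes_tested=filtered.n_genes,
    )
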