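"""Interval ops, exact-test DA, TSS summaries and expression integration."""

import numpy as np
import pandas as pd
import pytest

from epilineage.atac_accessibility import (
    DIST_BIN_LABELS,
    PeakSet,
    _double_tail_p,
    annotate_nearest_tss,
    estimate_common_dispersion,
    exact_test_da,
    integrate_da_expression,
    merge_peaks,
    metagene_profile,
    overlap_fraction,
    peak_intensity,
    signature_accessibility_compare,
    subtract_blacklist,
    tss_neighborhood_accessibility,
)
from epilineage.io_formats import Interval, build_gene_annotation


def _genes(rows):
    return build_gene_annotation(
        pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "start", "end"])
    )


def _random_intervals(rng, n, chroms=3, span=100_000, max_len=50):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        out.append(
            Interval(
                f"chr{int(rng.integers(1, chroms + 1))}",
                start,
                start + int(rng.integers(1, max_len)),
            )
        )
    return out


class TestMergePeaks:
    def test_bookended_merge(self):
        ivs = [Interval("chr1", 100, 200), Interval("chr1", 150, 250), Interval("chr1", 250, 300)]
        assert merge_peaks([ivs]) == [Interval("chr1", 100, 300)]

    def test_disjoint_unchanged(self):
        ivs = [Interval("chr1", 100, 200), Interval("chr1", 300, 400)]
        assert merge_peaks([ivs]) == ivs

    def test_strict_overlap_dialect_keeps_bookended_separate(self):
        ivs = [Interval("chr1", 100, 200), Interval("chr1", 200, 300)]
        assert merge_peaks([ivs], bookended=False) == ivs
        assert merge_peaks([ivs], bookended=True) == [Interval("chr1", 100, 300)]

    def test_matches_brute_force_union_on_10000_random_intervals(self, rng):
        ivs = _random_intervals(rng, 10_000)
        merged = merge_peaks([ivs[:5000], ivs[5000:]])
        # oracle: mark covered half-bases at doubled resolution so that
        # book-ended intervals (gap 0) become contiguous runs while gap-1
        # intervals stay separate; read off connected components
        by_chrom = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        expected = []
        for chrom in sorted(by_chrom):
            cover = np.zeros(2 * 100_100, dtype=bool)
            for iv in by_chrom[chrom]:
                cover[2 * iv.start : 2 * iv.end] = True
            padded = np.concatenate([[False], cover, [False]]).astype(int)
            edges = np.flatnonzero(np.diff(padded))
            for a, b in zip(edges[::2], edges[1::2]):
                expected.append(Interval(chrom, a // 2, b // 2))
        assert merged == expected

    def test_merge_then_blacklist_idempotent(self, rng):
        ivs = _random_intervals(rng, 500)
        blk = _random_intervals(rng, 20)
        once = subtract_blacklist(merge_peaks([ivs]), blk)
        twice = subtract_blacklist(merge_peaks([once]), blk)
        assert once == twice


class TestBlacklist:
    def test_overlapping_peak_removed_entirely(self):
        peaks = [Interval("chr1", 100, 200)]
        assert subtract_blacklist(peaks, [Interval("chr1", 150, 160)]) == []

    def test_empty_blacklist_identity(self):
        peaks = [Interval("chr1", 100, 200)]
        assert subtract_blacklist(peaks, []) == peaks

    def test_matches_brute_force_overlap(self, rng):
        peaks = _random_intervals(rng, 2000)
        blk = _random_intervals(rng, 100)
        got = subtract_blacklist(peaks, blk)
        expected = [
            p
            for p in peaks
            if not any(
                b.chrom == p.chrom and b.start < p.end and b.end > p.start for b in blk
            )
        ]
        assert got == expected

    def test_overlap_fraction(self):
        peaks = [Interval("chr1", 0, 10), Interval("chr1", 100, 110)]
        ann = [Interval("chr1", 5, 7)]
        assert overlap_fraction(peaks, ann) == pytest.approx(0.5)


class TestPeakIntensity:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["p1", "p2"])
        out = peak_intensity(counts, np.array([500, 500]), np.array([2e6]))
        assert out.loc["p1", "s"] == pytest.approx(np.log2(11), abs=1e-12)
        assert out.loc["p2", "s"] == 0.0

    def test_matches_formula_oracle(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 4)))
        lengths = rng.integers(100, 2000, 50)
        libs = rng.uniform(1e6, 5e6, 4)
        out = peak_intensity(counts, lengths, libs)
        for i in range(50):
            for j in range(4):
                rpkm = counts.iloc[i, j] / (lengths[i] / 1e3) / (libs[j] / 1e6)
                assert out.iloc[i, j] == pytest.approx(np.log2(rpkm + 1), abs=1e-12)

    def test_zero_length_raises(self):
        counts = pd.DataFrame({"s": [1]})
        with pytest.raises(ValueError):
            peak_intensity(counts, np.array([0]), np.array([1e6]))


class TestNearestTss:
    def test_distance_and_bin(self):
        genes = _genes([("a", "chr1", "+", 1000, 2000)])
        out = annotate_nearest_tss([Interval("chr1", 1200, 1400)], genes)
        # plus-strand TSS at 1000, inside? no: peak starts at 1200
        assert out["distance"].iloc[0] == 200
        assert out["bin"].iloc[0] == "<=0.5kb"

    def test_tss_inside_peak_distance_zero(self):
        genes = _genes([("a", "chr1", "+", 1000, 2000)])
        out = annotate_nearest_tss([Interval("chr1", 900, 1100)], genes)
        assert out["distance"].iloc[0] == 0

    def test_no_gene_chromosome_flagged_infinite(self):
        genes = _genes([("a", "chr1", "+", 0, 100)])
        out = annotate_nearest_tss([Interval("chr9", 0, 50)], genes)
        assert np.isinf(out["distance"].iloc[0])
        assert out["bin"].iloc[0] == ">10kb"

    def test_tie_broken_lexicographically(self):
        genes = _genes([("zeta", "chr1", "+", 900, 1500), ("alpha", "chr1", "+", 1300, 1400)])
        # peak equidistant (100) from TSS 900 (left) and 1300 (right)
        out = annotate_nearest_tss([Interval("chr1", 1000, 1201)], genes)
        assert out["distance"].iloc[0] == 100
        assert out["gene"].iloc[0] == "alpha"

    def test_matches_brute_force_all_pairs(self, rng):
        rows = []
        for i in range(400):
            chrom = f"chr{int(rng.integers(1, 4))}"
            start = int(rng.integers(0, 500_000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{i:04d}", chrom, strand, start, start + int(rng.integers(100, 5000))))
        genes = _genes(rows)
        peaks = _random_intervals(rng, 5000, chroms=3, span=500_000, max_len=400)
        out = annotate_nearest_tss(peaks, genes)
        tss = genes["tss"].to_numpy()
        chroms = genes["chrom"].to_numpy()
        syms = genes["symbol"].to_numpy()
        for k, p in enumerate(peaks):
            d = np.where(
                (tss >= p.start) & (tss < p.end),
                0,
                np.where(tss < p.start, p.start - tss, tss - (p.end - 1)),
            ).astype(float)
            d[chroms != p.chrom] = np.inf
            best = d.min()
            assert out["distance"].iloc[k] == best
            assert out["gene"].iloc[k] == min(syms[d == best])


class TestDispersion:
    def test_poisson_limit_recovered_near_zero(self, rng):
        mu = rng.lognormal(np.log(100), 0.5, 5000)
        counts = rng.poisson(np.tile(mu[:, None], (1, 8)))
        phi = estimate_common_dispersion(pd.DataFrame(counts), ["A"] * 4 + ["B"] * 4)
        assert phi < 0.01

    def test_planted_dispersion_recovered(self, rng):
        mu = rng.lognormal(np.log(100), 0.5, 5000)
        r = 1 / 0.2
        counts = rng.negative_binomial(r, r / (r + np.tile(mu[:, None], (1, 8))))
        phi = estimate_common_dispersion(pd.DataFrame(counts), ["A"] * 4 + ["B"] * 4)
        assert 0.15 <= phi <= 0.25

    def test_identical_replicates_boundary(self):
        counts = np.tile(np.arange(10, 110, 10)[:, None], (1, 6))
        phi = estimate_common_dispersion(pd.DataFrame(counts), ["A"] * 3 + ["B"] * 3)
        assert phi < 0.01

    def test_single_sample_groups_rejected(self):
        counts = pd.DataFrame(np.ones((5, 2)))
        with pytest.raises(ValueError):
            estimate_common_dispersion(counts, ["A", "B"])


class TestExactTest:
    def test_equal_pseudo_counts_give_p_one(self):
        counts = pd.DataFrame(
            np.tile(np.array([20, 50, 80])[:, None], (1, 8)),
            columns=[f"s{j}" for j in range(8)],
        )
        out = exact_test_da(counts, ["A"] * 4 + ["B"] * 4, phi=0.1)
        assert np.allclose(out["p"], 1.0)

    def test_poisson_limit_binomial_doubling(self):
        # totals 0 vs 10 at equal library sizes: p = 2 * (1/2)^10
        assert _double_tail_p(0, 10, 4, 4, 0.0) == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_group_swap_exchangeability(self, rng):
        mu = rng.lognormal(np.log(60), 0.4, 200)
        r = 1 / 0.2
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + np.tile(mu[:, None], (1, 8)))),
            columns=[f"s{j}" for j in range(8)],
        )
        g = ["A"] * 4 + ["B"] * 4
        out1 = exact_test_da(counts, g, phi=0.2)
        # present the samples in reverse so the comparison order flips
        out2 = exact_test_da(counts.iloc[:, ::-1], g, phi=0.2)
        assert np.allclose(out1["p"], out2["p"], atol=1e-12)
        assert np.allclose(out1["log2fc"], -out2["log2fc"], atol=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            exact_test_da(pd.DataFrame(np.ones((2, 4))), ["A", "A", "B", "B"], phi=-0.1)


def _tiled_peaks(n, width, value):
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * (width + 1),  # gap of 1 bp keeps them disjoint
            "end": np.arange(n) * (width + 1) + width,
        }
    )
    return peaks, np.full(n, value)


class TestMetagene:
    def test_uniform_coverage_gives_flat_profile(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
        genes = _genes([("a", "chr1", "+", 200_000, 210_000)])
        prof = metagene_profile(peaks, np.array([1.0]), genes)
        assert np.allclose(prof.values, 1.0)

    def test_promoter_peaks_peak_at_tss(self, rng):
        rows = []
        peaks = []
        for i in range(60):
            start = 100_000 + i * 50_000
            rows.append((f"g{i:03d}", "chr1", "+", start, start + 5000))
            peaks.append(("chr1", start - 200, start + 200))
        genes = _genes(rows)
        peak_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
        prof = metagene_profile(peak_df, np.ones(len(peaks)), genes)
        # maximum lies within +-500 bp of the TSS (flank bins 45-49, body 0-9)
        assert 45 <= int(np.argmax(prof.values)) < 60

    def test_minus_strand_gene_mirrors_plus(self, rng):
        L = 1_000_000
        gene_plus = _genes([("a", "chr1", "+", 400_000, 420_000)])
        gene_minus = _genes([("a", "chr1", "-", L - 420_000, L - 400_000)])
        pk = []
        for _ in range(30):
            s = int(rng.integers(390_000, 425_000))
            pk.append((s, s + int(rng.integers(100, 800))))
        pk_plus = pd.DataFrame([("chr1", s, e) for s, e in pk], columns=["chrom", "start", "end"])
        pk_minus = pd.DataFrame(
            [("chr1", L - e, L - s) for s, e in pk], columns=["chrom", "start", "end"]
        )
        vals = rng.uniform(0.5, 2.0, 30)
        p1 = metagene_profile(pk_plus, vals, gene_plus)
        p2 = metagene_profile(pk_minus, vals, gene_minus)
        assert np.allclose(p1.values, p2.values, atol=1e-9)

    def test_short_gene_skipped(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        genes = _genes([("tiny", "chr1", "+", 10, 60)])
        with pytest.raises(ValueError):
            metagene_profile(peaks, np.array([1.0]), genes)


class TestTssNeighborhood:
    @staticmethod
    def _peakset(peaks, counts, libs):
        ids = [f"p{i}" for i in range(len(peaks))]
        pk = pd.DataFrame(peaks, columns=["chrom", "start", "end"], index=ids)
        cnt = pd.DataFrame(counts, index=ids, columns=[f"s{j}" for j in range(len(libs))])
        return PeakSet(pk, cnt, pd.Series(libs, index=cnt.columns, dtype=float))

    def test_no_peaks_in_window_gives_zero(self):
        ps = self._peakset([("chr1", 500_000, 500_400)], [[10]], [1e6])
        genes = _genes([("a", "chr1", "+", 10_000, 20_000)])
        out = tss_neighborhood_accessibility(ps, genes)
        assert out.loc["a", "s0"] == 0.0

    def test_contained_peak_arithmetic(self):
        ps = self._peakset([("chr1", 12_000, 12_500)], [[10]], [1e6])
        genes = _genes([("a", "chr1", "+", 10_000, 30_000)])
        out = tss_neighborhood_accessibility(ps, genes)
        # RPKM = 10 / (20 kb * 1 M) = 0.5 -> log2(1.5)
        assert out.loc["a", "s0"] == pytest.approx(np.log2(1.5), abs=1e-12)

    def test_clipped_counts_never_exceed_whole_peak_counts(self, rng):
        peaks = []
        for _ in range(200):
            s = int(rng.integers(0, 200_000))
            peaks.append(("chr1", s, s + int(rng.integers(100, 3000))))
        peaks = sorted(set(peaks), key=lambda t: t[1])
        keep = []
        for p in peaks:
            if not keep or p[1] > keep[-1][2]:
                keep.append(p)
        counts = rng.integers(0, 100, (len(keep), 2))
        ps = self._peakset(keep, counts, [1e6, 2e6])
        genes = _genes([(f"g{i}", "chr1", "+", i * 20_000, i * 20_000 + 5000) for i in range(10)])
        clipped = tss_neighborhood_accessibility(ps, genes, clip=True)
        whole = tss_neighborhood_accessibility(ps, genes, clip=False)
        assert (clipped.to_numpy() <= whole.to_numpy() + 1e-12).all()


class TestSignatureAccessibilityCompare:
    def test_identical_intensities_null(self):
        inten = pd.DataFrame(
            np.ones((5, 4)), index=[f"g{i}" for i in range(5)], columns=list("abcd")
        )
        res = signature_accessibility_compare(inten, [f"g{i}" for i in range(5)], ["duct", "duct", "teb", "teb"])
        assert res.coefficient == 0.0 and res.p == 1.0

    def test_planted_shift_detected(self, rng):
        genes = [f"g{i}" for i in range(400)]
        base = rng.normal(3, 0.5, (400, 3))
        shifted = base + 1.0 + rng.normal(0, 0.1, (400, 3))
        inten = pd.DataFrame(np.hstack([shifted, base]), index=genes)
        res = signature_accessibility_compare(inten, genes, ["duct"] * 3 + ["teb"] * 3)
        assert res.p < 1e-6
        assert abs(res.coefficient - 1.0) <= 0.1

    def test_label_swap_negates_coefficient(self, rng):
        genes = [f"g{i}" for i in range(50)]
        inten = pd.DataFrame(rng.normal(size=(50, 6)), index=genes)
        g = ["duct"] * 3 + ["teb"] * 3
        r1 = signature_accessibility_compare(inten, genes, g)
        r2 = signature_accessibility_compare(inten.iloc[:, ::-1], genes, g)
        assert r1.coefficient == pytest.approx(-r2.coefficient)
        assert r1.p == pytest.approx(r2.p)

    def test_too_few_genes_raises(self):
        inten = pd.DataFrame(np.ones((2, 4)), index=["a", "b"])
        with pytest.raises(ValueError):
            signature_accessibility_compare(inten, ["a", "b"], ["x", "x", "y", "y"])


class TestIntegration:
    def test_perfect_coupling_slope_one(self):
        ids = [f"p{i}" for i in range(40)]
        fc = np.linspace(-2, 2, 40)
        fc = fc[fc != 0]
        ids = ids[: len(fc)]
        da = pd.DataFrame({"log2fc": fc, "da": True}, index=ids)
        annot = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(fc))], "bin": DIST_BIN_LABELS[0]},
            index=ids,
        )
        expr = pd.Series(fc, index=[f"g{i}" for i in range(len(fc))])
        out = integrate_da_expression(da, annot, expr)
        row = out.loc[DIST_BIN_LABELS[0]]
        assert row["slope"] == pytest.approx(1.0)
        assert row["r"] == pytest.approx(1.0)
        assert row["up_down"] == 0 and row["down_up"] == 0
        assert row["up_up"] + row["down_down"] == len(fc)

    def test_empty_bin_is_not_an_error(self):
        da = pd.DataFrame({"log2fc": [1.0], "da": [True]}, index=["p0"])
        annot = pd.DataFrame({"gene": ["g0"], "bin": DIST_BIN_LABELS[0]}, index=["p0"])
        out = integrate_da_expression(da, annot, pd.Series({"g0": 0.5}))
        assert out.loc[DIST_BIN_LABELS[3], "n_da_peaks"] == 0

    def test_quadrant_counts_sum_to_nonzero_expression_peaks(self, rng):
        n = 300
        ids = [f"p{i}" for i in range(n)]
        da = pd.DataFrame(
            {"log2fc": rng.normal(size=n), "da": rng.random(n) < 0.7}, index=ids
        )
        gene_ids = [f"g{int(rng.integers(0, 100))}" for _ in range(n)]
        annot = pd.DataFrame(
            {"gene": gene_ids, "bin": rng.choice(DIST_BIN_LABELS, n)}, index=ids
        )
        expr = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        expr.iloc[:10] = 0.0
        out = integrate_da_expression(da, annot, expr)
        merged_n = 0
        quad_n = 0
        for label in DIST_BIN_LABELS:
            row = out.loc[label]
            quad = row[["up_up", "up_down", "down_up", "down_down"]].sum()
            quad_n += quad
        sel = da["da"] & pd.Series(gene_ids, index=ids).map(expr).notna()
        nonzero = (pd.Series(gene_ids, index=ids).map(expr) != 0) & sel
        assert quad_n == int(nonzero.sum())
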