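"""Enrichment-procedure contracts: exact binomial tails, degenerate and
saturated nulls, the upper-bound (-V) correction, order invariance, repeat
clustering rules, and agreement with a uniform-redraw permutation oracle."""

import dataclasses
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.signal import fftconvolve
from scipy.stats import binom

from vlincscan.annotation import Promoter, RepeatElement
from vlincscan.caller import VlincRNA
from vlincscan.enrichment import (
    binomial_upper_tail,
    build_anti_space,
    build_promoter_space_stranded,
    cluster_ltr_elements,
    log10_binomial_upper_tail,
)
from vlincscan.enrichment import test_ltr_family_enrichment as ltr_family_enrichment
from vlincscan.enrichment import test_promoter_overlap_stranded as promoter_overlap_stranded
from vlincscan.enrichment import test_promoter_overlap_unstranded as promoter_overlap_unstranded
from vlincscan.enrichment import test_set_overlap as set_overlap
from vlincscan.intervals import Genome, GenomicInterval, IntervalSet, union_length


def exact_tail(N: int, q: Fraction, n: int) -> Fraction:
    """Brute-force rational P(X >= n) for X ~ Binomial(N, q)."""
    total = Fraction(0)
    for k in range(n, N + 1):
        total += (
            Fraction(math.comb(N, k)) * q**k * (1 - q) ** (N - k)
        )
    return total


class TestBinomialTail:
    @pytest.mark.parametrize(
        "N, q, n, expected",
        [
            (10, 0.5, 0, 1.0),
            (10, 0.5, 10, 0.0009765625),
            (5, 0.2, 2, 0.26272),  # 1 - 0.8^5 - 5*0.2*0.8^4
        ],
    )
    def test_examples(self, N, q, n, expected):
        assert binomial_upper_tail(N, q, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("N", [1, 7, 19, 30])
    def test_agrees_with_rational_summation(self, N):
        for q in (Fraction(1, 100), Fraction(1, 5), Fraction(1, 2), Fraction(9, 10)):
            for n in range(N + 1):
                got = binomial_upper_tail(N, float(q), n)
                want = float(exact_tail(N, q, n))
                assert got == pytest.approx(want, rel=1e-12)

    def test_monotone_in_n_and_q(self):
        ps = [binomial_upper_tail(50, 0.3, n) for n in range(51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        qs = [binomial_upper_tail(50, q, 25) for q in np.linspace(0.01, 0.99, 20)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_extreme_tails_finite_and_ordered_in_log_space(self):
        # printed-style magnitudes around 1e-150 and far below
        logs = [
            log10_binomial_upper_tail(2000, 0.01, n) for n in (150, 250, 400)
        ]
        assert all(np.isfinite(x) for x in logs)
        assert logs[0] > logs[1] > logs[2]
        assert logs[1] < -150  # deep in underflow territory for naive products

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            binomial_upper_tail(10, 1.5, 2)
        with pytest.raises(ValueError):
            binomial_upper_tail(10, 0.5, 11)


# ---------------------------------------------------------------------------
# a deterministic toy cosmos for the space-based procedures
# ---------------------------------------------------------------------------

GENOME = Genome({"synthchr1": 10_000_000})


def grid_vlincs(n=20, planted_strands=("+", "-"), length=100_000, spacing=400_000):
    out = []
    for i in range(n):
        start = 300_000 + i * spacing
        strand = planted_strands[i % len(planted_strands)]
        out.append(
            VlincRNA(
                GenomicInterval("synthchr1", start, start + length, strand),
                vlinc_id=f"v{i}",
            )
        )
    return out


def grid_genes():
    ivs = []
    for i in range(15):
        s = 150_000 + i * 600_000
        ivs.append(GenomicInterval("synthchr1", s, s + 30_000, "+" if i % 2 else "-"))
    return IntervalSet(ivs)


def planted_promoters(vlincs, k, rng=None, n_decoys=50):
    proms = []
    for v in vlincs[:k]:
        b = v.interval.five_prime()
        proms.append(
            Promoter(GenomicInterval("synthchr1", b - 1000, b + 1000), "Active", "K1")
        )
    rng = rng or np.random.default_rng(7)
    decoys = rng.integers(0, GENOME["synthchr1"] - 2000, size=n_decoys)
    for s in decoys:
        proms.append(
            Promoter(GenomicInterval("synthchr1", int(s), int(s) + 2000), "Active", "K1")
        )
    return proms


def unstranded(vlincs):
    return [
        VlincRNA(
            GenomicInterval(v.interval.chrom, v.interval.start, v.interval.end, "."),
            v.source_sample,
            v.vlinc_id,
        )
        for v in vlincs
    ]


class TestAntiSpace:
    def test_modes(self):
        genes = IntervalSet(
            [
                GenomicInterval("synthchr1", 0, 10_000, "+"),
                GenomicInterval("synthchr1", 40_000, 50_000, "-"),
            ]
        )
        blk = IntervalSet([GenomicInterval("synthchr1", 90_000, 95_000)])
        same = build_anti_space(genes, blk, None, "stranded-same", strand="+")
        assert [(iv.start, iv.end) for iv in same] == [(0, 10_000), (90_000, 95_000)]
        either = build_anti_space(genes, blk, None, "either-strand")
        assert union_length(either) == 25_000
        # inter-gene gap of 30 kb < 50 kb is filled; no blacklist term
        gaps = build_anti_space(genes, blk, None, "with-short-gaps", genome=GENOME)
        assert [(iv.start, iv.end) for iv in gaps] == [(0, 50_000)]

    def test_tested_regions_subtracted(self):
        genes = IntervalSet([GenomicInterval("synthchr1", 0, 10_000, "+")])
        tested = IntervalSet([GenomicInterval("synthchr1", 5_000, 10_000, "+")])
        out = build_anti_space(genes, None, tested, "either-strand")
        assert [(iv.start, iv.end) for iv in out] == [(0, 5_000)]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_anti_space(IntervalSet(), None, None, "sideways")


class TestPromoterProcedures:
    def test_empty_promoters_give_p_one(self):
        vl = grid_vlincs()
        res = promoter_overlap_stranded(vl, [], grid_genes(), None, GENOME)
        assert res.n_observed == 0 and res.m_expected == 0 and res.p_value == 1.0
        res2 = promoter_overlap_unstranded(
            unstranded(vl), [], grid_genes(), None, GENOME
        )
        assert res2.p_value == 1.0

    def test_saturated_promoters_give_p_one_and_full_counts(self):
        vl = grid_vlincs()
        tiling = IntervalSet([GenomicInterval("synthchr1", 0, GENOME["synthchr1"])])
        res = promoter_overlap_stranded(vl, tiling, grid_genes(), None, GENOME)
        assert res.n_observed == res.N == len(vl)
        assert all(p == 1.0 for p in res.success_probs)
        assert res.p_value == 1.0

    def test_planted_signal_is_detected(self):
        vl = grid_vlincs()
        proms = planted_promoters(vl, k=20)
        res = promoter_overlap_stranded(vl, proms, grid_genes(), None, GENOME)
        assert res.n_observed == 20
        assert res.p_value < 1e-6 and res.fold > 5

    def test_unstranded_probability_combines_both_boundaries(self):
        vl = unstranded(grid_vlincs())
        proms = planted_promoters(grid_vlincs(), k=10)
        res = promoter_overlap_unstranded(vl, proms, grid_genes(), None, GENOME)
        assert res.n_observed >= 10
        assert res.p_value < 1e-4

    def test_order_invariance(self):
        vl = grid_vlincs()
        proms = planted_promoters(vl, k=8)
        res1 = promoter_overlap_stranded(vl, proms, grid_genes(), None, GENOME)
        rng = np.random.default_rng(3)
        shuffled = list(vl)
        rng.shuffle(shuffled)
        res2 = promoter_overlap_stranded(
            shuffled, proms, grid_genes(), None, GENOME
        )
        assert res1.p_value == pytest.approx(res2.p_value, rel=1e-12)
        assert res1.m_expected == pytest.approx(res2.m_expected, rel=1e-12)

    def test_v_correction_is_an_upper_bound(self):
        """Dropping the -V correction can only lower the expected overlap and
        hence the p-value; the corrected p-value is the conservative one."""
        vl = grid_vlincs()
        proms = planted_promoters(vl, k=6)
        space = build_promoter_space_stranded(vl, grid_genes(), None, GENOME)
        res_with = promoter_overlap_stranded(
            vl, proms, grid_genes(), None, GENOME, space=space
        )
        space_no_v = dataclasses.replace(space, V=0)
        res_without = promoter_overlap_stranded(
            vl, proms, grid_genes(), None, GENOME, space=space_no_v
        )
        assert res_with.p_value >= res_without.p_value

    def test_degenerate_space_raises(self):
        genes = IntervalSet(
            [GenomicInterval("synthchr1", 0, GENOME["synthchr1"], s) for s in "+-"]
        )
        vl = grid_vlincs(n=4)
        with pytest.raises(ValueError, match="degenerate space"):
            promoter_overlap_stranded(
                vl, planted_promoters(vl, 0), genes, None, GENOME
            )

    def test_unstranded_vlinc_rejected_by_stranded_test(self):
        with pytest.raises(ValueError):
            promoter_overlap_stranded(
                unstranded(grid_vlincs(n=3)), [], grid_genes(), None, GENOME
            )


class TestSetOverlap:
    def test_trivial_cases(self):
        vl = grid_vlincs()
        whole = IntervalSet([GenomicInterval("synthchr1", 0, GENOME["synthchr1"])])
        res = set_overlap(vl, whole, grid_genes(), None, GENOME)
        assert res.n_observed == res.N and res.p_value == 1.0
        res2 = set_overlap(vl, IntervalSet(), grid_genes(), None, GENOME)
        assert res2.n_observed == 0 and res2.p_value == 1.0

    def test_self_overlap_is_significant(self):
        vl = grid_vlincs(n=10)
        set2 = IntervalSet(v.interval for v in vl)
        res = set_overlap(vl, set2, grid_genes(), None, GENOME)
        assert res.n_observed == 10
        assert res.p_value < 1e-4

    def test_single_base_snp_positions_supported(self):
        vl = grid_vlincs(n=10)
        # one SNP inside each of the first four regions
        snps = IntervalSet(
            GenomicInterval("synthchr1", v.interval.start + 50, v.interval.start + 51)
            for v in vl[:4]
        )
        res = set_overlap(vl, snps, grid_genes(), None, GENOME)
        assert res.n_observed == 4
        assert res.p_value < 0.01


class TestLtrClustering:
    def mk_prom(self, s, e):
        return Promoter(GenomicInterval("synthchr1", s, e), "Active", "K1")

    def mk_ltr(self, s, e, family="LTR7"):
        return RepeatElement(GenomicInterval("synthchr1", s, e, "+"), family, "LTR")

    def test_two_copies_in_one_promoter_form_one_cluster(self):
        proms = [self.mk_prom(0, 5000)]
        ltrs = [self.mk_ltr(100, 500), self.mk_ltr(3000, 3500)]
        assert len(cluster_ltr_elements(ltrs, proms, {0: "v1"})) == 1

    def test_promoters_of_same_vlinc_share_a_cluster(self):
        proms = [self.mk_prom(0, 5000), self.mk_prom(20_000, 25_000)]
        ltrs = [self.mk_ltr(100, 500), self.mk_ltr(21_000, 21_500)]
        same = cluster_ltr_elements(ltrs, proms, {0: "v1", 1: "v1"})
        assert len(same) == 1
        different = cluster_ltr_elements(ltrs, proms, {0: "v1", 1: "v2"})
        assert len(different) == 2

    def test_copy_spanning_two_promoters_is_split(self):
        proms = [self.mk_prom(0, 5000), self.mk_prom(5000, 10_000)]
        ltrs = [self.mk_ltr(4000, 6000)]
        clusters = cluster_ltr_elements(ltrs, proms, {0: "v1", 1: "v2"})
        assert len(clusters) == 2
        frags = sorted(
            (f.start, f.end) for c in clusters for f in c.fragments
        )
        assert frags == [(4000, 5000), (5000, 6000)]

    def test_copies_outside_promoters_are_singletons(self):
        clusters = cluster_ltr_elements(
            [self.mk_ltr(100, 500), self.mk_ltr(9000, 9500)], [], {}
        )
        assert len(clusters) == 2

    def test_mixed_families_rejected(self):
        with pytest.raises(ValueError, match="single repeat family"):
            cluster_ltr_elements(
                [self.mk_ltr(0, 100, "LTR7"), self.mk_ltr(200, 300, "LTR12C")],
                [],
                {},
            )


class TestFamilyEnrichment:
    def seeded_world(self, seed=11, n_vlincs=50, seeded_fraction=0.3,
                     n_decoys=300, decoy_ltr_fraction=0.02, sense_fraction=0.8):
        rng = np.random.default_rng(seed)
        genome = Genome({"synthchr1": 30_000_000})
        vlincs = []
        for i in range(n_vlincs):
            start = 300_000 + i * 550_000
            strand = "+" if rng.random() < 0.5 else "-"
            vlincs.append(
                VlincRNA(
                    GenomicInterval("synthchr1", start, start + 120_000, strand),
                    vlinc_id=f"v{i}",
                )
            )
        genes = IntervalSet(
            GenomicInterval("synthchr1", 200_000 + i * 1_500_000,
                            230_000 + i * 1_500_000, "+")
            for i in range(10)
        )
        promoters, ltrs = [], []
        for v in vlincs:
            b = v.interval.five_prime()
            iv = GenomicInterval("synthchr1", b - 1000, b + 1000)
            promoters.append(Promoter(iv, "Active", "K1"))
            if rng.random() < seeded_fraction:
                strand = (
                    v.strand
                    if rng.random() < sense_fraction
                    else ("-" if v.strand == "+" else "+")
                )
                s = int(rng.integers(iv.start, iv.end - 400))
                ltrs.append(
                    RepeatElement(
                        GenomicInterval("synthchr1", s, s + 400, strand),
                        "LTR7", "LTR",
                    )
                )
        for _ in range(n_decoys):
            s = int(rng.integers(0, genome["synthchr1"] - 2000))
            iv = GenomicInterval("synthchr1", s, s + 2000)
            promoters.append(Promoter(iv, "Active", "K1"))
            if rng.random() < decoy_ltr_fraction:
                ls = int(rng.integers(iv.start, iv.end - 400))
                ltrs.append(
                    RepeatElement(
                        GenomicInterval("synthchr1", ls, ls + 400,
                                        "+" if rng.random() < 0.5 else "-"),
                        "LTR7", "LTR",
                    )
                )
        return genome, vlincs, genes, promoters, ltrs

    def test_seeded_family_detected_and_stranded_is_upper_bound(self):
        genome, vlincs, genes, promoters, ltrs = self.seeded_world()
        res = ltr_family_enrichment(
            "LTR7", ltrs, vlincs, promoters, genes, genome, stranded=False
        )
        assert res.p_value < 1e-4 and res.fold > 5
        res_s = ltr_family_enrichment(
            "LTR7", ltrs, vlincs, promoters, genes, genome, stranded=True
        )
        assert res_s.p_value >= res.p_value

    def test_stranded_p_bounds_exact_per_strand_convolution(self):
        """The B(N+ + N-, max(p+, p-)) tail is an upper bound for the exact
        tail of the sum of the two per-strand binomials."""
        genome, vlincs, genes, promoters, ltrs = self.seeded_world(seed=13)
        res = ltr_family_enrichment(
            "LTR7", ltrs, vlincs, promoters, genes, genome, stranded=True
        )
        # recover per-strand counts to build the exact convolution
        from vlincscan.enrichment import build_anti_space, complement
        from vlincscan.enrichment import _family_counts_one_strand
        from vlincscan.intervals import adjust_boundaries

        parts = {}
        for strand in ("+", "-"):
            tested = IntervalSet(v.interval for v in vlincs if v.strand == strand)
            anti = build_anti_space(
                genes, None, tested, "with-short-gaps", genome=genome, strand=strand
            )
            space = complement(
                adjust_boundaries(anti, -5000, -5000, clip_to=genome), genome
            )
            strand_vlincs = [v for v in vlincs if v.strand == strand]
            strand_ltrs = [r for r in ltrs if r.interval.strand == strand]
            parts[strand] = _family_counts_one_strand(
                strand_ltrs, strand_vlincs, promoters, space, 5000
            )
        (np_, Np, pp), (nm, Nm, pm) = parts["+"], parts["-"]
        pmf = fftconvolve(binom.pmf(np.arange(Np + 1), Np, pp),
                          binom.pmf(np.arange(Nm + 1), Nm, pm))
        exact = float(pmf[np_ + nm:].sum())
        assert res.p_value >= exact - 1e-12

    def test_absent_family_gives_p_one(self):
        genome, vlincs, genes, promoters, ltrs = self.seeded_world()
        far = [
            RepeatElement(
                GenomicInterval("synthchr1", 29_000_000, 29_000_500, "+"),
                "THE1A", "LTR",
            )
        ]
        res = ltr_family_enrichment(
            "THE1A", far, vlincs, promoters, genes, genome, stranded=False
        )
        assert res.n_observed == 0 and res.p_value == 1.0

    def test_all_promoters_vlinc_promoters_gives_p_one(self):
        genome, vlincs, genes, promoters, ltrs = self.seeded_world(
            n_decoys=0, seeded_fraction=0.4
        )
        res = ltr_family_enrichment(
            "LTR7", ltrs, vlincs, promoters, genes, genome, stranded=False
        )
        assert res.success_probs[0] == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)


class TestPermutationOracle:
    def _draw_points(self, space, rng, size):
        """Uniform genomic positions within a flattened space."""
        chunks = []
        for chrom in space.chroms:
            s, e, _ = space._cover(chrom)
            chunks.append((chrom, s, e, (e - s)))
        lens = np.concatenate([c[3] for c in chunks])
        cum = np.cumsum(lens)
        offs = rng.integers(0, cum[-1], size=size)
        idx = np.searchsorted(cum, offs, side="right")
        starts = np.concatenate([c[1] for c in chunks])
        return starts[idx] + (offs - (cum[idx] - lens[idx]))

    @pytest.mark.parametrize("k_planted, max_reported_p", [(20, 1e-6), (6, 0.05)])
    def test_binomial_p_not_smaller_than_uniform_redraw_estimate(
        self, k_planted, max_reported_p
    ):
        """Redraw each vlincRNA boundary point uniformly within its eligible
        space and re-count promoter hits: the analytic binomial p-value must
        not overstate significance relative to this empirical null."""
        vl = grid_vlincs()
        proms = planted_promoters(vl, k=k_planted)
        genes = grid_genes()
        space = build_promoter_space_stranded(vl, genes, None, GENOME)
        res = promoter_overlap_stranded(
            vl, proms, genes, None, GENOME, space=space
        )
        assert res.p_value < max_reported_p

        ext = IntervalSet(
            GenomicInterval(p.interval.chrom, p.interval.start - 5000 + 1,
                            p.interval.end + 5000 - 1)
            for p in proms
        ).collapse_strands()
        rng = np.random.default_rng(17)
        reps = 3000
        hits = np.zeros(reps, dtype=np.int64)
        for i, sp in enumerate(space.per_element_space):
            pts = self._draw_points(sp, rng, reps)
            s, e, _ = ext._cover("synthchr1")
            j = np.searchsorted(s, pts, side="right")
            inside = (j > 0) & (pts < e[np.maximum(j - 1, 0)])
            hits += inside
        p_perm = float(np.mean(hits >= res.n_observed))
        se = max(np.sqrt(p_perm * (1 - p_perm) / reps), 1.0 / reps)
        assert res.p_value <= p_perm + 3 * se
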