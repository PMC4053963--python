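"""Binomial overlap-enrichment tests on an explicit genomic-space null.

Five procedures are provided, all sharing the same skeleton: for each tested
element an *eligible space* is constructed (the genome minus an "anti-space"
of annotated genes, blacklisted regions and, in some variants, short
inter-gene gaps, with element-length-dependent boundary extensions), a
per-element success probability is derived from the fraction of that space
occupied by the subject feature, and the observed number of overlaps is
compared against a binomial upper tail.

* :func:`test_promoter_overlap_stranded`   — stranded vlincRNAs vs promoters
  (one 10 kb window at the 5' boundary).
* :func:`test_promoter_overlap_unstranded` — unstranded vlincRNAs vs promoters
  (two windows, one per boundary; p_i = 1 - (1 - p_i+)(1 - p_i-)).
* :func:`test_set_overlap`                 — one region set vs another
  (symmetric L_i/2 extensions; also applicable to SNP positions).
* :func:`test_ltr_family_enrichment`       — repeat-family enrichment in
  vlincRNA promoters, over clusters of same-family repeats; the stranded
  variant reports an explicit upper bound B(N+ + N-, max(p+, p-)).

The subtraction of V (the total tested-region length) from each |Space_i|
makes every procedure an upper-bound (conservative) estimate, compensating
for the multiple regions tested. Success probabilities are clamped to [0, 1];
tail probabilities are computed in log space and remain finite down to
printed magnitudes of 1e-300 and below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .annotation import Promoter, RepeatElement, vlinc_boundary_windows
from .caller import VlincRNA
from .intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    adjust_boundaries,
    complement,
    interior_gaps,
    merge_within_gap,
    overlap_flags,
    subtract,
    union_length,
)

SHORT_GAP_MAX = 50_000  # inter-gene gaps below this length join the anti-space

LOG10E = math.log10(math.e)

ANTI_SPACE_MODES = ("stranded-same", "either-strand", "with-short-gaps")


# ---------------------------------------------------------------------------
# binomial tail
# ---------------------------------------------------------------------------

def binomial_upper_tail(N: int, q: float, n: int) -> float:
    """P(X >= n) for X ~ Binomial(N, q), exact via the regularized incomplete
    beta function. May underflow to 0.0 for extreme tails; see the log10
    variant for those."""
    if not (0 <= q <= 1):
        raise ValueError("success probability must be in [0, 1]")
    if not (0 <= n <= N):
        raise ValueError("threshold n must satisfy 0 <= n <= N")
    if n == 0:
        return 1.0
    return float(binom.sf(n - 1, N, q))


def log10_binomial_upper_tail(N: int, q: float, n: int) -> float:
    """log10 P(X >= n); finite even when the tail underflows a float."""
    if not (0 <= q <= 1):
        raise ValueError("success probability must be in [0, 1]")
    if not (0 <= n <= N):
        raise ValueError("threshold n must satisfy 0 <= n <= N")
    if n == 0:
        return 0.0
    if q == 0.0:
        return -math.inf
    if q == 1.0:
        return 0.0
    logp = float(binom.logsf(n - 1, N, q))
    if not math.isfinite(logp):
        # deeper than the double-precision survival function reaches:
        # sum the log pmf terms directly
        k = np.arange(n, N + 1, dtype=np.float64)
        logpmf = (
            gammaln(N + 1)
            - gammaln(k + 1)
            - gammaln(N - k + 1)
            + k * math.log(q)
            + (N - k) * math.log1p(-q)
        )
        logp = float(logsumexp(logpmf))
    return logp * LOG10E


@dataclass(frozen=True)
class EnrichmentResult:
    N: int
    n_observed: int
    m_expected: float
    success_probs: Tuple[float, ...]
    p_value: float
    log10_p: float

    @property
    def fold(self) -> float:
        """Observed over expected ("fold over chance")."""
        if self.m_expected > 0:
            return self.n_observed / self.m_expected
        return math.nan


def _result(N: int, n: int, m: float, probs: Sequence[float]) -> EnrichmentResult:
    q = min(max(m / N, 0.0), 1.0) if N > 0 else 0.0
    p = binomial_upper_tail(N, q, n)
    logp = log10_binomial_upper_tail(N, q, n)
    if p == 0.0:
        p = 10.0 ** max(logp, -323.0)
    return EnrichmentResult(
        N=N,
        n_observed=n,
        m_expected=m,
        success_probs=tuple(float(x) for x in probs),
        p_value=p,
        log10_p=logp,
    )


# ---------------------------------------------------------------------------
# space construction
# ---------------------------------------------------------------------------

def build_anti_space(
    genes: IntervalSet,
    blacklist: IntervalSet | None,
    tested_vlincs: IntervalSet | None,
    mode: str,
    genome: Genome | None = None,
    strand: str | None = None,
    short_gap_max: int = SHORT_GAP_MAX,
) -> IntervalSet:
    """The excluded territory of the null model.

    * ``stranded-same``  — genes on ``strand`` ("." genes match both) plus the
      blacklist; genes on the opposite strand count as intergenic.
    * ``either-strand``  — genes on both strands plus the blacklist.
    * ``with-short-gaps``— genes (on ``strand`` when given) plus inter-gene
      gaps shorter than ``short_gap_max``; no blacklist term in this variant.

    In every mode, bases overlapping ``tested_vlincs`` are subtracted and the
    result is flattened (unstranded).
    """
    if mode not in ANTI_SPACE_MODES:
        raise ValueError(f"unknown anti-space mode {mode!r}")
    if mode == "stranded-same":
        if strand is None:
            raise ValueError("stranded-same mode requires a strand")
        base = genes.restrict_strand(strand)
        parts = [base.collapse_strands()]
        if blacklist is not None:
            parts.append(blacklist.collapse_strands())
    elif mode == "either-strand":
        parts = [genes.collapse_strands()]
        if blacklist is not None:
            parts.append(blacklist.collapse_strands())
    else:  # with-short-gaps
        if genome is None:
            raise ValueError("with-short-gaps mode requires a genome")
        base = genes.restrict_strand(strand) if strand is not None else genes
        base = base.collapse_strands()
        gaps = interior_gaps(base, genome, max_length=short_gap_max)
        parts = [base, gaps]
    merged = IntervalSet(iv for part in parts for iv in part).collapse_strands()
    if tested_vlincs is not None and len(tested_vlincs):
        merged = subtract(merged, tested_vlincs)
    return merged.collapse_strands()


def _intersection_length(space: IntervalSet, other: IntervalSet) -> int:
    """|space ∩ other| in bases, strand-blind, via prefix sums."""
    total = 0
    for chrom in other.chroms:
        bs, be, _ = other._cover(chrom)
        ss, se, cum = space._cover(chrom)
        if not ss.size or not bs.size:
            continue
        total += int(
            np.sum(_covered_many(ss, se, cum, be) - _covered_many(ss, se, cum, bs))
        )
    return total


def _covered_many(
    ss: np.ndarray, se: np.ndarray, cum: np.ndarray, xs: np.ndarray
) -> np.ndarray:
    """Vectorised covered-bases-before-x for a flattened interval array."""
    idx = np.searchsorted(ss, xs, side="right")
    out = np.zeros(xs.shape, dtype=np.int64)
    nz = idx > 0
    i = idx[nz] - 1
    partial = np.minimum(se[i], xs[nz]) - ss[i]
    out[nz] = cum[i] + np.maximum(partial, 0)
    return out


@dataclass
class SpaceModel:
    """Precomputed per-element eligible spaces for the promoter/set tests.

    ``per_element_space[i]`` is vlincRNA i's Space_i; ``space_lengths[i]`` its
    total length; ``V`` the union length of all tested regions. Building the
    model once lets the subject features (promoters / set 2) vary cheaply,
    which the Monte-Carlo calibration tests exploit.
    """

    genome: Genome
    per_element_space: List[IntervalSet]
    space_lengths: np.ndarray
    V: int
    anti_space: Dict[str, IntervalSet] = field(default_factory=dict)

    def success_probs(self, occupied: np.ndarray) -> np.ndarray:
        denom = self.space_lengths - self.V
        if np.any(denom <= 0):
            raise ValueError("degenerate space: |Space_i| <= V")
        return np.clip(occupied / denom, 0.0, 1.0)


def _space_for(
    anti: IntervalSet,
    genome: Genome,
    left_ext: int,
    right_ext: int,
) -> IntervalSet:
    """Genome minus anti-space intervals extended by (left_ext, right_ext)."""
    extended = adjust_boundaries(anti, left_ext, right_ext, clip_to=genome)
    return complement(extended, genome)


def build_promoter_space_stranded(
    vlincs: Sequence[VlincRNA],
    genes: IntervalSet,
    blacklist: IntervalSet | None,
    genome: Genome,
) -> SpaceModel:
    """Per-element spaces for the stranded promoter test.

    Anti-space is built per strand from same-strand genes; each vlincRNA's
    Space_i extends the anti-space intervals' 5'-side boundary (left for plus
    strand, right for minus) by the vlincRNA's length.
    """
    tested = IntervalSet(v.interval for v in vlincs)
    V = union_length(tested)
    anti: Dict[str, IntervalSet] = {}
    for strand in ("+", "-"):
        anti[strand] = build_anti_space(
            genes, blacklist, tested.restrict_strand(strand), "stranded-same",
            strand=strand,
        )
    spaces = []
    lengths = []
    for v in vlincs:
        if v.strand == ".":
            raise ValueError("stranded promoter test requires stranded vlincRNAs")
        L = v.length
        if v.strand == "+":
            sp = _space_for(anti["+"], genome, L, 0)
        else:
            sp = _space_for(anti["-"], genome, 0, L)
        spaces.append(sp)
        lengths.append(union_length(sp))
    return SpaceModel(genome, spaces, np.asarray(lengths, dtype=np.int64), V, anti)


def build_promoter_space_unstranded(
    vlincs: Sequence[VlincRNA],
    genes: IntervalSet,
    blacklist: IntervalSet | None,
    genome: Genome,
) -> Tuple[SpaceModel, SpaceModel]:
    """(left-extended, right-extended) space models for the unstranded test."""
    tested = IntervalSet(v.interval for v in vlincs)
    V = union_length(tested)
    anti = build_anti_space(genes, blacklist, tested, "either-strand")
    plus_spaces, minus_spaces = [], []
    plus_len, minus_len = [], []
    for v in vlincs:
        L = v.length
        sp = _space_for(anti, genome, L, 0)
        sm = _space_for(anti, genome, 0, L)
        plus_spaces.append(sp)
        minus_spaces.append(sm)
        plus_len.append(union_length(sp))
        minus_len.append(union_length(sm))
    return (
        SpaceModel(genome, plus_spaces, np.asarray(plus_len, dtype=np.int64), V,
                   {".": anti}),
        SpaceModel(genome, minus_spaces, np.asarray(minus_len, dtype=np.int64), V,
                   {".": anti}),
    )


def build_set_overlap_space(
    set1: Sequence[VlincRNA] | Sequence[GenomicInterval],
    genes: IntervalSet,
    blacklist: IntervalSet | None,
    genome: Genome,
) -> SpaceModel:
    """Per-element spaces for the set-vs-set test (symmetric L_i/2 extension)."""
    ivs = [v.interval if isinstance(v, VlincRNA) else v for v in set1]
    tested = IntervalSet(ivs)
    V = union_length(tested)
    anti = build_anti_space(genes, blacklist, tested, "either-strand")
    spaces, lengths = [], []
    for iv in ivs:
        half = iv.length // 2
        sp = _space_for(anti, genome, half, half)
        spaces.append(sp)
        lengths.append(union_length(sp))
    return SpaceModel(genome, spaces, np.asarray(lengths, dtype=np.int64), V,
                      {".": anti})


# ---------------------------------------------------------------------------
# procedures I-III
# ---------------------------------------------------------------------------

def _extended_promoter_set(
    promoters: Sequence[Promoter] | IntervalSet,
    genome: Genome,
    halfwidth: int,
) -> Tuple[IntervalSet, IntervalSet]:
    """(raw, extended-by-halfwidth) promoter interval sets."""
    if isinstance(promoters, IntervalSet):
        raw = promoters
    else:
        raw = IntervalSet(p.interval for p in promoters)
    ext = adjust_boundaries(raw, halfwidth, halfwidth, clip_to=genome)
    return raw, ext.collapse_strands()


def test_promoter_overlap_stranded(
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter] | IntervalSet,
    genes: IntervalSet,
    blacklist: IntervalSet | None,
    genome: Genome,
    window_halfwidth: int = 5000,
    space: SpaceModel | None = None,
) -> EnrichmentResult:
    """Stranded vlincRNAs vs promoters (procedure with one 5'-boundary window).
    """
    if not vlincs:
        raise ValueError("no vlincRNAs to test")
    if space is None:
        space = build_promoter_space_stranded(vlincs, genes, blacklist, genome)
    raw, ext = _extended_promoter_set(promoters, genome, window_halfwidth)
    windows = [w for v in vlincs for w in vlinc_boundary_windows(v, window_halfwidth)]
    n = int(overlap_flags(windows, raw).sum())
    occ = np.array(
        [_intersection_length(sp, ext) for sp in space.per_element_space],
        dtype=np.float64,
    )
    probs = space.success_probs(occ)
    m = float(probs.sum())
    return _result(len(vlincs), n, m, probs)


def test_promoter_overlap_unstranded(
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter] | IntervalSet,
    genes: IntervalSet,
    blacklist: IntervalSet | None,
    genome: Genome,
    window_halfwidth: int = 5000,
    spaces: Tuple[SpaceModel, SpaceModel] | None = None,
) -> EnrichmentResult:
    """Unstranded vlincRNAs vs promoters: two boundary windows per region,
    p_i = 1 - (1 - p_i+)(1 - p_i-)."""
    if not vlincs:
        raise ValueError("no vlincRNAs to test")
    if spaces is None:
        spaces = build_promoter_space_unstranded(vlincs, genes, blacklist, genome)
    space_plus, space_minus = spaces
    raw, ext = _extended_promoter_set(promoters, genome, window_halfwidth)
    n = 0
    for v in vlincs:
        ws = vlinc_boundary_windows(v, window_halfwidth)
        if overlap_flags(ws, raw).any():
            n += 1
    occ_p = np.array(
        [_intersection_length(sp, ext) for sp in space_plus.per_element_space],
        dtype=np.float64,
    )
    occ_m = np.array(
        [_intersection_length(sp, ext) for sp in space_minus.per_element_space],
        dtype=np.float64,
    )
    p_plus = space_plus.success_probs(occ_p)
    p_minus = space_minus.success_probs(occ_m)
    probs = 1.0 - (1.0 - p_plus) * (1.0 - p_minus)
    m = float(probs.sum())
    return _result(len(vlincs), n, m, probs)


def test_set_overlap(
    set1: Sequence[VlincRNA] | Sequence[GenomicInterval],
    set2: IntervalSet,
    genes: IntervalSet,
    blacklist: IntervalSet | None,
    genome: Genome,
    space: SpaceModel | None = None,
) -> EnrichmentResult:
    """How many regions of set 1 overlap set 2 (regions or SNP positions)."""
    if not set1:
        raise ValueError("set 1 is empty")
    ivs = [v.interval if isinstance(v, VlincRNA) else v for v in set1]
    if space is None:
        space = build_set_overlap_space(set1, genes, blacklist, genome)
    n = int(overlap_flags(ivs, set2).sum())
    occ = np.empty(len(ivs), dtype=np.float64)
    for i, (iv, sp) in enumerate(zip(ivs, space.per_element_space)):
        half = iv.length // 2
        ext = adjust_boundaries(set2, half, half, clip_to=genome).collapse_strands()
        occ[i] = _intersection_length(sp, ext)
    probs = space.success_probs(occ)
    m = float(probs.sum())
    return _result(len(ivs), n, m, probs)


# ---------------------------------------------------------------------------
# procedures IV-V: repeat-family enrichment in vlincRNA promoters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LtrCluster:
    """A cluster of same-family repeat copies treated as one null trial."""

    family: str
    fragments: Tuple[GenomicInterval, ...]

    def overlaps_set(self, iset: IntervalSet) -> bool:
        return bool(overlap_flags(list(self.fragments), iset).any())


def cluster_ltr_elements(
    ltrs: Sequence[RepeatElement],
    promoters: Sequence[Promoter],
    promoter_to_vlinc: Mapping[int, str],
) -> List[LtrCluster]:
    """Collapse same-family repeat copies into clusters.

    Copies lying in the same promoter, or in promoters assigned to the same
    vlincRNA, form one cluster. A copy overlapping several promoters is split
    at each promoter into one fragment per promoter before clustering. Copies
    outside all promoters are singleton clusters. All repeats given must be of
    one family.
    """
    families = {r.family for r in ltrs}
    if len(families) > 1:
        raise ValueError("cluster_ltr_elements takes a single repeat family")
    family = families.pop() if families else ""

    # union-find over promoter indices, keyed by shared vlinc id
    parent = list(range(len(promoters)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    by_vlinc: Dict[str, List[int]] = {}
    for idx, vid in promoter_to_vlinc.items():
        by_vlinc.setdefault(vid, []).append(idx)
    for idxs in by_vlinc.values():
        for other in idxs[1:]:
            union(idxs[0], other)

    pivs = [p.interval for p in promoters]
    clusters: Dict[int, List[GenomicInterval]] = {}
    singletons: List[LtrCluster] = []
    for r in ltrs:
        iv = r.interval
        hits = [
            i
            for i, p in enumerate(pivs)
            if p.chrom == iv.chrom and iv.start < p.end and p.start < iv.end
        ]
        if not hits:
            singletons.append(LtrCluster(family, (iv,)))
            continue
        if len(hits) == 1:
            frags = [(hits[0], iv)]
        else:
            # split at promoter boundaries: one fragment per overlapped promoter
            frags = []
            for i in hits:
                p = pivs[i]
                lo, hi = max(iv.start, p.start), min(iv.end, p.end)
                frags.append(
                    (i, GenomicInterval(iv.chrom, lo, hi, iv.strand))
                )
        for i, frag in frags:
            clusters.setdefault(find(i), []).append(frag)
    out = [
        LtrCluster(family, tuple(frs)) for _, frs in sorted(clusters.items())
    ]
    return out + singletons


def _vlinc_promoter_subset(
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter],
    window_halfwidth: int = 5000,
) -> Tuple[List[int], Dict[int, str]]:
    """Promoter indices overlapping the 10 kb window at each vlincRNA 5' edge,
    plus a promoter-index -> vlinc-id map (first assignment wins)."""
    from .annotation import assign_promoters_to_vlincs

    assignments = assign_promoters_to_vlincs(vlincs, promoters, window_halfwidth)
    chosen: List[int] = []
    pro2vlinc: Dict[int, str] = {}
    for a in assignments:
        for idx in a.promoter_indices:
            if idx not in pro2vlinc:
                pro2vlinc[idx] = a.vlinc_id
                chosen.append(idx)
    return sorted(chosen), pro2vlinc


def test_ltr_family_enrichment(
    family: str,
    ltrs: Sequence[RepeatElement],
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter],
    genes: IntervalSet,
    genome: Genome,
    all_vlincs: Sequence[VlincRNA] | None = None,
    stranded: bool = False,
    window_halfwidth: int = 5000,
    shrink: int = 5000,
) -> EnrichmentResult:
    """Enrichment of one repeat family in vlincRNA promoters.

    Unstranded: n = family clusters overlapping vlincRNA promoters,
    N = clusters overlapping "space promoters" (promoters that overlap the
    eligible space), p = |vlinc promoters| / |space promoters|, tail from
    B(N, p). Stranded: the per-strand counts relative to the vlincRNA strand
    are combined into the explicit upper bound B(N+ + N-, max(p+, p-)).

    ``all_vlincs`` (default: ``vlincs``) is the union of regions, across all
    profiled samples, subtracted from the anti-space.
    """
    fam_ltrs = [r for r in ltrs if r.family == family]
    if all_vlincs is None:
        all_vlincs = vlincs

    if not stranded:
        tested = IntervalSet(v.interval for v in all_vlincs)
        anti = build_anti_space(
            genes, None, tested, "with-short-gaps", genome=genome
        )
        space = complement(
            adjust_boundaries(anti, -shrink, -shrink, clip_to=genome), genome
        )
        return _family_test_one_strand(
            fam_ltrs, vlincs, promoters, space, window_halfwidth
        )

    parts = {}
    for strand in ("+", "-"):
        tested = IntervalSet(
            v.interval for v in all_vlincs if v.strand == strand
        )
        anti = build_anti_space(
            genes, None, tested, "with-short-gaps", genome=genome, strand=strand
        )
        space = complement(
            adjust_boundaries(anti, -shrink, -shrink, clip_to=genome), genome
        )
        strand_vlincs = [v for v in vlincs if v.strand == strand]
        strand_ltrs = [r for r in fam_ltrs if r.interval.strand == strand]
        parts[strand] = _family_counts_one_strand(
            strand_ltrs, strand_vlincs, promoters, space, window_halfwidth
        )
    n = parts["+"][0] + parts["-"][0]
    N = parts["+"][1] + parts["-"][1]
    p_plus, p_minus = parts["+"][2], parts["-"][2]
    q = max(p_plus, p_minus)
    m = parts["+"][1] * p_plus + parts["-"][1] * p_minus
    p = binomial_upper_tail(N, q, n)
    logp = log10_binomial_upper_tail(N, q, n)
    if p == 0.0:
        p = 10.0 ** max(logp, -323.0)
    return EnrichmentResult(
        N=N, n_observed=n, m_expected=m,
        success_probs=(p_plus, p_minus), p_value=p, log10_p=logp,
    )


def _family_counts_one_strand(
    fam_ltrs: Sequence[RepeatElement],
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter],
    space: IntervalSet,
    window_halfwidth: int,
) -> Tuple[int, int, float]:
    """(n, N, p) for one strand / the unstranded pool."""
    vp_idx, pro2vlinc = _vlinc_promoter_subset(vlincs, promoters, window_halfwidth)
    vlinc_prom_set = IntervalSet(promoters[i].interval for i in vp_idx)
    space_prom_idx = [
        i
        for i, p in enumerate(promoters)
        if overlap_flags([p.interval], space)[0] or i in set(vp_idx)
    ]
    space_prom_set = IntervalSet(promoters[i].interval for i in space_prom_idx)
    vp_len = union_length(vlinc_prom_set)
    sp_len = union_length(space_prom_set)
    if sp_len == 0 and promoters:
        raise ValueError("no promoters overlap the eligible space")
    clusters = cluster_ltr_elements(fam_ltrs, promoters, pro2vlinc)
    n = sum(1 for c in clusters if len(vlinc_prom_set) and c.overlaps_set(vlinc_prom_set))
    N = sum(1 for c in clusters if len(space_prom_set) and c.overlaps_set(space_prom_set))
    p = vp_len / sp_len if sp_len > 0 else 0.0
    return n, N, min(p, 1.0)


def _family_test_one_strand(
    fam_ltrs: Sequence[RepeatElement],
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter],
    space: IntervalSet,
    window_halfwidth: int,
) -> EnrichmentResult:
    n, N, p = _family_counts_one_strand(
        fam_ltrs, vlincs, promoters, space, window_halfwidth
    )
    return _result(N, n, N * p, [p])
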