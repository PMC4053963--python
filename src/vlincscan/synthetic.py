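"""Fully synthetic genomes, annotations and coverage with planted ground truth.

The generator emulates the statistical structure of the data the pipeline is
designed for: multi-chromosome genomes carrying annotated genes; a panel of
cell lines spanning malignant, immortalized, primary and embryonic-stem
groups; planted vlincRNA regions (50 kb - 1 Mb) whose 5'-boundary promoters
are Active in their source line and embedded in LTR repeats at a
group-dependent rate (high in malignant/pluripotent lines, low in primary
ones); decoy promoters and background repeats; blacklist regions; and
per-sample coverage in both the strand-specific contig dialect and the
unstranded per-base density dialect.

One global seed drives named substreams (annotation / contigs / density /
shuffle), so regenerating one layer does not perturb the others. Chromosome
names use a reserved "synthchr" prefix to prevent accidental mixing with real
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .annotation import Promoter, RepeatElement
from .caller import Contig, VlincRNA
from .expression import ExpressionMatrix
from .intervals import Genome, GenomicInterval, IntervalSet, adjust_boundaries, complement
from .tracks import DensityTrack

import pandas as pd

# substream keys
_ANNOTATION, _CONTIGS, _DENSITY, _SHUFFLE, _MATRIX = range(5)


class SimulationError(ValueError):
    pass


def _rng(seed: int, layer: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(layer,)))


def _log_uniform(rng: np.random.Generator, lo: int, hi: int, size=None) -> np.ndarray:
    x = np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))
    return np.asarray(np.round(x), dtype=np.int64)


DEFAULT_CELL_LINES: Tuple[Tuple[str, str], ...] = (
    ("malig1", "malignant"),
    ("malig2", "malignant"),
    ("immort1", "immortalized"),
    ("primary1", "primary"),
    ("primary2", "primary"),
    ("esc1", "embryonic-stem"),
)

DEFAULT_LTR_PROMOTER_FRACTION: Dict[str, float] = {
    "primary": 0.03,
    "immortalized": 0.10,
    "malignant": 0.25,
    "embryonic-stem": 0.50,
    "other": 0.0,
}

DEFAULT_REPEAT_FAMILIES: Tuple[Tuple[str, str, int], ...] = (
    # (family, class, background copies per genome)
    ("LTR7", "LTR", 120),
    ("LTR12C", "LTR", 80),
    ("AluY", "other retroposon", 300),
    ("L1PA4", "other retroposon", 120),
)


@dataclass(frozen=True)
class SimParams:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 60
    gene_length_range: Tuple[int, int] = (5_000, 50_000)
    cell_lines: Tuple[Tuple[str, str], ...] = DEFAULT_CELL_LINES
    n_planted_vlincs: int = 5  # per cell line
    vlinc_length_range: Tuple[int, int] = (50_000, 1_000_000)  # log-uniform
    min_feature_gap: int = 12_000  # separation between planted features
    promoter_width: int = 2_000
    n_decoy_promoters_per_line: int = 40
    decoy_promoter_ltr_fraction: float = 0.02
    promoter_state_probs: Tuple[Tuple[str, float], ...] = (
        ("Active", 0.5), ("Weak", 0.3), ("Poised", 0.2),
    )
    ltr_promoter_fraction: Tuple[Tuple[str, float], ...] = tuple(
        DEFAULT_LTR_PROMOTER_FRACTION.items()
    )
    planted_ltr_family: str = "LTR7"
    planted_ltr_sense_fraction: float = 0.8  # LTR on the vlincRNA's strand
    repeat_families: Tuple[Tuple[str, str, int], ...] = DEFAULT_REPEAT_FAMILIES
    n_blacklist: int = 4
    blacklist_length: int = 30_000
    # contig emission
    contig_length_range: Tuple[int, int] = (500, 3_000)
    contig_gap_range: Tuple[int, int] = (50, 400)
    sparse_spacing: int = 15_000
    sparse_contig_length: int = 1_000
    noise_contigs_per_mb: float = 0.5
    noise_contig_length_range: Tuple[int, int] = (200, 2_000)
    noise_contig_density: float = 0.5
    cross_expression: bool = True
    # expression model (dimensionless densities); kept low enough that
    # emitted contig counts stay below the quantifier's artifact cutoff
    base_expression: float = 1.0
    expression_sigma: float = 0.5
    source_boost: float = 20.0
    off_factor_primary: Tuple[float, float] = (1.0, 0.05)  # (non-LTR, LTR)
    off_factor_elevated: Tuple[float, float] = (2.0, 1.0)
    # density emission
    density_noise: bool = True
    density_noise_run_range: Tuple[int, int] = (5_000, 40_000)

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length <= 0:
            raise ValueError("need >= 1 chromosome with positive length")
        for lo, hi in (self.gene_length_range, self.vlinc_length_range):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must satisfy 0 < lo <= hi")
        for _, frac in self.ltr_promoter_fraction:
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if not (0.0 <= self.decoy_promoter_ltr_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def groups(self) -> Dict[str, str]:
        return dict(self.cell_lines)

    @property
    def ltr_fraction_by_group(self) -> Dict[str, float]:
        return dict(self.ltr_promoter_fraction)


@dataclass
class PlantedVlinc:
    vlinc: VlincRNA
    promoter_id: int  # index into the source line's promoter list
    ltr_driven: bool
    expression: Dict[str, float]  # sample -> density

    @property
    def source_sample(self) -> str:
        return self.vlinc.source_sample


@dataclass
class TruthSet:
    planted: List[PlantedVlinc]

    def for_sample(self, sample: str) -> List[PlantedVlinc]:
        return [p for p in self.planted if p.source_sample == sample]

    def vlincs_for_sample(self, sample: str) -> List[VlincRNA]:
        return [p.vlinc for p in self.for_sample(sample)]

    def all_vlincs(self) -> List[VlincRNA]:
        return [p.vlinc for p in self.planted]


@dataclass
class Simulation:
    params: SimParams
    genome: Genome
    genes: List[GenomicInterval]
    promoters_by_line: Dict[str, List[Promoter]]
    repeats: List[RepeatElement]
    blacklist: IntervalSet
    truth: TruthSet

    @property
    def gene_set(self) -> IntervalSet:
        return IntervalSet(self.genes)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _pack_features(
    rng: np.random.Generator,
    genome: Genome,
    lengths: Sequence[int],
    min_gap: int,
) -> List[Tuple[str, int, int]]:
    """Place features of the given lengths on the genome, in the given order
    of identity, at uniformly random non-overlapping positions separated by at
    least ``min_gap`` bases. Raises SimulationError when they cannot fit."""
    chroms = list(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(len(chroms), size=len(lengths), p=weights)
    placements: List[Tuple[str, int, int]] = [("", 0, 0)] * len(lengths)
    for ci, chrom in enumerate(chroms):
        idx = [i for i in range(len(lengths)) if assignment[i] == ci]
        rng.shuffle(idx)
        total = sum(lengths[i] for i in idx)
        k = len(idx)
        slack = genome[chrom] - total - (k + 1) * min_gap
        if slack < 0:
            raise SimulationError(
                f"requested features exceed genome capacity on {chrom} "
                f"(need {total + (k + 1) * min_gap:,}, have {genome[chrom]:,})"
            )
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = min_gap + int(extra[0])
        for j, i in enumerate(idx):
            placements[i] = (chrom, pos, pos + lengths[i])
            pos += lengths[i] + min_gap + int(extra[j + 1])
    return placements


def _uniform_placements(
    rng: np.random.Generator,
    lengths: Sequence[int],
    eligible: IntervalSet,
) -> List[GenomicInterval]:
    """Place each feature uniformly at random (length-preserving) within the
    eligible space; overlapping placements are allowed."""
    slots: List[Tuple[str, int, int]] = []
    for chrom in eligible.chroms:
        s, e, _ = eligible._cover(chrom)
        slots.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
    out = []
    for L in lengths:
        weights = np.array(
            [max(0, (b - a) - L + 1) for _, a, b in slots], dtype=np.int64
        )
        W = int(weights.sum())
        if W == 0:
            raise SimulationError(
                f"feature of length {L} does not fit in the eligible space"
            )
        r = int(rng.integers(W))
        cum = np.cumsum(weights)
        k = int(np.searchsorted(cum, r, side="right"))
        offset = r - (int(cum[k - 1]) if k else 0)
        chrom, a, _ = slots[k]
        out.append(GenomicInterval(chrom, a + offset, a + offset + L))
    return out


def null_shuffle(
    features: IntervalSet,
    eligible_space: IntervalSet,
    seed: int | np.random.Generator,
) -> IntervalSet:
    """Redraw each feature uniformly (length-preserving) within the eligible
    space; strands are preserved, non-overlap of placements is not enforced.
    The null oracle for the enrichment calibration tests."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), _SHUFFLE)
    ivs = list(features)
    placed = _uniform_placements(rng, [iv.length for iv in ivs], eligible_space)
    return IntervalSet(
        GenomicInterval(p.chrom, p.start, p.end, iv.strand)
        for p, iv in zip(placed, ivs)
    )


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

def simulate_annotation(params: SimParams) -> Simulation:
    """Generate genome, genes, promoters per cell line, repeats, blacklist
    and the planted-truth set. Deterministic given ``params.seed``."""
    rng = _rng(params.seed, _ANNOTATION)
    genome = Genome(
        {f"synthchr{i + 1}": params.chrom_length for i in range(params.n_chroms)}
    )
    lines = [name for name, _ in params.cell_lines]
    groups = params.groups
    ltr_frac = params.ltr_fraction_by_group

    # --- plant genes and vlincRNAs jointly, non-overlapping, separated ----
    gene_lengths = _log_uniform(
        rng, *params.gene_length_range, size=params.n_genes
    )
    vlinc_meta: List[Tuple[str, int]] = [
        (line, j)
        for line in lines
        for j in range(params.n_planted_vlincs)
    ]
    vlinc_lengths = _log_uniform(
        rng, *params.vlinc_length_range, size=len(vlinc_meta)
    )
    all_lengths = list(gene_lengths) + list(vlinc_lengths)
    placements = _pack_features(rng, genome, all_lengths, params.min_feature_gap)

    genes: List[GenomicInterval] = []
    for i in range(params.n_genes):
        chrom, s, e = placements[i]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GenomicInterval(chrom, s, e, strand))

    promoters_by_line: Dict[str, List[Promoter]] = {line: [] for line in lines}
    repeats: List[RepeatElement] = []
    planted: List[PlantedVlinc] = []
    planted_promoter_ivs: List[GenomicInterval] = []

    half_pw = params.promoter_width // 2
    for k, (line, j) in enumerate(vlinc_meta):
        chrom, s, e = placements[params.n_genes + k]
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, s, e, strand)
        vid = f"{line}_planted_{j + 1}"
        v = VlincRNA(iv, source_sample=line, vlinc_id=vid)
        b = iv.five_prime()
        prom_iv = GenomicInterval(chrom, max(0, b - half_pw), b + half_pw)
        ltr_driven = bool(rng.random() < ltr_frac.get(groups[line], 0.0))
        if ltr_driven:
            ltr_len = int(rng.integers(300, 800))
            lo = prom_iv.start
            hi = prom_iv.end - ltr_len
            start = int(rng.integers(lo, max(lo + 1, hi)))
            if rng.random() < params.planted_ltr_sense_fraction:
                ltr_strand = strand
            else:
                ltr_strand = "-" if strand == "+" else "+"
            repeats.append(
                RepeatElement(
                    GenomicInterval(chrom, start, start + ltr_len, ltr_strand),
                    family=params.planted_ltr_family,
                    repeat_class="LTR",
                )
            )
        promoter = Promoter(
            interval=prom_iv, state="Active", cell_line=line, ltr_overlap=False
        )
        pid = len(promoters_by_line[line])
        promoters_by_line[line].append(promoter)
        planted_promoter_ivs.append(prom_iv)
        planted.append(
            PlantedVlinc(vlinc=v, promoter_id=pid, ltr_driven=ltr_driven,
                         expression={})
        )

    # --- leftover space for decoys / repeats / blacklist ------------------
    occupied = IntervalSet(
        list(genes)
        + [p.vlinc.interval for p in planted]
        + planted_promoter_ivs
    )
    margin = 2_000
    eligible = complement(
        adjust_boundaries(occupied, margin, margin, clip_to=genome), genome
    )

    # decoy promoters, per line
    state_names = [s for s, _ in params.promoter_state_probs]
    state_probs = np.array([p for _, p in params.promoter_state_probs])
    state_probs = state_probs / state_probs.sum()
    decoy_promoter_ivs: List[GenomicInterval] = []
    for line in lines:
        widths = rng.integers(1_000, 3_000, size=params.n_decoy_promoters_per_line)
        placed = _uniform_placements(rng, list(widths), eligible)
        states = rng.choice(len(state_names), size=len(placed), p=state_probs)
        for iv, si in zip(placed, states):
            promoters_by_line[line].append(
                Promoter(interval=iv, state=state_names[int(si)], cell_line=line)
            )
            decoy_promoter_ivs.append(iv)
            if rng.random() < params.decoy_promoter_ltr_fraction:
                ltr_len = int(rng.integers(300, min(800, iv.length)))
                start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - ltr_len)))
                repeats.append(
                    RepeatElement(
                        GenomicInterval(
                            iv.chrom, start, start + ltr_len,
                            "+" if rng.random() < 0.5 else "-",
                        ),
                        family=params.planted_ltr_family,
                        repeat_class="LTR",
                    )
                )

    # background repeats avoid all promoters, so promoter repeat content is
    # governed solely by the embedding fractions above
    promoter_free = complement(
        adjust_boundaries(
            IntervalSet(planted_promoter_ivs + decoy_promoter_ivs),
            200, 200, clip_to=genome,
        ),
        genome,
    )
    for family, rclass, count in params.repeat_families:
        lengths = rng.integers(300, 1_500, size=count)
        for iv in _uniform_placements(rng, list(lengths), promoter_free):
            repeats.append(
                RepeatElement(
                    GenomicInterval(
                        iv.chrom, iv.start, iv.end,
                        "+" if rng.random() < 0.5 else "-",
                    ),
                    family=family,
                    repeat_class=rclass,
                )
            )

    # blacklist regions in leftover space
    bl = _uniform_placements(
        rng, [params.blacklist_length] * params.n_blacklist, eligible
    )
    blacklist = IntervalSet(bl)

    # --- expression model --------------------------------------------------
    for p in planted:
        base = params.base_expression * float(
            rng.lognormal(0.0, params.expression_sigma)
        )
        src_group = groups[p.source_sample]
        for line in lines:
            eps = float(rng.lognormal(0.0, params.expression_sigma))
            if line == p.source_sample:
                value = base * params.source_boost
            else:
                g = groups[line]
                nonltr_f, ltr_f = (
                    params.off_factor_primary
                    if g == "primary"
                    else params.off_factor_elevated
                )
                value = base * (ltr_f if p.ltr_driven else nonltr_f) * eps
            p.expression[line] = value

    return Simulation(
        params=params,
        genome=genome,
        genes=genes,
        promoters_by_line=promoters_by_line,
        repeats=repeats,
        blacklist=blacklist,
        truth=TruthSet(planted),
    )


# ---------------------------------------------------------------------------
# coverage emission
# ---------------------------------------------------------------------------

def _tile_region(
    rng: np.random.Generator,
    iv: GenomicInterval,
    length_range: Tuple[int, int],
    gap_range: Tuple[int, int],
    density: float,
) -> List[Contig]:
    """Dense contig tiling of ``iv`` with gaps inside ``gap_range``; the first
    contig starts at iv.start and the last ends at iv.end exactly."""
    out: List[Contig] = []
    pos = iv.start
    lo, hi = length_range
    glo, ghi = gap_range
    while True:
        L = int(rng.integers(lo, hi + 1))
        gap = int(rng.integers(glo, ghi + 1))
        if pos + L + gap + lo >= iv.end:
            L = iv.end - pos
            out.append(
                Contig(
                    GenomicInterval(iv.chrom, pos, iv.end, iv.strand),
                    max(1, round(density * L)),
                )
            )
            break
        out.append(
            Contig(
                GenomicInterval(iv.chrom, pos, pos + L, iv.strand),
                max(1, round(density * L)),
            )
        )
        pos += L + gap
    return out


def emit_contigs(sim: Simulation, params: SimParams | None = None) -> Dict[str, List[Contig]]:
    """Per-sample contig tracks.

    The source sample of each planted region gets a dense boundary-exact
    tiling (gaps well below the first merge threshold); other samples get
    sparse isolated contigs (spacing far above the second merge threshold) so
    cross-sample expression is quantifiable without creating callable
    regions. Background noise contigs are short and isolated.
    """
    params = params or sim.params
    rng = _rng(params.seed, _CONTIGS)
    lines = [name for name, _ in params.cell_lines]
    genome_mb = sim.genome.total_length / 1e6

    vlinc_margin = params.min_feature_gap // 2
    noise_eligible = complement(
        adjust_boundaries(
            IntervalSet(
                list(sim.genes)
                + [p.vlinc.interval for p in sim.truth.planted]
            ),
            vlinc_margin, vlinc_margin, clip_to=sim.genome,
        ),
        sim.genome,
    )

    out: Dict[str, List[Contig]] = {}
    for line in lines:
        contigs: List[Contig] = []
        for p in sim.truth.planted:
            expr = p.expression.get(line, 0.0)
            iv = p.vlinc.interval
            if line == p.source_sample:
                contigs.extend(
                    _tile_region(
                        rng, iv, params.contig_length_range,
                        params.contig_gap_range, expr,
                    )
                )
            elif params.cross_expression and expr > 0:
                pos = iv.start
                L = params.sparse_contig_length
                while pos + L <= iv.end:
                    contigs.append(
                        Contig(
                            GenomicInterval(iv.chrom, pos, pos + L, iv.strand),
                            max(1, round(expr * L)),
                        )
                    )
                    pos += params.sparse_spacing
        n_noise = int(rng.poisson(params.noise_contigs_per_mb * genome_mb))
        if n_noise:
            lo, hi = params.noise_contig_length_range
            lengths = rng.integers(lo, hi + 1, size=n_noise)
            for iv in _uniform_placements(rng, list(lengths), noise_eligible):
                strand = "+" if rng.random() < 0.5 else "-"
                contigs.append(
                    Contig(
                        GenomicInterval(iv.chrom, iv.start, iv.end, strand),
                        max(1, round(params.noise_contig_density * iv.length)),
                    )
                )
        out[line] = contigs
    return out


def emit_density(
    sim: Simulation, params: SimParams | None = None
) -> Tuple[Dict[str, DensityTrack], Dict[str, float]]:
    """Per-sample unstranded density tracks plus their expected integrals.

    Signal runs are the sample's own planted regions at their expression
    value. Background noise runs are sized so that the nearest-rank 80th
    percentile of nonzero per-base density lands exactly on the weakest
    planted signal value: noise (at half the weakest value) falls below the
    threshold by construction and every planted region survives it.
    """
    params = params or sim.params
    rng = _rng(params.seed, _DENSITY)
    lines = [name for name, _ in params.cell_lines]

    margin = 2_000 + params.min_feature_gap // 4
    eligible = complement(
        adjust_boundaries(
            IntervalSet(
                list(sim.genes)
                + [p.vlinc.interval for p in sim.truth.planted]
            ),
            margin, margin, clip_to=sim.genome,
        ),
        sim.genome,
    )

    tracks: Dict[str, DensityTrack] = {}
    totals: Dict[str, float] = {}
    for line in lines:
        own = sim.truth.for_sample(line)
        rows: List[Tuple[str, int, int, float]] = []
        signal_bases = 0
        min_val, min_bases = math.inf, 0
        for p in own:
            iv = p.vlinc.interval
            val = p.expression[line]
            rows.append((iv.chrom, iv.start, iv.end, val))
            signal_bases += iv.length
            if val < min_val:
                min_val, min_bases = val, iv.length
        expected = sum((r[2] - r[1]) * r[3] for r in rows)
        if params.density_noise and own:
            budget = max(0, int(round(4 * signal_bases - 2.5 * min_bases)))
            noise_val = 0.5 * min_val
            lo, hi = params.density_noise_run_range
            lengths: List[int] = []
            remaining = budget
            while remaining > 0:
                L = int(rng.integers(lo, hi + 1))
                if L >= remaining:
                    L = remaining
                lengths.append(L)
                remaining -= L
            placed = _pack_noise_runs(rng, lengths, eligible, spacing=2_000)
            for iv in placed:
                rows.append((iv.chrom, iv.start, iv.end, noise_val))
                expected += iv.length * noise_val
        tracks[line] = DensityTrack.from_intervals(rows)
        totals[line] = expected
    return tracks, totals


def _pack_noise_runs(
    rng: np.random.Generator,
    lengths: Sequence[int],
    eligible: IntervalSet,
    spacing: int,
) -> List[GenomicInterval]:
    """Non-overlapping noise-run placement: fill eligible slots left to right
    with randomized spacings >= ``spacing`` between consecutive runs."""
    slots: List[Tuple[str, int, int]] = []
    for chrom in eligible.chroms:
        s, e, _ = eligible._cover(chrom)
        slots.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
    rng.shuffle(slots)
    out: List[GenomicInterval] = []
    li = 0
    for chrom, a, b in slots:
        pos = a
        while li < len(lengths):
            L = int(lengths[li])
            jitter = int(rng.integers(0, spacing))
            start = pos + jitter
            if start + L + spacing > b:
                break
            out.append(GenomicInterval(chrom, start, start + L))
            pos = start + L + spacing
            li += 1
        if li == len(lengths):
            break
    if li < len(lengths):
        raise SimulationError(
            "cannot fit density noise runs into the eligible space; "
            "reduce planted signal or enlarge the genome"
        )
    return out


# ---------------------------------------------------------------------------
# expression-matrix simulation (group-skew recovery)
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    seed: int,
    n_vlincs: int = 500,
    ltr_fraction: float = 0.5,
    ltr_skew: float = 10.0,
    base_upregulation: float = 5.0,
    sigma: float = 0.5,
    dropout: float = 0.02,
    n_malignant: int = 3,
    n_immortalized: int = 1,
    n_esc: int = 1,
    n_primary: int = 7,
) -> Tuple[ExpressionMatrix, Dict[str, bool]]:
    """A vlincRNA x sample matrix with a known LTR-stratum fold-skew.

    Primary-cell values are log-normal around a common baseline; malignant,
    immortalized and embryonic-stem values carry a ``base_upregulation``
    factor, multiplied by ``ltr_skew`` for LTR-driven regions. The quotient
    (LTR-stratum mean ratio) / (non-LTR mean ratio) therefore estimates
    ``ltr_skew`` exactly, up to sampling noise and the small ``dropout`` of
    zeroed entries.
    """
    rng = _rng(seed, _MATRIX)
    samples: List[Tuple[str, str]] = (
        [(f"cancer{i+1}", "malignant") for i in range(n_malignant)]
        + [(f"immort{i+1}", "immortalized") for i in range(n_immortalized)]
        + [(f"esc{i+1}", "embryonic-stem") for i in range(n_esc)]
        + [(f"primary{i+1}", "primary") for i in range(n_primary)]
    )
    ltr_flags = {
        f"vlinc_{i+1}": bool(rng.random() < ltr_fraction) for i in range(n_vlincs)
    }
    data = {}
    base = 10.0
    for name, group in samples:
        col = np.empty(n_vlincs)
        for i, vid in enumerate(ltr_flags):
            mu = base
            if group != "primary":
                mu *= base_upregulation
                if ltr_flags[vid]:
                    mu *= ltr_skew
            col[i] = mu * rng.lognormal(0.0, sigma)
        drop = rng.random(n_vlincs) < dropout
        col[drop] = 0.0
        data[name] = col
    df = pd.DataFrame(data, index=list(ltr_flags))
    return ExpressionMatrix(df, dict(samples)), ltr_flags
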