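"""Promoter-state handling, repeat classification, and vlincRNA annotation.

Promoters are chromatin-state segments (Active / Weak / Poised) annotated per
cell line by an upstream segmentation model; "All" in reports means the union
of the three states. A vlincRNA is *associated* with a promoter when the
promoter overlaps a 10 kb window centred on the vlincRNA's 5' boundary
(both boundaries for unstranded vlincRNAs) — equivalently, when the boundary
point falls inside the promoter extended by 5 kb on each side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .caller import VlincRNA
from .intervals import (
    GenomicInterval,
    IntervalSet,
    overlap_flags,
    union_length,
)
from .tracks import DensityTrack

PROMOTER_STATES = ("Active", "Weak", "Poised")
REPEAT_CLASSES = ("LTR", "other retroposon", "other")

_LTR_PREFIXES = ("LTR", "HERV", "MER", "THE", "MLT", "MST", "Harlequin", "ERV")
_RETRO_PREFIXES = ("Alu", "L1", "L2", "SVA", "MIR", "FLAM", "FRAM")


def repeat_class_for_family(family: str) -> str:
    """Crude family-name heuristic used only when no class column is given."""
    for p in _LTR_PREFIXES:
        if family.startswith(p):
            return "LTR"
    for p in _RETRO_PREFIXES:
        if family.startswith(p):
            return "other retroposon"
    return "other"


@dataclass(frozen=True)
class Promoter:
    interval: GenomicInterval
    state: str
    cell_line: str
    ltr_overlap: bool = False
    repeat_overlap_class: str = "none"

    def __post_init__(self) -> None:
        if self.state not in PROMOTER_STATES:
            raise ValueError(f"unknown promoter state {self.state!r}")
        if self.ltr_overlap and self.repeat_overlap_class != "LTR":
            raise ValueError("ltr_overlap inconsistent with repeat_overlap_class")


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    family: str
    repeat_class: str  # "LTR" | "other retroposon" | "other"

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")


@dataclass(frozen=True)
class PromoterAssignment:
    vlinc_id: str
    promoter_indices: Tuple[int, ...]  # indices into the promoter list given
    categories: frozenset  # subset of {"Active", "Weak", "Poised", "All"}
    ltr_driven: bool


def promoters_to_interval_set(promoters: Sequence[Promoter]) -> IntervalSet:
    return IntervalSet(p.interval for p in promoters)


def classify_promoter_repeats(
    promoters: Sequence[Promoter], repeats: Sequence[RepeatElement]
) -> List[Promoter]:
    """Flag each promoter by the repeat content it overlaps (strand-blind).

    ``repeat_overlap_class`` uses the precedence LTR > other retroposon > none;
    ``ltr_overlap`` is true iff >= 1 base is shared with an LTR-class repeat.
    """
    ltr_set = IntervalSet(r.interval for r in repeats if r.repeat_class == "LTR")
    retro_set = IntervalSet(
        r.interval for r in repeats if r.repeat_class == "other retroposon"
    )
    ivs = [p.interval for p in promoters]
    hit_ltr = overlap_flags(ivs, ltr_set)
    hit_retro = overlap_flags(ivs, retro_set)
    out = []
    for p, hl, hr in zip(promoters, hit_ltr, hit_retro):
        if hl:
            cls = "LTR"
        elif hr:
            cls = "non-LTR retroposon"
        else:
            cls = "none"
        out.append(replace(p, ltr_overlap=bool(hl), repeat_overlap_class=cls))
    return out


def derive_cellline_specific_promoters(
    promoters_by_line: Mapping[str, Sequence[Promoter]], target: str
) -> List[Promoter]:
    """Active promoters of ``target`` sharing no base with *any* promoter
    (Active, Weak or Poised) of any other cell line."""
    if target not in promoters_by_line:
        raise KeyError(f"cell line {target!r} not present")
    others = IntervalSet(
        p.interval
        for line, ps in promoters_by_line.items()
        if line != target
        for p in ps
    )
    active = [p for p in promoters_by_line[target] if p.state == "Active"]
    hit = overlap_flags([p.interval for p in active], others)
    return [p for p, h in zip(active, hit) if not h]


def vlinc_boundary_windows(
    vlinc: VlincRNA, halfwidth: int = 5000
) -> List[GenomicInterval]:
    """The promoter-search window(s): one 2*halfwidth window centred on the
    5' boundary for stranded vlincRNAs, one per boundary for unstranded."""
    iv = vlinc.interval
    if iv.strand == ".":
        centers = [iv.start, iv.end]
    else:
        centers = [iv.five_prime()]
    return [
        GenomicInterval(iv.chrom, max(0, c - halfwidth), c + halfwidth)
        for c in centers
        if c + halfwidth > 0
    ]


def assign_promoters_to_vlincs(
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter],
    window_halfwidth: int = 5000,
) -> List[PromoterAssignment]:
    """Assign promoters to vlincRNAs via boundary windows.

    A promoter is assigned iff it shares >= 1 base with a window. Categories
    record the states hit, plus "All" when any promoter is assigned.
    ``ltr_driven`` is true iff >= 1 assigned promoter has ``ltr_overlap``.
    """
    pstarts: Dict[str, List[Tuple[int, int, int]]] = {}
    for idx, p in enumerate(promoters):
        pstarts.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end, idx)
        )
    per_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, rows in pstarts.items():
        rows.sort()
        s = np.array([r[0] for r in rows], dtype=np.int64)
        e = np.array([r[1] for r in rows], dtype=np.int64)
        i = np.array([r[2] for r in rows], dtype=np.int64)
        per_chrom[chrom] = (s, e, i)

    out = []
    for v in vlincs:
        hits: List[int] = []
        for w in vlinc_boundary_windows(v, window_halfwidth):
            if w.chrom not in per_chrom:
                continue
            s, e, idx = per_chrom[w.chrom]
            j = int(np.searchsorted(s, w.end, side="left"))
            sel = np.flatnonzero(e[:j] > w.start)
            hits.extend(int(idx[k]) for k in sel)
        hits = sorted(set(hits))
        cats = {promoters[i].state for i in hits}
        if cats:
            cats.add("All")
        out.append(
            PromoterAssignment(
                vlinc_id=v.vlinc_id,
                promoter_indices=tuple(hits),
                categories=frozenset(cats),
                ltr_driven=any(promoters[i].ltr_overlap for i in hits),
            )
        )
    return out


def classify_standalone(
    vlincs: Sequence[VlincRNA],
    genes: IntervalSet,
    min_distance: int = 50_000,
) -> np.ndarray:
    """Stand-alone: both vlincRNA boundaries are more than ``min_distance``
    from every gene boundary and the vlincRNA overlaps no gene (strand-blind).
    """
    bounds: Dict[str, np.ndarray] = {}
    for (chrom, _), (s, e) in genes.groups().items():
        pts = bounds.get(chrom)
        cur = np.concatenate([s, e])
        bounds[chrom] = np.concatenate([pts, cur]) if pts is not None else cur
    for chrom in bounds:
        bounds[chrom] = np.sort(bounds[chrom])

    hit = overlap_flags([v.interval for v in vlincs], genes)
    out = np.zeros(len(vlincs), dtype=bool)
    for i, v in enumerate(vlincs):
        if hit[i]:
            continue
        pts = bounds.get(v.interval.chrom)
        if pts is None or pts.size == 0:
            out[i] = True
            continue
        ok = True
        for b in (v.interval.start, v.interval.end):
            j = int(np.searchsorted(pts, b))
            nearest = min(
                abs(b - int(pts[j - 1])) if j > 0 else math.inf,
                abs(int(pts[j]) - b) if j < pts.size else math.inf,
            )
            if nearest <= min_distance:  # "more than" fails at equality
                ok = False
                break
        out[i] = ok
    return out


def classify_antisense_bidirectional(
    vlincs: Sequence[VlincRNA],
    genes: Sequence[GenomicInterval],
    divergent_window: int = 1000,
    standalone_distance: int = 50_000,
) -> List[str]:
    """Positional labels for stranded vlincRNAs.

    * ``antisense`` — shares >= 1 base with a gene on the opposite strand;
    * ``bidirectional`` — not antisense, and its 5' end lies within
      ``divergent_window`` of an opposite-strand gene's 5' end (head-to-head);
    * ``standalone-like`` — no gene overlap and > ``standalone_distance`` from
      every gene boundary;
    * ``other`` — everything else.

    Precedence: antisense > bidirectional > standalone-like > other.
    The divergent-window default is a package choice (1 kb); there is no
    community-standard cutoff for calling divergent transcription.
    """
    gene_set = IntervalSet(genes)
    five_by_key: Dict[Tuple[str, str], List[int]] = {}
    for g in genes:
        if g.strand == ".":
            continue
        five_by_key.setdefault((g.chrom, g.strand), []).append(g.five_prime())
    five_sorted = {
        k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in five_by_key.items()
    }
    standalone = classify_standalone(vlincs, gene_set, standalone_distance)

    labels = []
    for i, v in enumerate(vlincs):
        iv = v.interval
        if iv.strand == ".":
            raise ValueError("classification requires stranded vlincRNAs")
        opp = "-" if iv.strand == "+" else "+"
        # antisense: overlap with an opposite-strand (or unstranded) gene
        anti = False
        for g in genes:
            if g.chrom == iv.chrom and g.strand in (opp, ".") and iv.overlaps(g):
                anti = True
                break
        if anti:
            labels.append("antisense")
            continue
        pts = five_sorted.get((iv.chrom, opp))
        bidir = False
        if pts is not None and pts.size:
            b = iv.five_prime()
            j = int(np.searchsorted(pts, b))
            for k in (j - 1, j):
                if 0 <= k < pts.size and abs(int(pts[k]) - b) <= divergent_window:
                    bidir = True
                    break
        if bidir:
            labels.append("bidirectional")
        elif standalone[i]:
            labels.append("standalone-like")
        else:
            labels.append("other")
    return labels


def boundary_promoter_profile(
    vlincs: Sequence[VlincRNA],
    promoters: Sequence[Promoter] | IntervalSet,
    bin_size: int = 1000,
    halfwidth: int = 50_000,
) -> np.ndarray:
    """Promoter-covered bases summed in fixed bins around vlincRNA boundaries.

    The axis runs from -halfwidth (upstream, outside the vlincRNA) to
    +halfwidth (downstream, inside). Stranded vlincRNAs contribute their 5'
    boundary (minus-strand profiles are orientation-flipped); unstranded ones
    contribute both boundaries, the right boundary flipped so "upstream"
    always points away from the region.
    """
    if (2 * halfwidth) % bin_size != 0:
        raise ValueError("bin_size must divide 2 * halfwidth")
    if isinstance(promoters, IntervalSet):
        pset = promoters
    else:
        pset = IntervalSet(p.interval for p in promoters)
    nbins = (2 * halfwidth) // bin_size
    profile = np.zeros(nbins, dtype=np.int64)
    for v in vlincs:
        iv = v.interval
        if iv.strand == "-":
            anchors = [(iv.end, -1)]
        elif iv.strand == "+":
            anchors = [(iv.start, +1)]
        else:
            anchors = [(iv.start, +1), (iv.end, -1)]
        for b, orient in anchors:
            for j in range(nbins):
                off_lo = -halfwidth + j * bin_size
                off_hi = off_lo + bin_size
                if orient == 1:
                    lo, hi = b + off_lo, b + off_hi
                else:
                    lo, hi = b - off_hi, b - off_lo
                if hi <= 0:
                    continue
                profile[j] += pset.covered_length_in(iv.chrom, max(lo, 0), hi)
    return profile


def flag_low_alignability_boundary(
    vlincs: Sequence[VlincRNA],
    alignability: DensityTrack,
    upstream_span: int = 5000,
    threshold: float = 0.5,
) -> np.ndarray:
    """True where mean alignability in the ``upstream_span`` upstream of the 5'
    end falls below ``threshold`` (uncovered positions count as 0).

    Unstranded vlincRNAs are checked at both ends and flagged if either
    qualifies. Windows truncated by a chromosome start are evaluated over the
    available span; an entirely unavailable window never flags.
    """
    out = np.zeros(len(vlincs), dtype=bool)
    for i, v in enumerate(vlincs):
        iv = v.interval
        windows = []
        if iv.strand in ("+", "."):
            windows.append((max(0, iv.start - upstream_span), iv.start))
        if iv.strand in ("-", "."):
            windows.append((iv.end, iv.end + upstream_span))
        for lo, hi in windows:
            if hi <= lo:
                continue
            if alignability.mean_over(iv.chrom, lo, hi) < threshold:
                out[i] = True
                break
    return out
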