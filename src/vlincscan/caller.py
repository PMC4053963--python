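"""Calling vlincRNA regions from RNA-seq coverage.

Two callers are provided, matching the two kinds of input the analysis uses:

* :func:`call_from_contigs` — strand-specific. Input is a set of coverage
  "contigs" (blocks of overlapping mapped reads). Contigs overlapping
  annotated genes on the *same* strand are removed, survivors are merged
  across gaps of at most ``merge_gap_1`` (default 1 kb), merged blocks shorter
  than ``min_length`` (default 50 kb) are discarded, and the remaining regions
  are merged again across gaps of at most ``merge_gap_2`` (default 5 kb).

* :func:`call_from_density` — non-strand-specific. Input is a per-base read
  density track. Positions inside annotated genes (either strand) are zeroed,
  a density threshold equal to the 80th percentile of the remaining nonzero
  per-base densities is applied, kept positions are merged across gaps of at
  most ``density_merge_gap`` (500 bp "blood mode" / 1000 bp "mouse mode"),
  and regions of at least ``min_length`` are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Sequence

from .intervals import (
    GenomicInterval,
    IntervalSet,
    merge_within_gap,
    overlap_flags,
)
from .tracks import DensityTrack


@dataclass(frozen=True)
class Contig:
    """A coverage block with the total bases covered by reads inside it."""

    interval: GenomicInterval
    base_count: int = 0

    def __post_init__(self) -> None:
        if self.base_count < 0:
            raise ValueError("base_count must be >= 0")


@dataclass(frozen=True)
class CallerParams:
    merge_gap_1: int = 1000
    min_length: int = 50_000
    merge_gap_2: int = 5000
    density_percentile: float = 0.80
    density_merge_gap: int = 500

    def __post_init__(self) -> None:
        if min(self.merge_gap_1, self.merge_gap_2, self.density_merge_gap) < 0:
            raise ValueError("merge gaps must be >= 0")
        if self.min_length <= 0:
            raise ValueError("min_length must be > 0")
        if not (0 < self.density_percentile < 1):
            raise ValueError("density_percentile must be in (0, 1)")

    @classmethod
    def blood_mode(cls, **kw) -> "CallerParams":
        return cls(density_merge_gap=500, **kw)

    @classmethod
    def mouse_mode(cls, **kw) -> "CallerParams":
        return cls(density_merge_gap=1000, **kw)


@dataclass(frozen=True)
class VlincRNA:
    """A called vlincRNA region.

    ``interval.strand`` is "+"/"-" for contig-called regions and "." for
    density-called ones. ``source_sample`` records which dataset it came from.
    """

    interval: GenomicInterval
    source_sample: str = "sample"
    vlinc_id: str = ""

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand


def _label(regions: Iterable[GenomicInterval], sample: str) -> List[VlincRNA]:
    out = []
    for i, iv in enumerate(regions, start=1):
        out.append(VlincRNA(iv, source_sample=sample, vlinc_id=f"{sample}_vlinc_{i}"))
    return out


def call_from_contigs(
    contigs: Sequence[Contig],
    genes: IntervalSet,
    params: CallerParams = CallerParams(),
    sample: str = "sample",
) -> List[VlincRNA]:
    """Strand-specific caller (see module docstring for the four stages).

    Gene filtering treats the full gene-body span (transcription start to end)
    as excluded territory on the gene's strand; opposite-strand genes do not
    remove contigs. Unstranded contigs are rejected.
    """
    for c in contigs:
        if c.interval.strand == ".":
            raise ValueError("contig caller requires stranded contigs")
    ivs = [c.interval for c in contigs]
    hit = overlap_flags(ivs, genes, strand_specific=True)
    kept = IntervalSet(iv for iv, h in zip(ivs, hit) if not h)
    merged = merge_within_gap(kept, params.merge_gap_1)
    long_enough = IntervalSet(
        iv for iv in merged if iv.length >= params.min_length
    )
    final = merge_within_gap(long_enough, params.merge_gap_2)
    return _label(final, sample)


def density_threshold(track: DensityTrack, percentile: float) -> float:
    """The nearest-rank ``percentile`` of per-base density over positions with
    density > 0. Raises on an all-zero track ("no expressed positions")."""
    return track.percentile_nonzero(percentile)


def call_from_density(
    track: DensityTrack,
    genes: IntervalSet,
    params: CallerParams = CallerParams(),
    sample: str = "sample",
) -> List[VlincRNA]:
    """Non-strand-specific caller. Gene positions (either strand) are removed
    *before* the percentile threshold is computed."""
    cleaned = track.zero_out(genes)
    thr = density_threshold(cleaned, params.density_percentile)
    kept = cleaned.threshold_runs(thr)
    merged = merge_within_gap(kept, params.density_merge_gap)
    final = [iv for iv in merged if iv.length >= params.min_length]
    return _label(final, sample)


def vlincs_to_interval_set(vlincs: Sequence[VlincRNA]) -> IntervalSet:
    return IntervalSet(v.interval for v in vlincs)


def vlincs_to_contigs(vlincs: Sequence[VlincRNA]) -> List[Contig]:
    """Convert called regions back to contigs (for fixed-point checks)."""
    return [Contig(v.interval, v.length) for v in vlincs]
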