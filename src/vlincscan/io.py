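"""Readers and writers for the plain-text genomics formats used throughout.

All files are tab-separated. Coordinates are written 0-based half-open (BED
convention); readers accept a ``one_based`` flag for browser-style 1-based
inclusive inputs and convert on ingest. Lines starting with ``#``, ``track``
or ``browser`` are skipped. Writers emit rows in the input order given, so
output is bit-stable for a fixed input ordering.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .intervals import Genome, GenomicInterval, IntervalSet
from .tracks import DensityTrack


def _data_lines(path: str | os.PathLike) -> Iterable[List[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield line.split("\t")


def read_chrom_sizes(path: str | os.PathLike) -> Genome:
    """Two-column TSV: chromosome name, length."""
    lengths: Dict[str, int] = {}
    for fields in _data_lines(path):
        lengths[fields[0]] = int(fields[1])
    return Genome(lengths)


def write_chrom_sizes(genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def _convert(start: int, end: int, one_based: bool) -> Tuple[int, int]:
    return (start - 1, end) if one_based else (start, end)


def read_bed(
    path: str | os.PathLike, one_based: bool = False
) -> List[GenomicInterval]:
    """BED3/BED6(+): returns intervals (strand from column 6 when present)."""
    out: List[GenomicInterval] = []
    for fields in _data_lines(path):
        start, end = _convert(int(fields[1]), int(fields[2]), one_based)
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def read_bed_records(
    path: str | os.PathLike, one_based: bool = False
) -> List[Tuple[GenomicInterval, str, List[str]]]:
    """BED with a name column: (interval, name, all fields) per row."""
    out = []
    for fields in _data_lines(path):
        start, end = _convert(int(fields[1]), int(fields[2]), one_based)
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        name = fields[3] if len(fields) >= 4 else "."
        out.append((GenomicInterval(fields[0], start, end, strand), name, fields))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
    header: str | None = None,
) -> None:
    """BED6 writer (name/score default to "." and 0)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_contig_bed(path: str | os.PathLike, one_based: bool = False):
    """ENCODE/CSHL contig dialect: BED with >= 9 columns, column 9 carrying the
    total bases covered by reads in the contig; strand from column 6.

    Returns a list of :class:`vlincscan.caller.Contig`.
    """
    from .caller import Contig  # local import to avoid a cycle

    out = []
    for fields in _data_lines(path):
        if len(fields) < 9:
            raise ValueError(
                f"contig BED needs >= 9 columns, got {len(fields)} in {path}"
            )
        start, end = _convert(int(fields[1]), int(fields[2]), one_based)
        strand = fields[5] if fields[5] in "+-" else "."
        out.append(
            Contig(GenomicInterval(fields[0], start, end, strand), int(float(fields[8])))
        )
    return out


def write_contig_bed(contigs, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcontig\t0\t{iv.strand}"
                f"\t{iv.start}\t{iv.end}\t{c.base_count}\n"
            )


def read_bedgraph(path: str | os.PathLike) -> DensityTrack:
    """Four-column BedGraph -> DensityTrack (runs must not overlap)."""
    rows = []
    for fields in _data_lines(path):
        rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return DensityTrack.from_intervals(rows)


def write_bedgraph(track: DensityTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_promoter_bed(
    path: str | os.PathLike, cell_line: str, one_based: bool = False
):
    """Promoter BED dialect: name column = chromatin state label
    (Active/Weak/Poised), one file per cell line.

    Returns a list of :class:`vlincscan.annotation.Promoter`.
    """
    from .annotation import PROMOTER_STATES, Promoter

    out = []
    for iv, name, _ in read_bed_records(path, one_based=one_based):
        if name not in PROMOTER_STATES:
            raise ValueError(f"unknown promoter state {name!r} in {path}")
        out.append(Promoter(interval=iv, state=name, cell_line=cell_line))
    return out


def write_promoter_bed(promoters, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.state}\t0\t{iv.strand}\n")


def read_repeat_bed(path: str | os.PathLike, one_based: bool = False):
    """Repeat BED6(+): family in the name column, repeat class in column 7
    when present (one of LTR / "other retroposon" / other; defaults by family
    prefix heuristics otherwise).
    """
    from .annotation import RepeatElement, repeat_class_for_family

    out = []
    for iv, name, fields in read_bed_records(path, one_based=one_based):
        rclass = fields[6] if len(fields) >= 7 else repeat_class_for_family(name)
        out.append(RepeatElement(interval=iv, family=name, repeat_class=rclass))
    return out


def write_repeat_bed(repeats, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.family}\t0\t{iv.strand}"
                f"\t{r.repeat_class}\n"
            )


def read_snp_positions(path: str | os.PathLike) -> IntervalSet:
    """SNPs as BED3 or a two-column chrom/pos TSV (pos 1-based -> 1-base
    half-open interval)."""
    ivs = []
    for fields in _data_lines(path):
        if len(fields) >= 3:
            ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        else:
            pos = int(fields[1]) - 1
            ivs.append(GenomicInterval(fields[0], pos, pos + 1))
    return IntervalSet(ivs)
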