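"""Strand-aware genomic interval algebra.

All coordinates are 0-based half-open (BED convention). Intervals carry an
optional strand in ``{"+", "-", "."}``; ``"."`` (unstranded) matches both
strands in strand-specific comparisons. Adjacent (touching) intervals do not
overlap, but ``merge_within_gap`` with ``max_gap=0`` still merges touching
intervals (their gap is 0).

The :class:`IntervalSet` container groups intervals by ``(chrom, strand)`` and
keeps them sorted; most operations are vectorised over numpy arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


def _flip_strand(strand: str) -> str:
    return {"+": "-", "-": "+", ".": "."}[strand]


def _strands_match(a: str, b: str) -> bool:
    """Strand compatibility for strand-specific comparisons.

    Unstranded (".") matches both strands.
    """
    return a == "." or b == "." or a == b


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """The 5' boundary coordinate (start for +/unstranded, end for -)."""
        return self.end if self.strand == "-" else self.start

    def three_prime(self) -> int:
        return self.start if self.strand == "-" else self.end

    def overlaps(self, other: "GenomicInterval", strand_specific: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if strand_specific and not _strands_match(self.strand, other.strand):
            return False
        return self.start < other.end and other.start < self.end


class Genome:
    """Chromosome name -> length map."""

    def __init__(self, chrom_lengths: Mapping[str, int]):
        if len(set(chrom_lengths)) != len(chrom_lengths):
            raise ValueError("duplicate chromosome names")
        for name, length in chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.chrom_lengths)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.chrom_lengths == other.chrom_lengths

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def as_interval_set(self) -> "IntervalSet":
        return IntervalSet(
            GenomicInterval(c, 0, n) for c, n in self.chrom_lengths.items()
        )


Key = Tuple[str, str]  # (chrom, strand)


class IntervalSet:
    """An ordered collection of intervals grouped by ``(chrom, strand)``.

    Construction sorts each group by ``(start, end)``. The set is *not*
    automatically flattened; use :meth:`flatten` / :func:`merge_within_gap`.
    """

    __slots__ = ("_groups", "_cover_cache")

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        groups: Dict[Key, Tuple[List[int], List[int]]] = {}
        for iv in intervals:
            starts, ends = groups.setdefault((iv.chrom, iv.strand), ([], []))
            starts.append(iv.start)
            ends.append(iv.end)
        self._groups: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
        for key, (starts, ends) in groups.items():
            s = np.asarray(starts, dtype=np.int64)
            e = np.asarray(ends, dtype=np.int64)
            order = np.lexsort((e, s))
            self._groups[key] = (s[order], e[order])
        self._cover_cache: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        strand: str = ".",
    ) -> "IntervalSet":
        obj = cls()
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        if s.size:
            if np.any(s >= e) or np.any(s < 0):
                raise ValueError("invalid intervals in arrays")
            order = np.lexsort((e, s))
            obj._groups[(chrom, strand)] = (s[order], e[order])
        return obj

    @classmethod
    def _from_groups(
        cls, groups: Dict[Key, Tuple[np.ndarray, np.ndarray]]
    ) -> "IntervalSet":
        obj = cls()
        obj._groups = {k: v for k, v in groups.items() if v[0].size}
        return obj

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return sum(s.size for s, _ in self._groups.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        rows = []
        for (chrom, strand), (s, e) in self._groups.items():
            for i in range(s.size):
                rows.append((chrom, int(s[i]), int(e[i]), strand))
        rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
        for chrom, start, end, strand in rows:
            yield GenomicInterval(chrom, start, end, strand)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._groups) != set(other._groups):
            return False
        return all(
            np.array_equal(self._groups[k][0], other._groups[k][0])
            and np.array_equal(self._groups[k][1], other._groups[k][1])
            for k in self._groups
        )

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, keys={sorted(self._groups)})"

    @property
    def chroms(self) -> List[str]:
        return sorted({c for c, _ in self._groups})

    def groups(self) -> Dict[Key, Tuple[np.ndarray, np.ndarray]]:
        return self._groups

    def restrict_strand(self, strand: str) -> "IntervalSet":
        """Intervals whose strand matches ``strand`` ("." matches both)."""
        return IntervalSet._from_groups(
            {k: v for k, v in self._groups.items() if _strands_match(k[1], strand)}
        )

    def with_strand(self, strand: str) -> "IntervalSet":
        """Same coordinates, all assigned ``strand`` (groups are re-merged)."""
        out: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, _), (s, e) in self._groups.items():
            if (chrom, strand) in out:
                s = np.concatenate([out[(chrom, strand)][0], s])
                e = np.concatenate([out[(chrom, strand)][1], e])
            order = np.lexsort((e, s))
            out[(chrom, strand)] = (s[order], e[order])
        return IntervalSet._from_groups(out)

    def mirror(self, genome: Genome) -> "IntervalSet":
        """Reflect every coordinate x -> L - x and swap strands."""
        out: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), (s, e) in self._groups.items():
            L = genome[chrom]
            ns, ne = L - e, L - s
            order = np.lexsort((ne, ns))
            out[(chrom, _flip_strand(strand))] = (ns[order], ne[order])
        return IntervalSet._from_groups(out)

    # -- per-chromosome strand-collapsed flattened cover ------------------
    def _cover(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (strand-collapsed) cover of ``chrom`` with a prefix-sum.

        Returns ``(starts, ends, cumlen)`` where ``cumlen[i]`` is the number of
        covered bases strictly before interval ``i``.
        """
        if chrom not in self._cover_cache:
            ss = [s for (c, _), (s, _e) in self._groups.items() if c == chrom]
            ee = [e for (c, _), (_s, e) in self._groups.items() if c == chrom]
            if not ss:
                empty = np.empty(0, dtype=np.int64)
                self._cover_cache[chrom] = (empty, empty, empty)
            else:
                s = np.concatenate(ss)
                e = np.concatenate(ee)
                s, e = _merge_arrays(s, e, gap=0)
                cum = np.concatenate([[0], np.cumsum(e - s)[:-1]])
                self._cover_cache[chrom] = (s, e, cum)
        return self._cover_cache[chrom]

    def covered_length_in(self, chrom: str, start: int, end: int) -> int:
        """Number of covered bases (strand-blind) within ``[start, end)``."""
        if end <= start:
            return 0
        s, e, cum = self._cover(chrom)
        if not s.size:
            return 0
        return int(_covered_before(s, e, cum, end) - _covered_before(s, e, cum, start))

    def point_covered(self, chrom: str, pos: int, strand: str = ".") -> bool:
        """Whether base ``pos`` is covered by an interval matching ``strand``."""
        for (c, st), (s, e) in self._groups.items():
            if c != chrom or not _strands_match(st, strand):
                continue
            i = np.searchsorted(s, pos, side="right")
            if i > 0 and np.any(e[:i][s[:i] <= pos] > pos):
                return True
        return False

    def flatten(self) -> "IntervalSet":
        """Union per (chrom, strand) group: no overlaps remain within a key."""
        return merge_within_gap(self, 0)

    def collapse_strands(self) -> "IntervalSet":
        """Strand-blind union: one unstranded flattened set."""
        out: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.chroms:
            s, e, _ = self._cover(chrom)
            out[(chrom, ".")] = (s.copy(), e.copy())
        return IntervalSet._from_groups(out)


# ---------------------------------------------------------------------------
# array kernels
# ---------------------------------------------------------------------------

def _merge_arrays(
    starts: np.ndarray, ends: np.ndarray, gap: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals where ``next.start - prev.end <= gap``."""
    if starts.size == 0:
        return starts, ends
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    run_max = np.maximum.accumulate(e)
    # break where the next interval starts more than `gap` after the running end
    brk = np.flatnonzero(s[1:] - run_max[:-1] > gap) + 1
    idx = np.concatenate([[0], brk])
    out_s = s[idx]
    out_e = np.concatenate([run_max[brk - 1], [run_max[-1]]]) if brk.size else run_max[-1:]
    return out_s, out_e


def _covered_before(
    starts: np.ndarray, ends: np.ndarray, cum: np.ndarray, x: int
) -> int:
    """Covered bases strictly before coordinate ``x`` (flattened arrays)."""
    i = int(np.searchsorted(starts, x, side="right"))
    if i == 0:
        return 0
    partial = min(int(ends[i - 1]), x) - int(starts[i - 1])
    return int(cum[i - 1]) + max(partial, 0)


def _subtract_arrays(
    a_s: np.ndarray, a_e: np.ndarray, b_s: np.ndarray, b_e: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """a minus b; both flattened & sorted; returns flattened arrays."""
    if a_s.size == 0 or b_s.size == 0:
        return a_s, a_e
    out_s: List[int] = []
    out_e: List[int] = []
    j0 = np.searchsorted(b_e, a_s, side="right")
    for i in range(a_s.size):
        cur = int(a_s[i])
        end = int(a_e[i])
        j = int(j0[i])
        while j < b_s.size and b_s[j] < end:
            if b_s[j] > cur:
                out_s.append(cur)
                out_e.append(int(b_s[j]))
            cur = max(cur, int(b_e[j]))
            if cur >= end:
                break
            j += 1
        if cur < end:
            out_s.append(cur)
            out_e.append(end)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _intersect_arrays(
    a_s: np.ndarray, a_e: np.ndarray, b_s: np.ndarray, b_e: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Intersection of two flattened sorted interval arrays."""
    out_s: List[int] = []
    out_e: List[int] = []
    i = j = 0
    while i < a_s.size and j < b_s.size:
        lo = max(int(a_s[i]), int(b_s[j]))
        hi = min(int(a_e[i]), int(b_e[j]))
        if lo < hi:
            out_s.append(lo)
            out_e.append(hi)
        if a_e[i] < b_e[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def merge_within_gap(iset: IntervalSet, max_gap: int) -> IntervalSet:
    """Merge intervals on the same (chrom, strand) separated by <= max_gap bp.

    With half-open coordinates the gap between ``[a,b)`` and ``[c,d)`` (c >= b)
    is ``c - b``; touching intervals (gap 0) merge at ``max_gap=0``. Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = {
        key: _merge_arrays(s, e, max_gap) for key, (s, e) in iset.groups().items()
    }
    return IntervalSet._from_groups(out)


def union_length(iset: IntervalSet) -> int:
    """Number of distinct (chrom, base) positions covered, strand-blind."""
    total = 0
    for chrom in iset.chroms:
        s, e, _ = iset._cover(chrom)
        total += int(np.sum(e - s))
    return total


def subtract(
    a: IntervalSet, b: IntervalSet, strand_specific: bool = False
) -> IntervalSet:
    """Bases of ``a`` not covered by ``b``; result flattened per (chrom, strand).

    When ``strand_specific``, only ``b`` intervals on a matching strand
    ("." matches both) remove coverage.
    """
    out: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), (s, e) in a.groups().items():
        s, e = _merge_arrays(s, e, gap=0)
        if strand_specific:
            bs = [
                v
                for (bc, bstrand), v in b.groups().items()
                if bc == chrom and _strands_match(bstrand, strand)
            ]
            if bs:
                b_s = np.concatenate([v[0] for v in bs])
                b_e = np.concatenate([v[1] for v in bs])
                b_s, b_e = _merge_arrays(b_s, b_e, gap=0)
            else:
                b_s = b_e = np.empty(0, dtype=np.int64)
        else:
            b_s, b_e, _ = b._cover(chrom)
        rs, re = _subtract_arrays(s, e, b_s, b_e)
        if rs.size:
            out[(chrom, strand)] = (rs, re)
    return IntervalSet._from_groups(out)


def intersect(
    a: IntervalSet, b: IntervalSet, strand_specific: bool = False
) -> IntervalSet:
    """Bases covered by both sets; strand semantics as :func:`subtract`.

    The result inherits the strand of the ``a`` group it came from.
    """
    out: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), (s, e) in a.groups().items():
        s, e = _merge_arrays(s, e, gap=0)
        if strand_specific:
            bs = [
                v
                for (bc, bstrand), v in b.groups().items()
                if bc == chrom and _strands_match(bstrand, strand)
            ]
            if not bs:
                continue
            b_s = np.concatenate([v[0] for v in bs])
            b_e = np.concatenate([v[1] for v in bs])
            b_s, b_e = _merge_arrays(b_s, b_e, gap=0)
        else:
            b_s, b_e, _ = b._cover(chrom)
        rs, re = _intersect_arrays(s, e, b_s, b_e)
        if rs.size:
            key = (chrom, strand)
            if key in out:
                rs = np.concatenate([out[key][0], rs])
                re = np.concatenate([out[key][1], re])
                order = np.lexsort((re, rs))
                rs, re = rs[order], re[order]
            out[key] = (rs, re)
    return IntervalSet._from_groups(out)


def adjust_boundaries(
    iset: IntervalSet,
    left_delta: int,
    right_delta: int,
    clip_to: Genome | None = None,
) -> IntervalSet:
    """Turn each ``[s, e)`` into ``[s - left_delta, e + right_delta)``.

    Positive deltas extend, negative shrink. Results are clipped to
    ``[0, chrom_length)`` when a genome is given (and to 0 otherwise); intervals
    that collapse (start >= end) are silently dropped, logging a count.
    No flattening is performed.
    """
    out: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
    dropped = 0
    for (chrom, strand), (s, e) in iset.groups().items():
        ns = s - left_delta
        ne = e + right_delta
        ns = np.maximum(ns, 0)
        if clip_to is not None:
            L = clip_to[chrom]
            ne = np.minimum(ne, L)
            ns = np.minimum(ns, L)
        keep = ns < ne
        dropped += int((~keep).sum())
        if keep.any():
            ns, ne = ns[keep], ne[keep]
            order = np.lexsort((ne, ns))
            out[(chrom, strand)] = (ns[order], ne[order])
    if dropped:
        log.debug("adjust_boundaries dropped %d collapsed intervals", dropped)
    return IntervalSet._from_groups(out)


def overlap_flags(
    query: Sequence[GenomicInterval] | IntervalSet,
    subject: IntervalSet,
    strand_specific: bool = False,
) -> np.ndarray:
    """Per-query booleans: does the query share >= 1 base with any subject?

    Queries may be given as a sequence (flags follow that order) or an
    IntervalSet (flags follow its sorted iteration order).
    """
    qlist = list(query)
    flags = np.zeros(len(qlist), dtype=bool)
    # precompute flattened subject covers per strand requirement
    for i, q in enumerate(qlist):
        if strand_specific:
            for (c, st), (s, e) in subject.groups().items():
                if c != q.chrom or not _strands_match(st, q.strand):
                    continue
                j = np.searchsorted(s, q.end, side="left")
                if np.any(e[:j] > q.start):
                    flags[i] = True
                    break
        else:
            s, e, _ = subject._cover(q.chrom)
            j = np.searchsorted(s, q.end, side="left")
            flags[i] = bool(j > 0 and np.any(e[:j] > q.start))
    return flags


def overlap_count(
    query: Sequence[GenomicInterval] | IntervalSet,
    subject: IntervalSet,
    strand_specific: bool = False,
) -> Tuple[int, np.ndarray]:
    """Count of queries overlapping the subject, plus the per-query flags."""
    flags = overlap_flags(query, subject, strand_specific=strand_specific)
    return int(flags.sum()), flags


def complement(iset: IntervalSet, genome: Genome) -> IntervalSet:
    """Unstranded complement of the strand-collapsed cover within the genome."""
    return subtract(genome.as_interval_set(), iset)


def interior_gaps(iset: IntervalSet, genome: Genome, max_length: int | None = None) -> IntervalSet:
    """Uncovered intervals strictly *between* covered intervals on a chromosome.

    Chromosome-end flanks are excluded. When ``max_length`` is given only gaps
    shorter than it are returned.
    """
    out: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in iset.chroms:
        s, e, _ = iset._cover(chrom)
        if s.size < 2:
            continue
        gs, ge = e[:-1], s[1:]
        keep = gs < ge
        if max_length is not None:
            keep &= (ge - gs) < max_length
        if keep.any():
            out[(chrom, ".")] = (gs[keep].copy(), ge[keep].copy())
    return IntervalSet._from_groups(out)
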