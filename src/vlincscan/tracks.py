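"""Sparse per-base density tracks (BedGraph-style run-length coverage).

A :class:`DensityTrack` stores, per chromosome, non-overlapping sorted runs
``[start, end)`` each carrying one density value (reads or signal per base).
Positions outside every run have density 0. Used for the non-strand-specific
vlincRNA caller, alignability profiles, and intron/exon density ratios.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

from .intervals import IntervalSet


class DensityTrack:
    __slots__ = ("_runs",)

    def __init__(
        self,
        runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    ):
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, v) in runs.items():
                self._set_chrom(chrom, s, e, v)

    def _set_chrom(self, chrom: str, s, e, v) -> None:
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)
        v = np.asarray(v, dtype=np.float64)
        if not (s.size == e.size == v.size):
            raise ValueError("run arrays must have equal length")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(s >= e):
            raise ValueError("runs must have start < end")
        if np.any(v < 0):
            raise ValueError("densities must be >= 0")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"overlapping runs on {chrom}")
        keep = v > 0  # zero-valued runs are equivalent to gaps
        if keep.any():
            self._runs[chrom] = (s[keep], e[keep], v[keep])

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[Tuple[str, int, int, float]]
    ) -> "DensityTrack":
        """Build from (chrom, start, end, value) tuples (non-overlapping)."""
        per: Dict[str, Tuple[List[int], List[int], List[float]]] = {}
        for chrom, start, end, value in intervals:
            s, e, v = per.setdefault(chrom, ([], [], []))
            s.append(start)
            e.append(end)
            v.append(value)
        return cls({c: (np.array(s), np.array(e), np.array(v)) for c, (s, e, v) in per.items()})

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom in self._runs:
            return self._runs[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0, dtype=np.float64)

    def iter_runs(self):
        for chrom in self.chroms:
            s, e, v = self._runs[chrom]
            for i in range(s.size):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def nonzero_bases(self) -> int:
        return sum(int(np.sum(e - s)) for s, e, _ in self._runs.values())

    def total_signal(self) -> float:
        """Integral of density over the genome (sum of value x run length)."""
        return float(
            sum(np.sum((e - s) * v) for s, e, v in self._runs.values())
        )

    def zero_out(self, regions: IntervalSet) -> "DensityTrack":
        """Set density to 0 inside ``regions`` (any strand)."""
        out: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in self._runs.items():
            rs, re, _ = regions._cover(chrom)
            if not rs.size:
                out[chrom] = (s.copy(), e.copy(), v.copy())
                continue
            ns: List[int] = []
            ne: List[int] = []
            nv: List[float] = []
            j0 = np.searchsorted(re, s, side="right")
            for i in range(s.size):
                cur, end, val = int(s[i]), int(e[i]), float(v[i])
                j = int(j0[i])
                while j < rs.size and rs[j] < end:
                    if rs[j] > cur:
                        ns.append(cur)
                        ne.append(int(rs[j]))
                        nv.append(val)
                    cur = max(cur, int(re[j]))
                    if cur >= end:
                        break
                    j += 1
                if cur < end:
                    ns.append(cur)
                    ne.append(end)
                    nv.append(val)
            if ns:
                out[chrom] = (
                    np.asarray(ns, dtype=np.int64),
                    np.asarray(ne, dtype=np.int64),
                    np.asarray(nv, dtype=np.float64),
                )
        track = DensityTrack()
        track._runs = out
        return track

    def percentile_nonzero(self, fraction: float) -> float:
        """Nearest-rank percentile of per-base density over positions with
        density > 0.

        With n nonzero bases, returns the ``ceil(fraction * n)``-th smallest
        per-base value (each base weighted by 1).
        """
        if not (0 < fraction < 1):
            raise ValueError("fraction must be in (0, 1)")
        vals: List[np.ndarray] = []
        wts: List[np.ndarray] = []
        for s, e, v in self._runs.values():
            vals.append(v)
            wts.append(e - s)
        if not vals:
            raise ValueError("no expressed positions")
        v = np.concatenate(vals)
        w = np.concatenate(wts).astype(np.int64)
        n = int(w.sum())
        if n == 0:
            raise ValueError("no expressed positions")
        order = np.argsort(v, kind="stable")
        v, w = v[order], w[order]
        rank = int(np.ceil(fraction * n))
        cum = np.cumsum(w)
        idx = int(np.searchsorted(cum, rank, side="left"))
        return float(v[idx])

    def threshold_runs(self, min_value: float) -> IntervalSet:
        """Positions with density >= ``min_value`` as an unstranded set."""
        out = IntervalSet()
        groups = {}
        for chrom, (s, e, v) in self._runs.items():
            keep = v >= min_value
            if keep.any():
                groups[(chrom, ".")] = (s[keep].copy(), e[keep].copy())
        return IntervalSet._from_groups(groups)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean density over ``[start, end)``; uncovered
        positions count as 0. Returns nan for an empty window."""
        if end <= start:
            return float("nan")
        s, e, v = self.runs(chrom)
        if not s.size:
            return 0.0
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        total = 0.0
        for i in range(lo, hi):
            ov = min(int(e[i]), end) - max(int(s[i]), start)
            if ov > 0:
                total += ov * float(v[i])
        return total / (end - start)

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Integrated density over ``[start, end)``."""
        if end <= start:
            return 0.0
        return self.mean_over(chrom, start, end) * (end - start)
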