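"""Quantification of vlincRNA expression and specificity summaries.

Raw per-region counts are the summed base counts of coverage contigs
overlapping the region (strand-specifically when both carry strand). Values
are normalised to a sequencing depth of 2e10 bases ("20G bases") and a region
length of 1e6 bases ("1 Mbp"), making them dimensionless densities comparable
across samples and regions. Contigs with base counts above 1e6 are dropped as
likely artifacts (snRNA/rRNA repeats). Zero values are replaced by the
minimal nonzero value in the dataset before any ratio is formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .caller import Contig, VlincRNA
from .intervals import GenomicInterval, _strands_match
from .tracks import DensityTrack

GROUPS = ("malignant", "immortalized", "primary", "embryonic-stem", "other")


@dataclass(frozen=True)
class QuantParams:
    depth_norm_target: float = 2e10  # "20G bases"
    length_norm_target: float = 1e6  # "1 Mbp of vlincRNA length"
    max_contig_count: int = 1_000_000  # contigs with counts > 1M are removed
    proportional_attribution: bool = False  # default: whole base_count per hit

    def __post_init__(self) -> None:
        if min(self.depth_norm_target, self.length_norm_target) <= 0:
            raise ValueError("normalisation targets must be positive")
        if self.max_contig_count <= 0:
            raise ValueError("max_contig_count must be positive")


@dataclass
class ExpressionMatrix:
    """vlincRNA x sample matrix of normalised expression densities."""

    values: pd.DataFrame  # rows: vlinc ids, columns: sample ids
    groups: Dict[str, str] = field(default_factory=dict)  # sample -> group

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0")
        for sample, group in self.groups.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} for sample {sample}")

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    @property
    def vlinc_ids(self) -> List[str]:
        return list(self.values.index)

    def min_nonzero(self) -> float:
        arr = self.values.to_numpy()
        nz = arr[arr > 0]
        if nz.size == 0:
            raise ValueError("matrix has no nonzero values")
        return float(nz.min())

    def with_zero_replacement(self) -> "ExpressionMatrix":
        """Replace zeros with the dataset-wide minimal nonzero value."""
        floor = self.min_nonzero()
        vals = self.values.where(self.values > 0, floor)
        return ExpressionMatrix(vals, dict(self.groups))

    def samples_in_group(self, group: str) -> List[str]:
        return [s for s in self.samples if self.groups.get(s) == group]


def quantify(
    contigs_by_sample: Mapping[str, Sequence[Contig]],
    vlincs: Sequence[VlincRNA],
    params: QuantParams = QuantParams(),
    groups: Mapping[str, str] | None = None,
    sample_total_bases: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Quantify each vlincRNA in each sample.

    raw(v, s) = sum of base counts of sample s contigs sharing >= 1 base with
    v (matching strand when both are stranded; a contig straddling a boundary
    contributes its full base count unless ``proportional_attribution``).
    value = raw * (depth_target / sample_total) * (length_target / length).

    The per-sample depth denominator defaults to the sample's summed retained
    contig base counts; pass ``sample_total_bases`` to override (e.g. with
    total sequenced bases).
    """
    data: Dict[str, List[float]] = {}
    for sample, contigs in contigs_by_sample.items():
        kept = [c for c in contigs if c.base_count <= params.max_contig_count]
        if sample_total_bases is not None and sample in sample_total_bases:
            total = float(sample_total_bases[sample])
        else:
            total = float(sum(c.base_count for c in kept))
        if total <= 0:
            raise ValueError(f"sample {sample} has zero total bases")
        # group contigs per (chrom): sorted arrays for overlap queries
        per_chrom: Dict[str, List[Tuple[int, int, str, int, int]]] = {}
        for c in kept:
            iv = c.interval
            per_chrom.setdefault(iv.chrom, []).append(
                (iv.start, iv.end, iv.strand, c.base_count, iv.length)
            )
        for rows in per_chrom.values():
            rows.sort()
        col: List[float] = []
        for v in vlincs:
            iv = v.interval
            raw = 0.0
            for cs, ce, cstrand, count, clen in per_chrom.get(iv.chrom, ()):
                if cs >= iv.end:
                    break
                if ce <= iv.start:
                    continue
                if iv.strand != "." and cstrand != ".":
                    if not _strands_match(cstrand, iv.strand):
                        continue
                if params.proportional_attribution:
                    ov = min(ce, iv.end) - max(cs, iv.start)
                    raw += count * ov / clen
                else:
                    raw += count
            value = (
                raw
                * (params.depth_norm_target / total)
                * (params.length_norm_target / iv.length)
            )
            col.append(value)
        data[sample] = col
    df = pd.DataFrame(data, index=[v.vlinc_id for v in vlincs])
    return ExpressionMatrix(df, dict(groups or {}))


@dataclass(frozen=True)
class SpecificityIndex:
    vlinc_id: str
    index: float
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        if not self.index > 0:
            raise ValueError("specificity index must be > 0")


def tissue_specificity_index(
    matrix: ExpressionMatrix, vlinc_id: str
) -> SpecificityIndex:
    """Ratio of the highest expresser to the second highest expresser
    (after zero replacement)."""
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples")
    vals = matrix.with_zero_replacement().values.loc[vlinc_id].to_numpy()
    order = np.sort(vals)[::-1]
    return SpecificityIndex(vlinc_id, float(order[0] / order[1]))


def cellline_specificity_index(
    matrix: ExpressionMatrix, vlinc_id: str, target_sample: str
) -> SpecificityIndex:
    """Ratio of the target sample's level to the maximum level over all other
    samples (after zero replacement)."""
    if target_sample not in matrix.samples:
        raise KeyError(f"sample {target_sample!r} not in matrix")
    row = matrix.with_zero_replacement().values.loc[vlinc_id]
    others = row.drop(labels=[target_sample])
    if others.empty:
        raise ValueError("need >= 1 non-target sample")
    return SpecificityIndex(
        vlinc_id, float(row[target_sample] / others.max()), target_sample
    )


def cellline_specific_vlincs(
    matrix: ExpressionMatrix,
    target_sample: str,
    called_in_target: Sequence[str] | None = None,
    cutoff: float = 5.0,
) -> List[str]:
    """Regions specific to one cell line: called in the target sample (when a
    called-id list is given) and with a cell-line specificity index >= cutoff.

    The cutoff has no canonical value; 5 is the package default.
    """
    candidates = (
        list(called_in_target) if called_in_target is not None else matrix.vlinc_ids
    )
    return [
        vid
        for vid in candidates
        if cellline_specificity_index(matrix, vid, target_sample).index >= cutoff
    ]


RATIO_COLUMNS = (
    "max_cancer_vs_max_primary",
    "immortalized_vs_max_primary",
    "esc_vs_max_primary",
)


def group_ratio_summary(
    matrix: ExpressionMatrix,
    ltr_flags: Mapping[str, bool],
    geometric: bool = False,
) -> pd.DataFrame:
    """Mean per-region ratios of group-maximal expression vs primary cells,
    stratified by LTR-driven status.

    Per region: max(malignant) / max(primary), max(immortalized) / max(primary)
    and max(embryonic-stem) / max(primary), all after zero replacement.
    Rows: "LTR", "non-LTR"; a stratum or group with no members yields NaN.
    """
    repl = matrix.with_zero_replacement()
    cancer = repl.samples_in_group("malignant")
    primary = repl.samples_in_group("primary")
    immortal = repl.samples_in_group("immortalized")
    esc = repl.samples_in_group("embryonic-stem")
    if not primary:
        raise ValueError("no primary samples: ratios are undefined")

    rows = {"LTR": [], "non-LTR": []}
    for vid in repl.vlinc_ids:
        if vid not in ltr_flags:
            continue
        r = repl.values.loc[vid]
        denom = r[primary].max()
        ratios = [
            r[cancer].max() / denom if cancer else math.nan,
            r[immortal].max() / denom if immortal else math.nan,
            r[esc].max() / denom if esc else math.nan,
        ]
        rows["LTR" if ltr_flags[vid] else "non-LTR"].append(ratios)

    def agg(stratum: List[List[float]]) -> List[float]:
        if not stratum:
            return [math.nan] * 3
        arr = np.asarray(stratum, dtype=float)
        out = []
        for j in range(3):
            col = arr[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                out.append(math.nan)
            elif geometric:
                out.append(float(np.exp(np.mean(np.log(col)))))
            else:
                out.append(float(np.mean(col)))
        return out

    return pd.DataFrame(
        {"LTR": agg(rows["LTR"]), "non-LTR": agg(rows["non-LTR"])},
        index=list(RATIO_COLUMNS),
    ).T


@dataclass(frozen=True)
class Transcript:
    """A spliced transcript model: exon blocks on one chromosome/strand."""

    transcript_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript needs >= 1 exon")
        prev = -1
        for s, e in self.exons:
            if not (0 <= s < e) or s < prev:
                raise ValueError("exons must be sorted and non-overlapping")
            prev = e

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )


def intron_exon_ratio(
    density: DensityTrack, transcripts: Sequence[Transcript]
) -> Tuple[Dict[str, float], float]:
    """Per-transcript (mean intronic density) / (mean exonic density) and the
    cohort median. Transcripts with no introns or zero exonic density are
    excluded from both outputs."""
    if not transcripts:
        raise ValueError("empty transcript set")
    ratios: Dict[str, float] = {}
    for t in transcripts:
        introns = t.introns
        if not introns:
            continue
        exon_len = sum(e - s for s, e in t.exons)
        exon_sig = sum(density.sum_over(t.chrom, s, e) for s, e in t.exons)
        if exon_sig <= 0:
            continue
        intron_len = sum(e - s for s, e in introns)
        intron_sig = sum(density.sum_over(t.chrom, s, e) for s, e in introns)
        ratios[t.transcript_id] = (intron_sig / intron_len) / (exon_sig / exon_len)
    median = float(np.median(list(ratios.values()))) if ratios else math.nan
    return ratios, median
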