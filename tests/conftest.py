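import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vlincscan.intervals import Genome, GenomicInterval, IntervalSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TOY_CHROM_LEN = 10_000


def per_base_cover(iset: IntervalSet, chrom: str, length: int, strand=None) -> np.ndarray:
    """Brute-force boolean per-base cover of a toy chromosome.

    ``strand=None`` means strand-blind; otherwise only intervals matching the
    strand ("." matches both) contribute.
    """
    cover = np.zeros(length, dtype=bool)
    for iv in iset:
        if iv.chrom != chrom:
            continue
        if strand is not None and not (
            iv.strand == "." or strand == "." or iv.strand == strand
        ):
            continue
        cover[iv.start : min(iv.end, length)] = True
    return cover


def cover_to_intervals(cover: np.ndarray, chrom: str, strand: str = ".") -> list:
    """Back-convert a boolean cover to a sorted interval list."""
    out = []
    padded = np.concatenate([[False], cover, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return out


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome({"toy": TOY_CHROM_LEN})
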