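"""Alignment I/O: per-base depth profiles and anomalous read-pair extraction.

This module is the only place that touches SAM/BAM; everything downstream
works on numpy depth arrays and small dataclasses. Depth follows plain
pileup semantics: a position's depth is the number of counted reads whose
reference-consuming CIGAR span covers it. Unmapped, secondary, supplementary
and duplicate-flagged records are never counted. Coordinates are 0-based
half-open internally; SAM's 1-based positions are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

DELETION_LIKE = "deletion-like"
AMPLIFICATION_LIKE = "amplification-like"


@dataclass
class DepthProfile:
    """Per-base read depth for one chromosome of one sample."""

    chrom: str
    depths: np.ndarray  # int array, one entry per base of the chromosome

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if len(self.depths) and self.depths.min() < 0:
            raise ValueError("depths must be non-negative")

    @property
    def length(self) -> int:
        return len(self.depths)

    def mean(self) -> float:
        return float(self.depths.mean()) if self.length else 0.0


@dataclass(frozen=True)
class AnomalousPair:
    """A read pair whose insert deviates beyond tolerance from the library's.

    ``insert`` is the outer mapped span taken from the template length of the
    leftmost mate. Inserts larger than expected flag deletions (the reference
    contains sequence the sample lacks); smaller inserts flag amplifications.
    """

    chrom: str
    left: int  # leftmost mapped base, 0-based
    insert: int
    category: str  # DELETION_LIKE or AMPLIFICATION_LIKE


@dataclass
class AnomalyExtraction:
    """Result bundle of :func:`extract_anomalous_pairs`."""

    pairs: list[AnomalousPair] = field(default_factory=list)
    n_skipped: int = 0  # counted mates with missing/invalid template length


def _open_alignment(path: str | Path) -> pysam.AlignmentFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    return pysam.AlignmentFile(str(path), mode, check_sq=False)


def _counted(read: pysam.AlignedSegment, min_mapq: int = 0) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_duplicate:
        return False
    if min_mapq and read.mapping_quality < min_mapq:
        return False
    return True


def read_chrom_list(path: str | Path) -> list[str]:
    """Read a chromosome-name list, one name per line, blanks ignored."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines()]
    names = [n for n in names if n]
    if not names:
        raise ValueError(f"chromosome list {path} is empty")
    return names


def read_depth_profile(
    alignment_file: str | Path,
    chroms: Sequence[str],
    min_mapq: int = 0,
) -> dict[str, DepthProfile]:
    """Compute per-base depth for each requested chromosome.

    Depth at position p equals the number of counted reads whose aligned
    (reference-consuming) blocks cover p. Chromosomes with no alignments
    yield an all-zero profile.
    """
    if not chroms:
        raise ValueError("chroms must be non-empty")
    with _open_alignment(alignment_file) as af:
        header_lengths = dict(zip(af.references, af.lengths))
        for chrom in chroms:
            if chrom not in header_lengths:
                raise ValueError(
                    f"chromosome {chrom!r} absent from header of {alignment_file}"
                )
        profiles: dict[str, DepthProfile] = {}
        wanted = set(chroms)
        depth_arrays = {
            chrom: np.zeros(header_lengths[chrom], dtype=np.int32) for chrom in chroms
        }
        for read in af.fetch(until_eof=True):
            if not _counted(read, min_mapq):
                continue
            chrom = read.reference_name
            if chrom not in wanted:
                continue
            arr = depth_arrays[chrom]
            n = len(arr)
            for start, end in read.get_blocks():
                lo, hi = max(start, 0), min(end, n)
                if lo < hi:
                    arr[lo:hi] += 1
        for chrom in chroms:
            profiles[chrom] = DepthProfile(chrom=chrom, depths=depth_arrays[chrom])
    return profiles


def extract_anomalous_pairs(
    alignment_file: str | Path,
    expected_insert: float,
    insert_sd: float,
    n_sd: float = 1.0,
    chroms: Iterable[str] | None = None,
) -> AnomalyExtraction:
    """Collect read pairs with anomalous insert sizes, one entry per pair.

    A pair is emitted iff ``|insert - expected_insert| > n_sd * insert_sd``,
    with the insert read from the template length of the leftmost mate
    (TLEN > 0), so each proper pair is counted exactly once. Larger-than-
    expected inserts are deletion-like, smaller amplification-like.
    """
    if expected_insert <= 0:
        raise ValueError("expected_insert must be positive")
    if insert_sd < 0 or n_sd <= 0:
        raise ValueError("insert_sd must be >= 0 and n_sd > 0")
    tolerance = n_sd * insert_sd
    wanted = set(chroms) if chroms is not None else None
    out = AnomalyExtraction()
    saw_paired = False
    with _open_alignment(alignment_file) as af:
        for read in af.fetch(until_eof=True):
            if not _counted(read):
                continue
            if not read.is_paired:
                continue
            saw_paired = True
            if read.mate_is_unmapped:
                continue
            tlen = read.template_length
            if tlen < 0:
                continue  # rightmost mate; the pair is counted at its left end
            if tlen == 0:
                out.n_skipped += 1
                continue
            chrom = read.reference_name
            if wanted is not None and chrom not in wanted:
                continue
            insert = int(tlen)
            if abs(insert - expected_insert) <= tolerance:
                continue
            category = DELETION_LIKE if insert > expected_insert else AMPLIFICATION_LIKE
            out.pairs.append(
                AnomalousPair(
                    chrom=chrom,
                    left=read.reference_start,
                    insert=insert,
                    category=category,
                )
            )
    if not saw_paired:
        logger.warning(
            "%s contains no paired records; no anomalous pairs extracted",
            alignment_file,
        )
    return out
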