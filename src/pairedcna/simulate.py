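"""Synthetic paired-sample data with implanted copy-number alterations.

Two generators are provided. The depth-profile generator draws independent
per-base Poisson depths — the quantity the caller actually consumes — with
the test-sample rate scaled by copy_number/2 inside implanted events. The
read-pair generator places paired reads on an event-modified donor genome
(deletions removed, amplifications as in-place tandem copies, split across
two haplotypes) and lifts them back to reference coordinates, so pairs
spanning a deletion show inflated reference inserts and pairs spanning a
tandem-amplification junction show deflated ones; it exists to exercise the
insert-size boundary module and emits minimal coordinate-sorted SAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .caller import AMPLIFICATION, DELETION
from .depth import DepthProfile

DEFAULT_COPY_STATES = (0, 1, 3, 4)


@dataclass(frozen=True)
class SimulatedEvent:
    """A ground-truth implanted amplification or deletion."""

    chrom: str
    start: int
    end: int
    kind: str
    copy_number: int

    @property
    def length(self) -> int:
        return self.end - self.start


def simulate_events(
    genome_len: int,
    fraction: float = 0.015,
    size_range: tuple[int, int] = (10_000, 50_000),
    copy_states: tuple[int, ...] = DEFAULT_COPY_STATES,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
    min_gap: int = 10_000,
) -> list[SimulatedEvent]:
    """Draw non-overlapping events covering ~``fraction`` of the genome.

    Sizes are uniform in ``size_range``; sizes are accumulated until the
    total reaches fraction * genome_len, so the realized total is within one
    event size of the target. Placements are uniform, rejected on overlap
    (events keep at least ``min_gap`` bases apart so neighboring events stay
    separable). Deterministic under a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    lo, hi = size_range
    if not 0 < lo <= hi < genome_len:
        raise ValueError("size_range must satisfy 0 < min <= max < genome_len")
    if any(cs == 2 or cs < 0 for cs in copy_states):
        raise ValueError("copy_states must be non-negative and never 2 (neutral)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    target = fraction * genome_len
    sizes: list[int] = []
    while sum(sizes) < target:
        sizes.append(int(rng.integers(lo, hi + 1)))
    if sum(sizes) + min_gap * (len(sizes) + 1) > genome_len:
        raise ValueError(
            f"cannot pack {len(sizes)} events totalling {sum(sizes)} bases "
            f"into a {genome_len}-base genome"
        )

    placed: list[tuple[int, int]] = []
    for size in sorted(sizes, reverse=True):  # big events first: easier packing
        for _ in range(10_000):
            start = int(rng.integers(0, genome_len - size + 1))
            end = start + size
            if all(end + min_gap <= s or e + min_gap <= start for s, e in placed):
                placed.append((start, end))
                break
        else:
            raise ValueError("infeasible packing: could not place all events")

    placed.sort()
    events = []
    for start, end in placed:
        cn = int(rng.choice(copy_states))
        kind = DELETION if cn < 2 else AMPLIFICATION
        events.append(
            SimulatedEvent(chrom=chrom, start=start, end=end, kind=kind, copy_number=cn)
        )
    return events


def simulate_depth_pair(
    genome_len: int,
    events: list[SimulatedEvent],
    coverage: float,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
) -> tuple[DepthProfile, DepthProfile]:
    """Paired per-base Poisson depth profiles (test, ref).

    Ref depth at every base is Poisson(coverage); test depth is
    Poisson(coverage * copy_number / 2) inside events and Poisson(coverage)
    elsewhere, independent across positions.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = rng.poisson(coverage, genome_len).astype(np.int32)
    test = rng.poisson(coverage, genome_len).astype(np.int32)
    for ev in events:
        rate = coverage * ev.copy_number / 2.0
        test[ev.start : ev.end] = rng.poisson(rate, ev.length)
    return (
        DepthProfile(chrom=chrom, depths=test),
        DepthProfile(chrom=chrom, depths=ref),
    )


@dataclass
class SimulatedPairs:
    """Reference-coordinate placements of simulated read pairs."""

    chrom: str
    genome_len: int
    read_len: int
    r1_start: np.ndarray  # 0-based ref start of one mate
    r2_start: np.ndarray  # 0-based ref start of the other mate

    def __len__(self) -> int:
        return len(self.r1_start)

    @property
    def left(self) -> np.ndarray:
        return np.minimum(self.r1_start, self.r2_start)

    @property
    def ref_insert(self) -> np.ndarray:
        """Outer mapped span on the reference, per pair."""
        right = np.maximum(self.r1_start, self.r2_start) + self.read_len
        return right - self.left


def _haplotype_segments(
    genome_len: int, events: list[SimulatedEvent]
) -> list[list[tuple[int, int]]]:
    """Donor-genome segment lists (ref_start, ref_end) for two haplotypes.

    copy_number c splits as ceil(c/2) copies on haplotype 1 and floor(c/2)
    on haplotype 2 (neutral regions: one copy each); amplified segments are
    tandem-repeated in place.
    """
    haps: list[list[tuple[int, int]]] = [[], []]
    pos = 0
    for ev in sorted(events, key=lambda e: e.start):
        if ev.start > pos:
            for h in haps:
                h.append((pos, ev.start))
        copies = (math.ceil(ev.copy_number / 2), ev.copy_number // 2)
        for h, c in zip(haps, copies):
            h.extend([(ev.start, ev.end)] * c)
        pos = ev.end
    if pos < genome_len:
        for h in haps:
            h.append((pos, genome_len))
    return haps


def simulate_read_pairs(
    genome_len: int,
    events: list[SimulatedEvent],
    coverage: float,
    read_len: int = 76,
    insert_mean: float = 250.0,
    insert_sd: float = 50.0,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
) -> SimulatedPairs:
    """Place paired reads on the donor genome and lift them to the reference.

    Pair count is coverage * donor_len / (2 * read_len), split across the two
    haplotypes in proportion to their lengths. Inserts are Gaussian
    (insert_mean, insert_sd) floored at 2 * read_len. Each read maps at the
    reference position of its donor start (full-length match; junction
    splitting is not modeled — the anomalous signal lives in the pair span).
    """
    if read_len >= insert_mean:
        raise ValueError("read_len must be smaller than insert_mean")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    haps = _haplotype_segments(genome_len, events)
    r1_parts, r2_parts = [], []
    for segments in haps:
        if not segments:
            continue
        seg = np.array(segments)
        seg_len = seg[:, 1] - seg[:, 0]
        donor_len = int(seg_len.sum())
        if donor_len < 2 * read_len + 1:
            continue
        n_pairs = int(round(coverage * donor_len / (2.0 * read_len)))
        if n_pairs == 0:
            continue
        inserts = np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(np.int64)
        inserts = np.maximum(inserts, 2 * read_len)
        inserts = np.minimum(inserts, donor_len)
        starts = np.floor(rng.random(n_pairs) * (donor_len - inserts + 1)).astype(
            np.int64
        )
        mate2 = starts + inserts - read_len
        cum = np.concatenate(([0], np.cumsum(seg_len)))
        for donor_pos, sink in ((starts, r1_parts), (mate2, r2_parts)):
            idx = np.searchsorted(cum, donor_pos, side="right") - 1
            sink.append(seg[idx, 0] + (donor_pos - cum[idx]))
    if not r1_parts:
        empty = np.empty(0, dtype=np.int64)
        return SimulatedPairs(chrom, genome_len, read_len, empty, empty.copy())
    return SimulatedPairs(
        chrom=chrom,
        genome_len=genome_len,
        read_len=read_len,
        r1_start=np.concatenate(r1_parts),
        r2_start=np.concatenate(r2_parts),
    )


def write_sam(pairs: SimulatedPairs, path: str | Path) -> None:
    """Emit the simulated pairs as minimal coordinate-sorted SAM."""
    left = pairs.left
    right = np.maximum(pairs.r1_start, pairs.r2_start)
    insert = pairs.ref_insert
    records = []
    for i in range(len(pairs)):
        name = f"pair{i}"
        l, r, ins = int(left[i]), int(right[i]), int(insert[i])
        # leftmost mate: paired, proper, mate-reverse, first-in-pair
        records.append((l, f"{name}\t99\t{pairs.chrom}\t{l + 1}\t60\t"
                           f"{pairs.read_len}M\t=\t{r + 1}\t{ins}\t*\t*"))
        records.append((r, f"{name}\t147\t{pairs.chrom}\t{r + 1}\t60\t"
                           f"{pairs.read_len}M\t=\t{l + 1}\t{-ins}\t*\t*"))
    records.sort(key=lambda t: t[0])
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{pairs.chrom}\tLN:{pairs.genome_len}",
    ]
    lines += [rec for _, rec in records]
    Path(path).write_text("\n".join(lines) + "\n")
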