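"""Breakpoint detection from anomalous read-pair density.

Anomalous pairs (insert size outside the library tolerance) are counted in
coarse bins per category. Because the anomaly rate is a fixed fraction of
local coverage, the count in each bin is proportional to local copy number,
so the ratio of counts between adjacent bins jumps at a copy-state
transition: ratios near 0 or 0.5 in the deletion category mark entry into a
full or mono-allelic deletion (copy states 0 and 1), ratios near 1.5, 2,
2.5, ... in the amplification category mark entry into copy states 3, 4,
5, ... Boundaries found in the matched normal are subtracted (within a
small tolerance) to leave somatic breakpoints, which can then refine the
caller's coarse call edges.

This module deliberately applies no coverage normalization: it operates on
each sample separately and does not require equal test/ref coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .caller import AMPLIFICATION, DELETION, ScnaCall
from .depth import AMPLIFICATION_LIKE, DELETION_LIKE, AnomalousPair


@dataclass(frozen=True)
class BoundaryPoint:
    """A copy-state transition at the junction between two coarse bins."""

    chrom: str
    pos: int  # genomic coordinate of the bin junction
    category: str  # "deletion" or "amplification"
    ratio: float  # adjacent-bin anomalous-count ratio that fired
    copy_state: int  # inferred integer copy number (never 2)


def ratio_windows(max_copy_state: int = 10, half_width: float = 0.1) -> dict:
    """Category-specific (center, copy_state) ratio windows.

    Deletion: 0 -> state 0, 0.5 -> state 1. Amplification: 1.5 + 0.5*m for
    m = 0, 1, ... -> states 3, 4, ... up to ``max_copy_state``. Each window
    spans center +/- half_width.
    """
    windows = {DELETION: [(0.0, 0), (0.5, 1)], AMPLIFICATION: []}
    center = 1.5
    while round(2 * center) <= max_copy_state:
        windows[AMPLIFICATION].append((center, int(round(2 * center))))
        center += 0.5
    return {
        cat: [(c - half_width, c + half_width, state) for c, state in entries]
        for cat, entries in windows.items()
    }


def bin_anomalous(
    pairs: Iterable[AnomalousPair],
    bin_size: int = 5000,
    genome_len: int | None = None,
) -> dict[str, np.ndarray]:
    """Histogram anomalous pairs by leftmost position, per category.

    Returns {"deletion": counts, "amplification": counts} with half-open
    bins [i*bin_size, (i+1)*bin_size).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    pairs = list(pairs)
    max_pos = max((p.left for p in pairs), default=-1)
    extent = genome_len if genome_len is not None else max_pos + 1
    n_bins = max((extent + bin_size - 1) // bin_size, 1)
    counts = {
        DELETION: np.zeros(n_bins, dtype=np.int64),
        AMPLIFICATION: np.zeros(n_bins, dtype=np.int64),
    }
    for p in pairs:
        cat = DELETION if p.category == DELETION_LIKE else AMPLIFICATION
        b = p.left // bin_size
        if 0 <= b < n_bins:
            counts[cat][b] += 1
    return counts


def detect_boundaries(
    counts: dict[str, np.ndarray],
    chrom: str = "",
    bin_size: int = 5000,
    min_count: int = 5,
    max_copy_state: int = 10,
    test_reciprocal: bool = True,
) -> list[BoundaryPoint]:
    """Scan adjacent-bin count ratios for copy-state transitions.

    For each adjacent bin pair (i, i+1) within a category whose larger count
    reaches ``min_count``, the ratio r = counts[i+1] / counts[i] is tested
    against the category's windows (r = 0 when only the numerator is zero;
    the pair is skipped when both are zero). With ``test_reciprocal`` the
    inverse ratio is tested too, so leaving an event is detected as well as
    entering it. A firing ratio emits a boundary at the bin junction.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    windows = ratio_windows(max_copy_state=max_copy_state)
    out: list[BoundaryPoint] = []
    for category in (DELETION, AMPLIFICATION):
        c = np.asarray(counts[category])
        for i in range(len(c) - 1):
            a, b = int(c[i]), int(c[i + 1])
            if a == 0 and b == 0:
                continue
            if max(a, b) < min_count:
                continue
            candidates = []
            if a > 0:
                candidates.append(b / a)
            if test_reciprocal and b > 0:
                candidates.append(a / b)
            hit = None
            for r in candidates:
                for lo, hi, state in windows[category]:
                    if lo <= r <= hi:
                        hit = (r, state)
                        break
                if hit:
                    break
            if hit:
                out.append(
                    BoundaryPoint(
                        chrom=chrom,
                        pos=(i + 1) * bin_size,
                        category=category,
                        ratio=float(hit[0]),
                        copy_state=hit[1],
                    )
                )
    out.sort(key=lambda bp: (bp.pos, bp.category))
    return out


def subtract_normal_boundaries(
    test_bounds: Sequence[BoundaryPoint],
    ref_bounds: Sequence[BoundaryPoint],
    tol: int = 100,
) -> list[BoundaryPoint]:
    """Drop test boundaries within ``tol`` bases of any matched-normal one.

    Comparison is across categories: a normal-sample boundary of either
    category suppresses a nearby test boundary.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not ref_bounds:
        return list(test_bounds)
    ref_pos = np.sort(np.array([b.pos for b in ref_bounds]))
    kept = []
    for b in test_bounds:
        i = np.searchsorted(ref_pos, b.pos)
        near = False
        for j in (i - 1, i):
            if 0 <= j < len(ref_pos) and abs(int(ref_pos[j]) - b.pos) <= tol:
                near = True
                break
        if not near:
            kept.append(b)
    return kept


def refine_call_boundaries(
    calls: Sequence[ScnaCall],
    bounds: Sequence[BoundaryPoint],
    max_snap: int = 5000,
) -> list[ScnaCall]:
    """Snap call edges to the nearest surviving compatible boundary.

    Deletion calls snap only to deletion boundaries, amplifications to
    amplification boundaries. An edge with no boundary within ``max_snap``
    is unchanged; a snap that would produce a zero- or negative-length call
    is rejected and the call left as-is.
    """
    if max_snap < 0:
        raise ValueError("max_snap must be >= 0")
    by_cat = {
        DELETION: np.sort(np.array([b.pos for b in bounds if b.category == DELETION])),
        AMPLIFICATION: np.sort(
            np.array([b.pos for b in bounds if b.category == AMPLIFICATION])
        ),
    }

    def nearest(pos: int, positions: np.ndarray) -> int | None:
        if len(positions) == 0:
            return None
        i = np.searchsorted(positions, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(int(positions[j]) - pos)
                if d <= max_snap and (best is None or d < best[0]):
                    best = (d, int(positions[j]))
        return best[1] if best else None

    refined = []
    for call in calls:
        positions = by_cat[call.kind]
        new_start = nearest(call.start, positions)
        new_end = nearest(call.end, positions)
        start = new_start if new_start is not None else call.start
        end = new_end if new_end is not None else call.end
        if start < end and (start, end) != (call.start, call.end):
            refined.append(replace(call, start=start, end=end, refined=True))
        else:
            refined.append(replace(call))
    return refined
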