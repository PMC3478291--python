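"""Benchmark metrics: call/truth matching, summary scores, interval algebra.

A call matches a truth event of the same kind when each of its breakpoints
deviates by at most a fixed fraction (default 10%) of the truth length;
matching is one-to-one, greedy by overlap. Scores follow the standard
definitions: sensitivity = % of truth events matched, false-positive rate =
% of calls matching nothing, and mean size deviation =
mean |detected - simulated| / simulated x 100 over matched calls.

The interval helpers implement the subtractive somatic approach (test MINUS
ref call sets) and base-level concordance between two call sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

TP, FP, FN = "TP", "FP", "FN"


@dataclass
class MatchResult:
    """Outcome of matching calls to a truth set."""

    matches: list[tuple[object, object]] = field(default_factory=list)  # (call, truth)
    fp_calls: list[object] = field(default_factory=list)
    fn_truths: list[object] = field(default_factory=list)
    n_calls: int = 0
    n_truth: int = 0


@dataclass
class BenchmarkSummary:
    sensitivity_pct: float
    false_positive_pct: float
    mean_size_deviation_pct: float


def _span(x) -> tuple[int, int]:
    return int(x.start), int(x.end)


def match_events(calls, truth, margin: float = 0.10) -> MatchResult:
    """Greedy one-to-one matching of calls to truth events.

    Candidate pairs must share kind and satisfy the breakpoint margin:
    |call.start - truth.start| <= margin * truth_length and likewise for the
    end. Pairs are consumed in order of decreasing overlap; leftovers are
    false positives (calls) and false negatives (truths).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    calls, truth = list(calls), list(truth)
    candidates = []
    for ci, c in enumerate(calls):
        cs, ce = _span(c)
        for ti, t in enumerate(truth):
            if c.kind != t.kind:
                continue
            ts, te = _span(t)
            tol = margin * (te - ts)
            if abs(cs - ts) > tol or abs(ce - te) > tol:
                continue
            overlap = min(ce, te) - max(cs, ts)
            candidates.append((overlap, ci, ti))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    result = MatchResult(n_calls=len(calls), n_truth=len(truth))
    for _, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        result.matches.append((calls[ci], truth[ti]))
    result.fp_calls = [c for i, c in enumerate(calls) if i not in used_c]
    result.fn_truths = [t for i, t in enumerate(truth) if i not in used_t]
    return result


def summarize(result: MatchResult) -> BenchmarkSummary:
    """Sensitivity, false-positive and size-deviation percentages."""
    tp = len(result.matches)
    sens = 100.0 * tp / result.n_truth if result.n_truth else 0.0
    fp = 100.0 * len(result.fp_calls) / result.n_calls if result.n_calls else 0.0
    devs = []
    for call, truth in result.matches:
        cs, ce = _span(call)
        ts, te = _span(truth)
        devs.append(100.0 * abs((ce - cs) - (te - ts)) / (te - ts))
    mean_dev = float(np.mean(devs)) if devs else 0.0
    return BenchmarkSummary(
        sensitivity_pct=sens,
        false_positive_pct=fp,
        mean_size_deviation_pct=mean_dev,
    )


def _normalize(intervals) -> list[tuple[int, int]]:
    """Sort and merge overlapping/abutting half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_subtract(a, b) -> list[tuple[int, int]]:
    """Exact base-level set difference a MINUS b, as maximal intervals."""
    a = _normalize(a)
    b = _normalize(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _total(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def concordance(a, b, min_length: int = 0) -> float:
    """Fraction of concordant bases: |a n b| / |a u b|.

    ``min_length`` optionally drops intervals shorter than that many bases
    from both inputs (a minimum-support filter; off by default). Two empty
    sets give 0 with a warning.
    """
    if min_length:
        a = [(s, e) for s, e in a if e - s >= min_length]
        b = [(s, e) for s, e in b if e - s >= min_length]
    a, b = _normalize(a), _normalize(b)
    union = _total(_normalize(a + b))
    if union == 0:
        logger.warning("concordance of two empty interval sets is undefined; returning 0")
        return 0.0
    inter = _total(a) + _total(b) - union
    return inter / union
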