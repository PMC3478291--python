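"""The paired-sample SCNA caller.

Pipeline: per-base depths are averaged into fixed-width bins; test:ref
log2 ratios are computed per bin, with zero-depth bins tagged as undefined
(Udef) and resolved from their neighborhood; ratios are smoothed by an
unweighted sliding average; the smoothed ratios of k contiguous bins are
summed into a cumulative log2 ratio (clr) whose square root is treated as
normal with variance 1/4 per sample; windows significant at the configured
p-value are fused into calls, and each call is localized to the
highest-scoring segment of raw per-bin ratios.

The sign convention is test-over-ref: a stretch of negative ratios marks a
deletion, positive an amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import norm

from .config import RunConfig
from .depth import DepthProfile

logger = logging.getLogger(__name__)

# Bin definedness tags.
DEFINED = 0
UDEF_DELETION = 1  # test depth 0, ref > 0
UDEF_AMPLIFICATION = 2  # ref depth 0, test > 0
UDEF_NEUTRAL = 3  # both 0

TAG_NAMES = {
    DEFINED: "Defined",
    UDEF_DELETION: "Udef-Deletion",
    UDEF_AMPLIFICATION: "Udef-Amplification",
    UDEF_NEUTRAL: "Udef-Neutral",
}

AMPLIFICATION = "amplification"
DELETION = "deletion"


@dataclass
class BinnedDepth:
    """Mean read depth per fixed-width bin, ordered by genomic position."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


class RatioBin(NamedTuple):
    index: int
    lr: float
    tag: int


@dataclass
class RatioBins:
    """Array-backed sequence of per-bin log2 ratios with definedness tags.

    Undefined bins carry lr = nan until :func:`resolve_udef` assigns them a
    value; tags are preserved through resolution for reporting.
    """

    lr: np.ndarray
    tag: np.ndarray

    def __post_init__(self) -> None:
        self.lr = np.asarray(self.lr, dtype=float)
        self.tag = np.asarray(self.tag, dtype=np.int8)
        if self.lr.shape != self.tag.shape:
            raise ValueError("lr and tag must have equal length")

    def __len__(self) -> int:
        return len(self.lr)

    def __getitem__(self, i: int) -> RatioBin:
        return RatioBin(i, float(self.lr[i]), int(self.tag[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))


class ClrWindow(NamedTuple):
    start_bin: int
    k: int
    clr: float
    z: float
    p: float


@dataclass
class ClrWindows:
    """All k-bin cumulative-log2-ratio windows of one chromosome."""

    k: int
    clr: np.ndarray
    z: np.ndarray
    p: np.ndarray

    def __len__(self) -> int:
        return len(self.clr)

    def __getitem__(self, i: int) -> ClrWindow:
        return ClrWindow(i, self.k, float(self.clr[i]), float(self.z[i]), float(self.p[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))


@dataclass
class ScnaCall:
    """A reported amplification/deletion interval.

    ``start``/``end`` are 0-based half-open internally; the TSV writer emits
    1-based inclusive coordinates.
    """

    chrom: str
    start: int
    end: int
    clr: float
    z: float
    p: float
    kind: str
    refined: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def bin_depths(profile: DepthProfile, bin_size: int = 50) -> BinnedDepth:
    """Average per-base depths into bins of ``bin_size`` bases.

    The trailing partial bin (fewer than bin_size positions) is dropped so
    every bin has equal support.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = profile.length // bin_size
    if n_bins * bin_size < profile.length:
        logger.debug(
            "%s: dropping trailing partial bin of %d positions",
            profile.chrom,
            profile.length - n_bins * bin_size,
        )
    trimmed = profile.depths[: n_bins * bin_size].astype(float)
    values = trimmed.reshape(n_bins, bin_size).mean(axis=1) if n_bins else np.empty(0)
    return BinnedDepth(chrom=profile.chrom, bin_size=bin_size, values=values)


def pairwise_log_ratios(
    test: BinnedDepth,
    ref: BinnedDepth,
    coverage_ratio: float | str = "auto",
) -> RatioBins:
    """Per-bin log2(test/ref), normalized by the coverage ratio.

    Bins with zero depth in test, ref or both are tagged Udef-Deletion,
    Udef-Amplification and Udef-Neutral respectively and carry nan until
    resolved.
    """
    if test.bin_size != ref.bin_size:
        raise ValueError("test and ref bin sizes differ")
    if len(test) != len(ref):
        raise ValueError(
            f"bin count mismatch: test has {len(test)}, ref has {len(ref)}"
        )
    t, r = test.values, ref.values
    if coverage_ratio == "auto":
        ref_mean = r.mean() if len(r) else 0.0
        if ref_mean == 0:
            raise ValueError("coverage_ratio 'auto' undefined: ref depth is all zero")
        coverage_ratio = t.mean() / ref_mean
    coverage_ratio = float(coverage_ratio)
    if coverage_ratio <= 0:
        raise ValueError("coverage_ratio must be positive")

    tag = np.full(len(t), DEFINED, dtype=np.int8)
    tag[(t == 0) & (r > 0)] = UDEF_DELETION
    tag[(r == 0) & (t > 0)] = UDEF_AMPLIFICATION
    tag[(t == 0) & (r == 0)] = UDEF_NEUTRAL

    lr = np.full(len(t), np.nan)
    defined = tag == DEFINED
    lr[defined] = np.log2(t[defined] / r[defined]) - np.log2(coverage_ratio)
    return RatioBins(lr=lr, tag=tag)


def resolve_udef(
    bins: RatioBins,
    cap: float = 5.0,
    inherit_min: float = 0.5,
) -> RatioBins:
    """Assign log2 ratios to undefined bins.

    An undefined deletion (resp. amplification) bin inherits the ratio of the
    nearest defined bin flanking its undefined run, provided that neighbor is
    itself event-like in the same direction (|lr| >= ``inherit_min`` with the
    matching sign). Otherwise the run is isolated and the bin receives -cap
    (deletion) or +cap (amplification); undefined-neutral bins get 0. Tags
    are preserved.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    lr = bins.lr.copy()
    tag = bins.tag.copy()
    n = len(lr)
    i = 0
    while i < n:
        if tag[i] == DEFINED:
            i += 1
            continue
        j = i
        while j < n and tag[j] != DEFINED:
            j += 1
        left = lr[i - 1] if i > 0 else np.nan
        right = lr[j] if j < n else np.nan
        left_del = np.isfinite(left) and left <= -inherit_min
        right_del = np.isfinite(right) and right <= -inherit_min
        left_amp = np.isfinite(left) and left >= inherit_min
        right_amp = np.isfinite(right) and right >= inherit_min
        for b in range(i, j):
            t = tag[b]
            if t == UDEF_NEUTRAL:
                lr[b] = 0.0
                continue
            if t == UDEF_DELETION:
                ok_left, ok_right, fallback = left_del, right_del, -cap
            else:  # UDEF_AMPLIFICATION
                ok_left, ok_right, fallback = left_amp, right_amp, cap
            d_left = b - (i - 1)
            d_right = j - b
            if ok_left and (not ok_right or d_left <= d_right):
                lr[b] = left
            elif ok_right:
                lr[b] = right
            else:
                lr[b] = fallback
        i = j
    return RatioBins(lr=lr, tag=tag)


def smooth_ratios(lr: np.ndarray | RatioBins, window: int = 4) -> np.ndarray:
    """Unweighted (rectangular) sliding average over ``window`` forward bins.

    alr_i = mean(lr_i .. lr_{i+window-1}); for the last window-1 positions
    the window shrinks to the available tail, so output length equals input
    length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = lr.lr if isinstance(lr, RatioBins) else np.asarray(lr, dtype=float)
    n = len(values)
    if n == 0:
        return np.empty(0)
    cs = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    end = np.minimum(idx + window, n)
    return (cs[end] - cs[idx]) / (end - idx)


def clr_significance(clr, n_samples: int = 2):
    """Normal [0,1] statistic and one-sided p-value for a clr.

    sqrt(|clr|) is treated as approximately normal with variance 1/4 per
    sample, so z = sqrt(|clr|) / sqrt(n_samples / 4) and p is the upper-tail
    standard-normal probability at z. Only the magnitude of clr enters; its
    sign merely orients the call.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    arr = np.asarray(clr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("clr must be finite")
    z = np.sqrt(np.abs(arr)) / np.sqrt(n_samples / 4.0)
    p = norm.sf(z)
    if np.isscalar(clr) or arr.ndim == 0:
        return float(z), float(p)
    return z, p


def clr_windows(alr: np.ndarray, k: int = 10, n_samples: int = 2) -> ClrWindows:
    """Sum every k contiguous smoothed ratios, starting from every bin."""
    if k < 1:
        raise ValueError("k must be >= 1")
    alr = np.asarray(alr, dtype=float)
    n = len(alr)
    if n < k:
        logger.warning("only %d bins available for %d-bin clr windows", n, k)
        empty = np.empty(0)
        return ClrWindows(k=k, clr=empty, z=empty.copy(), p=empty.copy())
    cs = np.concatenate(([0.0], np.cumsum(alr)))
    clr = cs[k:] - cs[:-k]
    z, p = clr_significance(clr, n_samples=n_samples)
    return ClrWindows(k=k, clr=clr, z=z, p=p)


def _trim_to_best_segment(
    lr: np.ndarray, g0: int, g1: int, k: int, sign: int
) -> tuple[int, int]:
    """Localize a fused call: the sub-interval of [g0, g1) bins, at least k
    bins long, maximizing |sum(lr)| / sqrt(length) with the call's sign.

    Ratios are magnitude-clipped at 1 (one copy-change unit) first, so that
    capped or inherited undefined-bin values cannot bias edge placement:
    localization rides on the sign pattern, not on magnitude heterogeneity.
    The fused window union overhangs the true event by at most about k bins
    per side, so for large regions only edge-adjacent candidates need to be
    searched. Ties prefer the leftmost, then the longest segment.
    """
    v = np.clip(lr[g0:g1], -1.0, 1.0)
    n = len(v)
    if n < k:
        return g0, g1
    cs = np.concatenate(([0.0], np.cumsum(v)))
    reach = 2 * k + 2
    if n <= 2 * reach + k:
        starts = np.arange(0, n - k + 1)
        end_lo = None
    else:
        starts = np.arange(0, reach + 1)
        end_lo = n - reach
    best = None
    for i in starts:
        lo = max(i + k, end_lo) if end_lo is not None else i + k
        ends = np.arange(lo, n + 1)
        if not len(ends):
            continue
        sums = cs[ends] - cs[i]
        if sign > 0:
            scores = sums / np.sqrt(ends - i)
        else:
            scores = -sums / np.sqrt(ends - i)
        j = int(np.argmax(scores))
        # np.argmax takes the first maximum -> shortest end; prefer longest on ties
        tie = np.flatnonzero(scores == scores[j])
        j = int(tie[-1])
        cand = (float(scores[j]), -int(i), int(ends[j]))
        if best is None or cand > best:
            best = cand
    if best is None or best[0] <= 0:
        return g0, g1
    _, neg_i, end = best
    return g0 - neg_i, g0 + end


def merge_calls(
    windows: ClrWindows | Sequence[ClrWindow],
    p_threshold: float = 0.001,
    bin_size: int = 50,
    k: int = 10,
    chrom: str = "",
    resolved_lr: np.ndarray | None = None,
) -> list[ScnaCall]:
    """Fuse significant clr windows into SCNA calls.

    Windows with p below threshold whose k-bin spans overlap or abut and
    share clr sign form one call. The call reports the clr and statistic of
    its most significant window and the minimum window p. When the resolved
    per-bin ratios are supplied, the call interval is localized to the
    highest-scoring ratio segment within the fused span (never shorter than
    k bins); otherwise it is the union of the fused window spans.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    wins = list(windows) if not isinstance(windows, ClrWindows) else None
    if isinstance(windows, ClrWindows):
        sig_idx = np.flatnonzero(windows.p < p_threshold)
        sig = [windows[int(i)] for i in sig_idx]
    else:
        sig = [w for w in wins if w.p < p_threshold]
        sig.sort(key=lambda w: w.start_bin)
    calls: list[ScnaCall] = []
    group: list[ClrWindow] = []

    def flush(group: list[ClrWindow]) -> None:
        if not group:
            return
        g0 = group[0].start_bin
        g1 = max(w.start_bin for w in group) + k
        best = min(group, key=lambda w: (w.p, -abs(w.clr), w.start_bin))
        sign = 1 if best.clr > 0 else -1
        if resolved_lr is not None:
            g0, g1 = _trim_to_best_segment(np.asarray(resolved_lr), g0, g1, k, sign)
        calls.append(
            ScnaCall(
                chrom=chrom,
                start=g0 * bin_size,
                end=g1 * bin_size,
                clr=best.clr,
                z=best.z,
                p=min(w.p for w in group),
                kind=AMPLIFICATION if sign > 0 else DELETION,
            )
        )

    for w in sig:
        if group and w.start_bin <= group[-1].start_bin + k and (
            (w.clr > 0) == (group[0].clr > 0)
        ):
            group.append(w)
        else:
            flush(group)
            group = [w]
    flush(group)
    return calls


def call_scnas(
    test_profile: DepthProfile,
    ref_profile: DepthProfile,
    config: RunConfig | None = None,
) -> list[ScnaCall]:
    """Run the full caller on one chromosome of a test:ref pair."""
    config = config or RunConfig()
    if test_profile.chrom != ref_profile.chrom:
        raise ValueError(
            f"chromosome mismatch: {test_profile.chrom} vs {ref_profile.chrom}"
        )
    n = min(test_profile.length, ref_profile.length)
    test = bin_depths(
        DepthProfile(test_profile.chrom, test_profile.depths[:n]), config.bin_size
    )
    ref = bin_depths(
        DepthProfile(ref_profile.chrom, ref_profile.depths[:n]), config.bin_size
    )
    ratios = pairwise_log_ratios(test, ref, config.coverage_ratio)
    resolved = resolve_udef(ratios, cap=config.udef_cap, inherit_min=config.udef_inherit_min)
    alr = smooth_ratios(resolved, window=config.smooth_window)
    windows = clr_windows(alr, k=config.merge_bins)
    return merge_calls(
        windows,
        p_threshold=config.p_threshold,
        bin_size=config.bin_size,
        k=config.merge_bins,
        chrom=test_profile.chrom,
        resolved_lr=resolved.lr,
    )
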