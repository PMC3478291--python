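# Methods

This note documents the model implemented in `pairedcna`, the defaults and
the reasoning behind the choices that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Model and assumptions

The caller assumes that read depth at a locus is proportional to the copy
number of that locus in the sequenced sample, and that technical biases
(GC content, library preparation, mappability) act equally on a tumor and
its matched normal sequenced under the same protocol. Under these
assumptions the binned test:ref depth ratio is centred at copy_number/2 in
somatic events and at 1 elsewhere, once unequal total coverage is divided
out. The pipeline is deterministic: identical inputs and configuration
yield identical calls.

Samples with strong heterogeneity (low tumor purity, subclonal events)
violate the proportionality assumption — an event present in a fraction f
of cells shifts the expected ratio by only f·(cn/2 − 1) — and are outside
the intended scope, as is single-sample CNV calling.

## Caller stages and defaults

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 50 nt | depth-averaging bin width (60 supported) |
| `smooth_window` | 4 bins | rectangular sliding-average width |
| `merge_bins` (k) | 10 bins | bins summed into one clr window |
| `p_threshold` | 0.001 | one-sided retention cutoff |
| `coverage_ratio` | auto | test:ref mean-depth ratio divided out of lr |
| `udef_cap` | 5 | \|lr\| assigned to isolated zero-depth runs |
| `udef_inherit_min` | 0.5 | neighbor \|lr\| needed to seed a Udef run |
| `min_mapq` | 0 (off) | optional mapping-quality floor |

Depth follows pileup semantics: a read contributes to every reference base
its reference-consuming CIGAR operations cover; unmapped, secondary,
supplementary and duplicate-flagged records are excluded. No
mapping-quality filter is applied by default — in a pair-wise design both
samples suffer ambiguous mappings equally — but a floor is exposed for
users who want one. Bin values are the *mean* of per-base depths (the
test:ref ratio is identical to a sum at equal bin size, and means make the
coverage ratio interpretable); a trailing bin with fewer than `bin_size`
positions is dropped rather than averaged over unequal support.

**Udef resolution.** Bins with zero depth in the test, the reference or
both have no finite log-ratio. A zero-test run flanked by a defined bin
that is itself deletion-like inherits that neighbor's ratio (the run is the
interior of a larger event); symmetrically for amplifications. "Is itself
event-like" is operationalized as |lr| ≥ `udef_inherit_min` with the
matching sign: under Poisson noise a *neutral* flank bin is negative half
the time, and inheriting a near-zero noise value would silence every
isolated homozygous deletion. The floor of 0.5 sits far above neutral noise
at any usable coverage (at 5X, bin-ratio noise is ~0.13 SD) and below the
1.0 signal of a single-copy change. Runs with no eligible neighbor get
±`udef_cap` so fully deleted (or ref-absent) regions remain callable;
zero-zero bins get 0. Tags are preserved for reporting.

**Significance.** Binned read depths are Poisson (per-base depths are iid
Poisson in the simulator, so bin *sums* are exactly Poisson), and the
square root of a Poisson variable has variance ≈ ¼ nearly independent of
its mean (the classic variance-stabilizing transform; the acceptance suite
verifies var ≈ 0.25 ± 0.03 empirically). The clr statistic standardizes
accordingly: z = √|clr| / √(n/4) with n = 2 samples per comparison, and
p is the one-sided upper tail of the standard normal, so clr = 0 gives
p = 0.5 and retention at P < 0.001 corresponds to |clr| > 4.77. Only the
magnitude of clr is scored; its sign orients the call. This algebraic form
is an interpretation — it is the unique standardization consistent with
"normal [0,1] statistic", the ¼-per-sample variance and a two-sample
comparison — and is flagged as such. No multiple-testing correction is
applied; the fixed cutoff is the method's operating point and is exposed
as config.

**Detection vs localization.** Significant windows whose 10-bin spans
overlap or abut and share clr sign are fused. The fused union
systematically overhangs the true event: a window overlapping a strong
event by even one bin can clear the threshold, so the union inflates each
edge by up to k−1 bins plus smoothing bleed. The package therefore splits
detection from localization: smoothed ratios decide *whether* a region is
called, and the call interval is then the sub-interval of *raw* resolved
ratios (≥ k bins) maximizing the standardized segment score |Σlr|/√len —
the same normal-on-√ rationale as the clr statistic. Ratios are
magnitude-clipped at 1 (one copy-change unit) for this search so that
capped or inherited Udef values cannot bias edge placement; localization
rides on the sign pattern, not on magnitude heterogeneity. Ties prefer the
leftmost, then the longest segment, keeping the pipeline symmetric under
test/ref exchange. Every call still spans at least k × bin_size = 500 nt,
the caller's resolution floor. Note the 50 nt grid quantizes edges: an
event not aligned to the grid genuinely intersects ⌈len/50⌉ + 1 bins, so a
500 nt off-grid implant is correctly reported as either 500 or 550 nt; the
resolution-identity check therefore implants on the grid.

The fused group reports the clr and statistic of its most significant
window and the minimum window p. Primary output coordinates are 1-based
inclusive (SAM-style); BED export is 0-based half-open.

## Boundary segmentation

Read pairs whose template length deviates from the expected insert by more
than `n_sd` (default 1) standard deviations are classified deletion-like
(too large) or amplification-like (too small) and counted in 5 kb bins by
leftmost mate position, one count per proper pair. Since the tails of the
insert distribution are a fixed fraction of all pairs, these counts are a
copy-number proxy: entering a copy-0 or copy-1 deletion drops the
deletion-category count ratio to 0 or 0.5; entering a copy-3, 4, 5, …
amplification raises the amplification-category ratio to 1.5, 2, 2.5, …
(windows ±0.1, amplification centers extended as 1.5 + 0.5·m up to copy
state `max_copy_state` = 10). Ratios are oriented downstream/upstream; the
reciprocal is also tested (config, default on) so transitions *out* of an
event fire the same windows. A `min_boundary_count` floor (default 5 on the
larger of the two bins) suppresses ratios of tiny counts — invented
plumbing, not part of the published scheme. Junction-spanning pairs with
grossly inflated/deflated inserts additionally pile up in the flanking
bins, sharpening exactly the transitions of interest.

Boundaries detected in the matched normal are removed from the test set
when within ±100 nt, compared across categories (a germline breakpoint
suppresses a nearby somatic candidate of either category). Surviving
boundaries can snap call edges: each edge moves to the nearest boundary of
the *same* event polarity within `snap` (default 5000 nt = one boundary
bin); snaps that would invert an interval are rejected.

Two documented caveats. First, the ±0.1 ratio windows are narrow relative
to count noise (a ratio of two ~50-count bins has SD ≈ 0.3), so
amplification boundaries are detected stochastically at moderate coverage;
full deletions, whose ratio is exactly 0, are robust. Second, an
alternative reading of the count-ratio scheme — ratios of *total* read
counts against a neutral baseline — would support the same copy-state
mapping; the anomalous-count reading is implemented because it is the one
that needs no coverage normalization, and the module indeed applies none
(test and ref coverages may differ freely).

## Simulator

`simulate_events` packs non-overlapping events of uniform size within the
requested range until their total reaches the requested genome fraction
(realized total within one event size of the target), placed uniformly
with a minimum inter-event gap (default 10 kb) so neighboring truth events
cannot merge into one call during benchmarking; copy states are drawn
uniformly from {0, 1, 3, 4} unless specified. `simulate_depth_pair` draws
per-base depths: ref ~ Poisson(coverage) everywhere, test ~
Poisson(coverage·cn/2) inside events, independent across positions.
`simulate_read_pairs` builds a two-haplotype donor genome (copy number c
split ⌈c/2⌉/⌊c/2⌋; amplified segments tandem-repeated in place, deletions
removed), places pairs uniformly at the requested coverage with Gaussian
inserts (250 ± 50 by default, floored at 2·read_len), lifts both mates back
to reference coordinates, and writes minimal coordinate-sorted SAM. Reads
map at the reference position of their donor start with a full-length match
CIGAR; junction splitting within a read is not modeled — the anomalous
signal used downstream lives in the pair span, and split-read breakpointing
is deliberately out of scope.

What the depth simulator does *not* emulate: depth autocorrelation over the
read length (independent per-base draws carry ~√(bin_size/read_len) ≈ 2.6×
less binned noise than read-placement depth at bin 50/read 76 — and
read-level depth is further overdispersed by the shared randomness of read
starts), GC and mappability structure, duplicate reads, or tumor impurity.
Passing benchmarks on these profiles therefore demonstrates the pipeline's
correctness and its noise-free operating characteristics, not its
performance envelope on real low-coverage libraries; in particular the
low-coverage degradation seen with read-level simulation (size deviation
above ~24% at 2.5X) does not reproduce under per-base Poisson profiles,
where 2.5X is still comfortably inside the detectable regime — the
acceptance suite records the honest (small) value rather than the
read-level one. The breakpoint-margin matching rule itself caps the size
deviation of *matched* calls at 2× the margin (20% at the default 10%), a
structural ceiling worth keeping in mind when comparing deviation figures
across matching conventions.

Benchmark scores: sensitivity = % of truth events matched (one-to-one,
greedy by overlap, same kind, both breakpoints within margin × truth
length); false positives = % of *calls* matching nothing (the per-call
denominator is a documented choice; a per-truth denominator is equally
computable from the returned labels); size deviation =
|detected − simulated|/simulated × 100 averaged over matches. Interval
subtraction (test MINUS ref, for deriving somatic events from two
single-sample call sets) and base-level concordance |a∩b|/|a∪b| are exact
set operations on half-open intervals; concordance of two empty sets is
defined as 0 with a warning, and an optional minimum-support filter can
drop short intervals before comparison (off by default).

## Problem sizes

The shipped tests and the acceptance script use synthetic chromosomes of
0.1–25 Mb: 100 kb for the resolution check, 1 Mb for null calibration
(event-free 10X pair; < 1% of windows may reach P < 0.001, observed ~0),
5–10 Mb at 5–30X for recovery and coverage-saturation checks, and 25 Mb at
2.5X for the low-coverage benchmark. These sizes give hundreds of
thousands of bins — ample for the statistics exercised — while keeping a
full run in tens of seconds.

## Known limitations

- Tumor purity and subclonality are not modeled (see assumptions).
- The significance standardization is an interpretation (above); its
  operating point matches the documented P < 0.001 / |clr| > 4.77 cutoff.
- Amplification boundary detection is noise-limited by the ±0.1 windows.
- CRAM input, realignment, duplicate marking and GC correction are out of
  scope; the pair-wise ratio is the bias correction.
- Inter-chromosomal insertions are not simulated; amplifications are
  in-place tandem.
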