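# Methods

This document describes the models implemented in `allokaryo`, their
parameters (with units and defaults), the scope of the synthetic data
generator, and the numerical choices made. It makes no empirical claims
beyond what the test suite computes on simulated data.

## 1. Reference model and coverage windows

A *combined reference* concatenates one genome per donor species. Each
chromosome is addressed by a `(species_tag, chromosome)` slot; on disk the
two are joined as `tag-chrom` and split on the **first** hyphen (species
tags must not contain hyphens). A chromosome named `mt` is the
mitochondrial genome: it is excluded from the nuclear genome size and from
all nuclear per-chromosome calls.

Depth of coverage is summarized in non-overlapping windows of `window_size`
bp (default 10 000). Internally windows are 0-based half-open; per-base
input follows the 1-based `genomeCoverageBed -d` dialect, positions absent
from the input count as depth 0, and the final short window is averaged
over its actual length. Window tables round-trip through TSV bit-exactly
(`%.17g`).

## 2. Karyotype calling

**Depth per copy.** Two anchors are available:

- *Mass conservation* (preferred): `Σ(depth × window length) /
  genome_size_fcm`, where the genome size comes from flow cytometry. This
  resolves absolute ploidy.
- *Modal fallback*: the lowest substantial mode (≥ 25% of the maximum
  peak) of a Gaussian KDE over positive window means is taken as the
  single-copy depth. This fails by construction on uniform genomes — a
  pure diploid is indistinguishable from a haploid at twice the per-copy
  depth — so flow-cytometry anchoring should be used whenever available.

**Whole-chromosome copy number** is `round(median of non-zero window
means / depth_per_copy)`, rounding half away from zero, capped at 12
copies. A chromosome with ≥ 90% zero windows is called absent (0 copies);
scattered zeros in an otherwise covered chromosome are treated as
mappability dropout and excluded from the median.

**Arm-level unbalanced translocations** are found by exhaustive
single-changepoint search minimizing the two-segment squared error of
per-window copy estimates (prefix sums, O(n) per chromosome). Zero windows
are kept in the scan so a fully deleted arm is detectable. A call is
emitted only if the rounded segment copies differ, each segment spans at
least 20% of the chromosome (`min_arm_fraction=0.2`), and the one-segment
SSE exceeds the two-segment SSE by more than a factor 2
(`improvement_factor=2.0`). The breakpoint is reported as the start of the
first right-segment window.

**Copy-level convention for segmented chromosomes.** After a
translocation the chromosome's whole-copy level is defined as its
*majority (longer) arm* — this is what a coverage median reports and what
a cross passes on. The caller, the simulator and the aberration
accountant all use this convention.

## 3. Flow-cytometry ploidy

The G1 fluorescence peak is the KDE mode restricted below 1.5× the first
major peak (so an asynchronous G2 shoulder cannot capture it). The
sample/reference peak ratio is the mean copy number per chromosome slot,
and `ratio × haploid_genome_size` is the FCM genome size.

## 4. Genome metrics

- **Percent retention**: `Pspp = (Ct × Ws / Gs) × 100`, `Ct` counting
  windows with depth **strictly greater** than the threshold (default 2),
  mitochondrial windows excluded, clamped at 100%.
- **Genome size from karyotype**: `Σ copies × chromosome length`, with
  segmented chromosomes contributing per-segment.
- **Cassette copy ratio**: cassette mean depth divided by the host
  chromosome's median window depth; input longer than 10× the window size
  is treated as per-base depth and re-windowed (default window 3 900 bp).
  The side with ratio ≠ 1 is tested with the one-sided exact rank-sum
  test. An uncovered chromosome yields an `undefined` report.
- **Cell geometry**: projected area A maps to radius `r = √(A/π)` and
  spherical volume `(4/3)πr³`. The transform is per cell; because it is
  nonlinear, the volume of the mean area differs from the mean of
  per-cell volumes, and callers must choose the averaging order explicitly
  (the library does not average).

## 5. Pedigree aberration accounting

A hybrid's expected karyotype is the elementwise sum of its two parents'
observed karyotypes (whole-genome fusion, no meiosis); an evolved
isolate's expectation is its ancestor unchanged. Per slot, the
observed−expected difference counts one event per copy by default
(`per_chromosome=True` collapses multi-copy changes to one event). For a
chromosome carrying segment calls, the arm closest to the expected level
is used as its whole-chromosome level — the other arm's deviation is the
translocation itself, counted separately. A segment call is new unless a
parent carries a segment on the same chromosome with the same sign of arm
imbalance.

## 6. Mitotype classification

Per species, the covered fraction of the mt genome is the share of windows
with depth > 2. Fractions ≥ 0.9 mean the donor's molecule is fully
present; ≤ 0.1, absent. One full donor → homoplasmic (heteroplasmic if
several); otherwise, two partially covered donors whose covered blocks are
contiguous (gap tolerance 2 windows), sit at opposite ends, and have
complementary fractions (sum within `max(0.15, 2/n)` of 1) → recombinant;
anything else → incomplete.

## 7. Growth kinetics

μ (h⁻¹) is the steepest least-squares slope of ln(OD) over a sliding
window after background subtraction (blank-subtracted OD floored at
1e-4). The window length adapts to a coarse crossing-time rate estimate:
it spans ~1.5 doublings, capped at 30% of the curve's 5%–95% rise
duration and at n/3 points (minimum `window_points=5`). When the curve
has plateaued (terminal log-slope over the last ~10 points below 0.2 μ),
the winning slope is rescaled by `(1 − OD₀/K)/(1 − mean_window_OD/K)`
with `K` the maximum OD — a finite window averages the logistic
instantaneous slope `r(1 − OD/K)` over ODs above the inoculum, biasing μ
low. Curves still rising at the last timepoint are never adjusted, so an
exact exponential is recovered exactly.

## 8. Statistics

- **Rank-sum (one-sided)**: exact p by enumerating all assignments of
  average-tie ranks to the smaller group when total n ≤ 12 *or*
  `C(n, min(na, nb)) ≤ 200 000` (covers heavily unbalanced designs such
  as 3 cassette windows vs 100 chromosome windows); otherwise the normal
  approximation with continuity and tie corrections.
- **Spearman**: exact two-sided p over all n! permutations for n ≤ 8,
  t-approximation otherwise.
- **t-tests**: paired (df = n−1) and unpaired Welch.
- **Two-factor ANOVA**: `P ~ M * C` with sequential (type-I) sums of
  squares; a constant response reports F = 0, p = 1 for every term.
- **Linear regression**: OLS slope with its F-test p, plus r² and
  intercept.

## 9. Synthetic data generator

The generator is the package's test bed; its defaults are the study
conditions.

**Karyotype process.** Founders are euploid diploids of their own species.
At each cross (or evolution step) the base karyotype is the parental sum,
then events are drawn per slot: each copy is lost with `loss_rate`
(default 0.05), surviving slots gain copies with `gain_rate` (0.02,
duplicating present material only), and `transloc_rate` (0.01) creates an
unbalanced arm segment (breakpoint uniform in the middle 60%, one arm
±1 copy). Event rates are free parameters: the modeled experiments report
outcomes, not per-cross rates.

**Identifiability constraints.** Within one cross the three event types
are mutually exclusive per slot: gains skip slots that just lost, and
translocations skip slots that just gained or lost. Offsetting events
(e.g. a gain plus a −1 arm) are observationally identical to smaller
event sets in coverage data, so only exclusive events keep the event log
reconcilable with observed−expected accounting. Segments are **not
propagated** through crosses: a child inherits the majority-arm copy
level as whole chromosomes. Both are simplifications of the biology.

**Read-out models.**

- Coverage: window depth = level × `depth_per_copy` (15 per copy ⇒ 30×
  for a diploid) × lognormal(0, `noise_sigma`=0.2), with
  `mappability_dropout`=0.02 of windows zeroed; segment-aware.
- Mitochondria: homoplasmic molecules covered end-to-end; heteroplasmic
  donors share depth (`mt_bias`=0.8 toward the first parent);
  recombinants cover a prefix of one donor and the complementary suffix
  of the other.
- Flow cytometry: fluorescence = 1e-5 units/bp × genome size ×
  (1 + N(0, `fcm_cv`=0.05)).
- Growth: logistic with `r = μ/(1 − N₀/K)` so that the initial log-slope
  after the lag equals μ; inoculum defaults to K/20 (a realistic
  back-dilution), 15-minute cadence, additive OD noise
  (`od_noise_sd`=0.002) on top of a constant background.
- Cell areas: proportional to (genome ratio)^(2/3), lognormal scatter
  (`area_sigma`=0.1).

All draws come from `SeedSequence(seed, spawn_key=crc32(labels))`
substreams, so per-node results are independent of evaluation order and
fully reproducible from one integer seed.

**Scope and limits.** The generator produces window-level depth, not
reads: mappability, GC bias and repeat structure are reduced to a uniform
dropout probability. Translocation breakpoints are drawn at window
resolution for calling purposes; balanced translocations, segmental
amplifications smaller than an arm, and multi-changepoint chromosomes are
out of scope (the caller fits a single changepoint per chromosome).
Mitochondrial copy number is not modeled, only presence patterns.

## 10. Known limitations

- Absolute ploidy from depth alone is unidentifiable for uniform genomes;
  use the FCM anchor.
- One changepoint per chromosome; complex arm architectures collapse to
  their best single split or to a whole-chromosome call.
- The aberration accountant assumes the majority-arm convention; mixing
  karyotypes produced by other tools with different conventions will
  miscount translocated chromosomes.
- Exact tests switch to approximations outside their enumeration bounds
  (section 8); p-values across the boundary are not guaranteed to agree
  to machine precision.
- The growth-rate saturation correction assumes a logistic-shaped
  approach to a single plateau; diauxic or multi-phase curves get the
  uncorrected sliding-window estimate at best.
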