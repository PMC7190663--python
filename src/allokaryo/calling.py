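"""Copy-number calling from windowed coverage.

The depth signal over a hybrid genome is, per chromosome, approximately
(copy number) x (depth per one chromosome copy), corrupted by lognormal
window noise and mappability dropout (windows forced to zero).  Calling
proceeds in two steps:

1. estimate the per-copy depth, either from a flow-cytometry genome size
   (mass conservation: total covered mass / genome size) or, absent flow
   cytometry, as the lowest substantial mode of the positive window means;
2. per chromosome, the copy number is the median window depth (dropout
   zeros excluded) divided by the per-copy depth, rounded half away from
   zero, with an exhaustive single-changepoint scan flagging arm-level
   unbalanced translocations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator

from .karyotype import FLAG_ABSENT, FLAG_RECOMBINANT, FLAG_WHOLE, Karyotype, SegmentCall
from .reference import MT_CHROM_NAME, CombinedReference, WindowedCoverage

__all__ = [
    "PloidyEstimate",
    "FlowPloidyEstimator",
    "KaryotypeCaller",
    "estimate_depth_per_copy",
    "call_copy_numbers",
    "detect_unbalanced_translocations",
    "estimate_ploidy_fcm",
]


def _round_half_away(x: float) -> int:
    """Round half away from zero: 6.5 -> 7 (a chromosome showing ~6.5 copy
    units is read as 7)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class PloidyEstimate:
    """Flow-cytometry DNA content relative to a haploid reference.

    ``mean_copies`` is the average number of copies per chromosome slot
    (the base-ploidy n); ``genome_size_fcm`` the implied total genome size.
    """

    fluorescence_ratio: float
    mean_copies: float
    genome_size_fcm: float

    def __post_init__(self) -> None:
        if self.fluorescence_ratio <= 0:
            raise ValueError("fluorescence ratio must be positive")


def _kde_modes(values: np.ndarray, bandwidth=None, rel_height: float = 0.25):
    """Positions of local maxima of a Gaussian KDE, lowest first, keeping
    only peaks at least ``rel_height`` of the global maximum."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        # degenerate sample: single atom is its own mode
        return np.array([float(values[0])])
    kde = scipy.stats.gaussian_kde(values, bw_method=bandwidth)
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = grid[1:-1][interior & (dens[1:-1] >= rel_height * dens.max())]
    if peaks.size == 0:
        peaks = np.array([grid[np.argmax(dens)]])
    return peaks


def _g1_peak(values: np.ndarray, bandwidth=None) -> float:
    """G1 fluorescence peak: mode of the KDE restricted below 1.5x the first
    major peak (excludes the G2 population of an asynchronous sample)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty fluorescence sample")
    first = _kde_modes(values, bandwidth)[0]
    g1_pool = values[values < 1.5 * first]
    if g1_pool.size == 0:
        raise ValueError("no detectable G1 peak")
    return float(_kde_modes(g1_pool, bandwidth)[0])


def estimate_ploidy_fcm(
    sample_g1_values, reference_g1_values, haploid_genome_size: float,
    bandwidth=None,
) -> PloidyEstimate:
    """Calibrate DNA content against a haploid laboratory reference.

    The G1 peak of each sample is located by kernel density; the ratio of
    sample to reference peaks is the mean copy number per chromosome slot,
    and times the haploid genome size gives the flow-cytometry genome size.
    """
    sample_peak = _g1_peak(np.asarray(sample_g1_values, float), bandwidth)
    ref_peak = _g1_peak(np.asarray(reference_g1_values, float), bandwidth)
    if ref_peak <= 0:
        raise ValueError("reference G1 peak is non-positive")
    ratio = sample_peak / ref_peak
    return PloidyEstimate(
        fluorescence_ratio=ratio,
        mean_copies=ratio,
        genome_size_fcm=ratio * haploid_genome_size,
    )


class FlowPloidyEstimator(BaseEstimator):
    """Flow-cytometry ploidy calibrator in estimator form.

    ``fit`` learns the haploid reference G1 peak; ``predict`` maps sample G1
    fluorescence values to a :class:`PloidyEstimate`.
    """

    def __init__(self, haploid_genome_size: float = 12_000_000.0, bandwidth=None):
        self.haploid_genome_size = haploid_genome_size
        self.bandwidth = bandwidth

    def fit(self, reference_g1_values, y=None) -> "FlowPloidyEstimator":
        self.reference_peak_ = _g1_peak(
            np.asarray(reference_g1_values, float), self.bandwidth
        )
        return self

    def predict(self, sample_g1_values) -> PloidyEstimate:
        sample_peak = _g1_peak(np.asarray(sample_g1_values, float), self.bandwidth)
        ratio = sample_peak / self.reference_peak_
        return PloidyEstimate(ratio, ratio, ratio * self.haploid_genome_size)


# ---------------------------------------------------------------------------
# Depth-per-copy and copy-number calling


def estimate_depth_per_copy(
    coverage: WindowedCoverage,
    ploidy_estimate: PloidyEstimate | None,
    reference: CombinedReference,
    bandwidth=None,
) -> float:
    """Depth corresponding to one chromosome copy.

    With a flow-cytometry genome size: total nuclear covered mass divided by
    that genome size (mass conservation).  Without: the lowest substantial
    mode of the positive window means, read as the 1-copy depth level.
    """
    nuclear = coverage.records[coverage.records["chromosome"] != MT_CHROM_NAME]
    depths = nuclear["depth"].to_numpy(dtype=float)
    if depths.size == 0 or np.all(depths == 0):
        raise ValueError("all-zero coverage: cannot estimate depth per copy")
    if ploidy_estimate is not None:
        if ploidy_estimate.genome_size_fcm <= 0:
            raise ValueError("non-positive flow-cytometry genome size")
        mass = float(
            np.sum(depths * (nuclear["end"] - nuclear["start"]).to_numpy(float))
        )
        return mass / ploidy_estimate.genome_size_fcm
    positive = depths[depths > 0]
    return float(_kde_modes(positive, bandwidth)[0])


def _two_segment_sse(copies: np.ndarray):
    """Best single changepoint of a 1-D signal by exhaustive scan.

    Returns (k, sse2, sse1): split index (left = [:k]), its two-segment SSE,
    and the one-segment SSE.  Prefix sums keep the scan O(n)."""
    n = copies.size
    s = np.concatenate([[0.0], np.cumsum(copies)])
    s2 = np.concatenate([[0.0], np.cumsum(copies**2)])

    def sse(i, j):  # SSE of copies[i:j] around its own mean
        m = j - i
        tot = s[j] - s[i]
        return (s2[j] - s2[i]) - tot * tot / m

    sse1 = sse(0, n)
    best_k, best = 1, math.inf
    for k in range(1, n):
        cur = sse(0, k) + sse(k, n)
        if cur < best:
            best, best_k = cur, k
    return best_k, best, sse1


def detect_unbalanced_translocations(
    coverage: WindowedCoverage,
    species: str,
    chromosome: str,
    depth_per_copy: float,
    min_windows: int = 10,
    min_arm_fraction: float = 0.2,
    improvement_factor: float = 2.0,
    sse_epsilon: float = 1e-9,
) -> SegmentCall | None:
    """Arm-level unbalanced translocation scan for one chromosome.

    Exhaustive single-changepoint search minimizing the two-segment squared
    error of per-window copy estimates.  Zero windows are kept in the scan
    so that a fully deleted arm (a 0-copy segment) is detectable; scattered
    mappability dropout does not produce calls because the rounded segment
    copies must differ.  A call is emitted only when the rounded segment
    copies differ, each segment spans at least ``min_arm_fraction`` of the
    chromosome, and the two-segment fit reduces the squared error by more
    than ``improvement_factor``.
    """
    win = coverage.chromosome(species, chromosome)
    if len(win) < min_windows:
        return None
    depths = win["depth"].to_numpy(dtype=float)
    if (depths > 0).sum() < min_windows:
        return None  # absent or nearly-absent chromosome: a loss, not an arm event
    copies = depths / depth_per_copy
    starts = win["start"].to_numpy(dtype=np.int64)
    length = int(win["end"].max())

    k, sse2, sse1 = _two_segment_sse(copies)
    if sse1 <= sse_epsilon:
        return None  # flat signal
    if sse2 > sse_epsilon and sse1 / sse2 <= improvement_factor:
        return None
    left = _round_half_away(float(copies[:k].mean()))
    right = _round_half_away(float(copies[k:].mean()))
    if left == right:
        return None
    breakpoint = int(starts[k])
    if breakpoint < min_arm_fraction * length or (length - breakpoint) < (
        min_arm_fraction * length
    ):
        return None
    return SegmentCall(
        species=species,
        chromosome=chromosome,
        breakpoint=breakpoint,
        left_copies=left,
        right_copies=right,
    )


def call_copy_numbers(
    coverage: WindowedCoverage,
    depth_per_copy: float,
    reference: CombinedReference,
    max_copies: int = 12,
    absent_fraction: float = 0.9,
    detect_segments: bool = True,
    min_arm_fraction: float = 0.2,
    improvement_factor: float = 2.0,
) -> Karyotype:
    """Integer copy number for every nuclear (species, chromosome) slot.

    Per chromosome the call is round(median of the non-zero window means /
    depth_per_copy), half rounded away from zero and capped at
    ``max_copies``.  A chromosome with at least ``absent_fraction`` zero
    windows is called 0 copies (flag ``absent``); zeros in an otherwise
    covered chromosome are treated as mappability dropout and excluded from
    the median.
    """
    if depth_per_copy <= 0:
        raise ValueError("depth_per_copy must be positive")
    copies: dict[tuple[str, str], int] = {}
    flags: dict[tuple[str, str], str] = {}
    segments: list[SegmentCall] = []
    for tag, chrom in reference.nuclear_slots():
        depths = coverage.depths(tag, chrom)
        if depths.size == 0:
            raise ValueError(f"{tag}-{chrom}: no coverage windows")
        zero_frac = float(np.mean(depths == 0))
        if zero_frac >= absent_fraction:
            copies[(tag, chrom)] = 0
            flags[(tag, chrom)] = FLAG_ABSENT
            continue
        med = float(np.median(depths[depths > 0]))
        c = min(_round_half_away(med / depth_per_copy), max_copies)
        copies[(tag, chrom)] = c
        flags[(tag, chrom)] = FLAG_WHOLE
        if detect_segments:
            seg = detect_unbalanced_translocations(
                coverage,
                tag,
                chrom,
                depth_per_copy,
                min_arm_fraction=min_arm_fraction,
                improvement_factor=improvement_factor,
            )
            if seg is not None:
                segments.append(seg)
                flags[(tag, chrom)] = FLAG_RECOMBINANT
                # the whole-chromosome level of a segmented chromosome is
                # its majority arm (matching what crosses propagate)
                length = reference.chrom_length(tag, chrom)
                arm = (
                    seg.left_copies
                    if seg.breakpoint >= length - seg.breakpoint
                    else seg.right_copies
                )
                copies[(tag, chrom)] = min(arm, max_copies)
    return Karyotype(copies=copies, segments=segments, flags=flags)


class KaryotypeCaller(BaseEstimator):
    """End-to-end karyotype caller over a combined multi-species reference.

    ``fit`` estimates the per-copy depth from a coverage table (optionally
    anchored to a flow-cytometry ploidy estimate); ``predict`` returns the
    full :class:`~allokaryo.karyotype.Karyotype` including arm-level
    unbalanced-translocation calls.

    Parameters
    ----------
    reference : CombinedReference
        The combined reference the coverage is windowed over.
    max_copies : int
        Cap on called copies per chromosome (default 12, the design base
        ploidy of a six-species double-diploid stack).
    absent_fraction : float
        Fraction of zero windows at which a chromosome is declared absent.
    min_arm_fraction : float
        Minimum span of each segment of an unbalanced-translocation call,
        as a fraction of chromosome length.
    improvement_factor : float
        Required one-segment/two-segment SSE ratio for a changepoint call.
    kde_bandwidth : float or None
        Bandwidth factor for the depth-mode and G1-peak kernel densities.
    """

    def __init__(
        self,
        reference: CombinedReference = None,
        max_copies: int = 12,
        absent_fraction: float = 0.9,
        min_arm_fraction: float = 0.2,
        improvement_factor: float = 2.0,
        kde_bandwidth=None,
    ):
        self.reference = reference
        self.max_copies = max_copies
        self.absent_fraction = absent_fraction
        self.min_arm_fraction = min_arm_fraction
        self.improvement_factor = improvement_factor
        self.kde_bandwidth = kde_bandwidth

    def fit(
        self,
        coverage: WindowedCoverage,
        y=None,
        ploidy_estimate: PloidyEstimate | None = None,
    ) -> "KaryotypeCaller":
        if self.reference is None:
            raise ValueError("KaryotypeCaller requires a reference")
        self.depth_per_copy_ = estimate_depth_per_copy(
            coverage, ploidy_estimate, self.reference, self.kde_bandwidth
        )
        return self

    def predict(self, coverage: WindowedCoverage) -> Karyotype:
        return call_copy_numbers(
            coverage,
            self.depth_per_copy_,
            self.reference,
            max_copies=self.max_copies,
            absent_fraction=self.absent_fraction,
            min_arm_fraction=self.min_arm_fraction,
            improvement_factor=self.improvement_factor,
        )

    def fit_predict(
        self,
        coverage: WindowedCoverage,
        ploidy_estimate: PloidyEstimate | None = None,
    ) -> Karyotype:
        return self.fit(coverage, ploidy_estimate=ploidy_estimate).predict(coverage)
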