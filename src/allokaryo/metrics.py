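"""Genome retention, genome size, cassette copy-ratio test, cell geometry.

Retention of a parent genome in a hybrid is quantified directly from the
windowed coverage: Pspp = (Ct x Ws / Gs) x 100, where Ct is the number of
that species' windows with mean depth above the cutoff (default 2), Ws the
window size and Gs the species' nuclear reference size.  Presence is
reported, not copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .karyotype import Karyotype
from .reference import MT_CHROM_NAME, CombinedReference, WindowedCoverage
from .stats import StatResult, rank_sum_one_sided

__all__ = [
    "RetentionRecord",
    "CassetteReport",
    "CellMeasure",
    "percent_retention",
    "genome_size_from_karyotype",
    "cassette_copy_ratio",
    "cell_volume_from_area",
]


@dataclass
class RetentionRecord:
    species: str
    pspp: float  # percent of the parent genome detected, in [0, 100]
    ct: int  # windows above threshold
    threshold: float
    retained_bp: float

    def __post_init__(self) -> None:
        if not 0 <= self.pspp <= 100:
            raise ValueError("Pspp outside [0, 100]")


def percent_retention(
    coverage: WindowedCoverage,
    species: str,
    reference: CombinedReference,
    threshold: float = 2.0,
) -> RetentionRecord:
    """Percent of one parent species' nuclear genome detected in a hybrid.

    Ct counts windows with mean depth strictly greater than ``threshold``;
    Pspp = (Ct x Ws / Gs) x 100, clamped at 100 (the final short window of
    each chromosome can push the product past the genome size).
    """
    sp = reference.get_species(species)  # raises KeyError for unknown species
    rec = coverage.records
    mask = (rec["species"] == species) & (rec["chromosome"] != MT_CHROM_NAME)
    depths = rec.loc[mask, "depth"].to_numpy(dtype=float)
    ct = int(np.sum(depths > threshold))
    gs = sp.genome_size
    pspp = min(100.0, 100.0 * ct * reference.window_size / gs)
    return RetentionRecord(
        species=species,
        pspp=pspp,
        ct=ct,
        threshold=threshold,
        retained_bp=pspp / 100.0 * gs,
    )


def genome_size_from_karyotype(
    karyotype: Karyotype, reference: CombinedReference
) -> float:
    """Total genome size in bp: copies x length summed over every nuclear
    slot; chromosomes with an arm-level segment call contribute each
    segment's length x its own copy number."""
    total = 0.0
    for tag, chrom in reference.nuclear_slots():
        length = reference.chrom_length(tag, chrom)
        seg = karyotype.segment_for(tag, chrom)
        if seg is None:
            total += karyotype.get(tag, chrom) * length
        else:
            total += seg.left_copies * seg.breakpoint
            total += seg.right_copies * (length - seg.breakpoint)
    return total


@dataclass
class CassetteReport:
    """Copy-ratio test of an engineered cassette against its host chromosome.

    The cassette's mean depth is compared with the distribution of host-
    chromosome window means at the cassette's own window size; under a 1:1
    copy ratio the cassette behaves like one more chromosome window.
    """

    cassette_mean_depth: float
    chromosome_window_depths: np.ndarray
    ratio: float | None
    p_value: float | None
    n_windows: int
    undefined: bool = False
    test: StatResult | None = None


def _window_means(per_base: np.ndarray, window: int) -> np.ndarray:
    """Means over consecutive fixed-size windows; the final short window is
    averaged over its actual length."""
    n = per_base.size
    n_win = -(-n // window)
    sums = np.add.reduceat(per_base, np.arange(0, n, window))
    lengths = np.diff(np.append(np.arange(0, n, window), n))
    assert len(sums) == n_win
    return sums / lengths


def cassette_copy_ratio(
    cassette_depths,
    chromosome_depth,
    cassette_window: int = 3900,
) -> CassetteReport:
    """Test the cassette : host-chromosome copy ratio against 1:1.

    ``cassette_depths`` are the cassette's window mean depths (one or more
    values); ``chromosome_depth`` is either the host chromosome's per-base
    depth (re-windowed here at ``cassette_window`` bp) or a pre-computed
    vector of window means at that size.  The ratio is cassette mean over
    chromosome median, and the p-value a one-sided Wilcoxon rank-sum test in
    the direction the ratio deviates.
    """
    cassette = np.asarray(cassette_depths, dtype=float)
    if cassette.size < 1:
        raise ValueError("need at least one cassette depth value")
    chrom = np.asarray(chromosome_depth, dtype=float)
    if chrom.size > 10 * cassette_window:  # heuristically per-base input
        chrom_windows = _window_means(chrom, cassette_window)
    else:
        chrom_windows = chrom
    if chrom_windows.size < 5:
        raise ValueError("need at least 5 host-chromosome windows")
    if np.all(chrom_windows == 0):
        return CassetteReport(
            cassette_mean_depth=float(cassette.mean()),
            chromosome_window_depths=chrom_windows,
            ratio=None,
            p_value=None,
            n_windows=chrom_windows.size,
            undefined=True,
        )
    ratio = float(cassette.mean() / np.median(chrom_windows))
    side = "greater" if ratio >= 1 else "less"
    res = rank_sum_one_sided(cassette, chrom_windows, alternative=side)
    return CassetteReport(
        cassette_mean_depth=float(cassette.mean()),
        chromosome_window_depths=chrom_windows,
        ratio=ratio,
        p_value=res.p_value,
        n_windows=chrom_windows.size,
        test=res,
    )


@dataclass
class CellMeasure:
    """Spherical-cell geometry from a projected area measurement."""

    area: float  # um^2
    radius: float  # um
    volume: float  # um^3


def cell_volume_from_area(area: float) -> CellMeasure:
    """Sphere volume implied by a projected cell area: r = sqrt(A/pi),
    V = (4/3) pi r^3."""
    if area < 0:
        raise ValueError("area must be non-negative")
    r = math.sqrt(area / math.pi)
    v = 4.0 / 3.0 * math.pi * r**3
    return CellMeasure(area=float(area), radius=r, volume=v)
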