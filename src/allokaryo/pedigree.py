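"""Pedigree-aware aberration accounting and mitotype classification.

A hybrid's *expected* karyotype is the elementwise sum of its parents'
observed karyotypes (whole-genome fusion: the crossing scheme mates whole
diploids, no meiosis intervenes); an evolved isolate's expectation is its
ancestor's karyotype unchanged.  New aberrations at a node are the
differences between observed and expected, so events arising in an earlier
cross and merely inherited are never counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .karyotype import Karyotype
from .reference import MT_CHROM_NAME, CombinedReference, Pedigree, WindowedCoverage

__all__ = [
    "AberrationReport",
    "MitotypeCall",
    "MitotypeClassifier",
    "expected_karyotype",
    "count_new_aberrations",
    "classify_mitotype",
    "pedigree_aberration_table",
]


@dataclass
class AberrationReport:
    """New chromosomal aberrations at one pedigree node.

    By default each chromosome-copy difference is one event (losing two
    copies of a chromosome counts as two losses), which makes counts
    additive over a pedigree; ``per_chromosome=True`` collapses multi-copy
    differences on one chromosome to a single event.
    """

    node: str
    gains: int
    losses: int
    unbalanced_translocations: int

    @property
    def total_new(self) -> int:
        return self.gains + self.losses + self.unbalanced_translocations


def expected_karyotype(parent_karyotypes: list[Karyotype]) -> Karyotype:
    """Elementwise sum of 1 or 2 parental karyotypes (a single ancestor
    yields an identical expectation)."""
    if not parent_karyotypes or len(parent_karyotypes) > 2:
        raise ValueError("expected 1 or 2 parent karyotypes")
    return Karyotype.from_sum(parent_karyotypes)


def _segment_is_new(seg, parents: list[Karyotype]) -> bool:
    """A segment call is inherited (not new) when some parent carries a
    segment on the same chromosome with the same sign of arm imbalance."""
    sign = np.sign(seg.right_copies - seg.left_copies)
    for p in parents:
        for ps in p.segments:
            if (
                ps.species == seg.species
                and ps.chromosome == seg.chromosome
                and np.sign(ps.right_copies - ps.left_copies) == sign
            ):
                return False
    return True


def count_new_aberrations(
    observed: Karyotype,
    expected: Karyotype,
    node: str = "",
    parents: list[Karyotype] | None = None,
    per_chromosome: bool = False,
) -> AberrationReport:
    """Count gains, losses and new unbalanced translocations at one node.

    Losses and gains are per-slot differences between expected and observed
    copy numbers; a translocation is counted when the observed karyotype
    carries a segment call not present in any parent.
    """
    slots = set(observed.copies) | set(expected.copies)
    seg_arms: dict[tuple[str, str], set[int]] = {}
    for seg in observed.segments:
        seg_arms.setdefault((seg.species, seg.chromosome), set()).update(
            (seg.left_copies, seg.right_copies)
        )
    gains = losses = 0
    for slot in slots:
        obs_c = observed.copies.get(slot, 0)
        exp_c = expected.copies.get(slot, 0)
        if slot in seg_arms:
            # a translocated chromosome has two arm levels; its whole-
            # chromosome level is the arm closest to expectation (the other
            # arm's deviation is the translocation itself, counted below).
            # This makes the count independent of whether copies were stored
            # as the pre-translocation base or the majority arm.
            obs_c = min(seg_arms[slot] | {obs_c}, key=lambda c: abs(c - exp_c))
        diff = obs_c - exp_c
        if diff > 0:
            gains += 1 if per_chromosome else diff
        elif diff < 0:
            losses += 1 if per_chromosome else -diff
    parent_list = parents if parents is not None else []
    translocs = sum(1 for seg in observed.segments if _segment_is_new(seg, parent_list))
    return AberrationReport(
        node=node, gains=gains, losses=losses, unbalanced_translocations=translocs
    )


def pedigree_aberration_table(
    pedigree: Pedigree,
    karyotypes: dict[str, Karyotype],
    per_chromosome: bool = False,
) -> list[AberrationReport]:
    """Aberration reports for every non-founder node of a pedigree, each
    against the sum of its parents' observed karyotypes."""
    reports = []
    for node in pedigree.topological_order():
        if pedigree.roles[node] == "founder":
            continue
        parents = [karyotypes[p] for p in pedigree.parents[node]]
        reports.append(
            count_new_aberrations(
                karyotypes[node],
                expected_karyotype(parents),
                node=node,
                parents=parents,
                per_chromosome=per_chromosome,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Mitotype classification


@dataclass
class MitotypeCall:
    """Mitochondrial inheritance call from mt coverage.

    ``covered_fraction`` maps each species' mt genome to the proportion of
    its windows above the depth cutoff.  Classes: homoplasmic (one donor
    fully covered), heteroplasmic (two or more fully covered), recombinant
    (two complementary contiguous blocks), incomplete (partial coverage not
    explained by recombination), none.
    """

    covered_fraction: dict[str, float]
    kind: str
    donors: list[str] = field(default_factory=list)


def _covered_block(covered: np.ndarray, gap_tolerance: int = 2):
    """(is_contiguous, first, last) for a boolean coverage vector, tolerating
    internal gaps of up to ``gap_tolerance`` windows (mappability holes)."""
    idx = np.nonzero(covered)[0]
    if idx.size == 0:
        return False, -1, -1
    gaps = np.diff(idx)
    return bool(np.all(gaps <= gap_tolerance + 1)), int(idx[0]), int(idx[-1])


class MitotypeClassifier(BaseEstimator):
    """Threshold classifier of mitochondrial inheritance from mt coverage.

    Parameters
    ----------
    full_threshold, absent_threshold : float
        Covered-fraction cutoffs: at or above ``full_threshold`` a species'
        mt genome counts as fully present; at or below ``absent_threshold``
        as absent; strictly between, as a recombination candidate.
    depth_threshold : float
        Window mean depth above which a window counts as covered (same
        cutoff as the nuclear retention metric).
    gap_tolerance : int
        Internal gaps of up to this many windows do not break contiguity.
    """

    def __init__(
        self,
        full_threshold: float = 0.9,
        absent_threshold: float = 0.1,
        depth_threshold: float = 2.0,
        gap_tolerance: int = 2,
    ):
        self.full_threshold = full_threshold
        self.absent_threshold = absent_threshold
        self.depth_threshold = depth_threshold
        self.gap_tolerance = gap_tolerance

    def fit(self, X=None, y=None) -> "MitotypeClassifier":
        return self  # thresholds are fixed hyperparameters

    def predict(
        self, mt_coverage: WindowedCoverage, reference: CombinedReference
    ) -> MitotypeCall:
        mt_species = [sp.tag for sp in reference.species if sp.mt_length is not None]
        if not mt_species:
            raise ValueError("reference has no mitochondrial genomes")
        covered_vec: dict[str, np.ndarray] = {}
        fractions: dict[str, float] = {}
        for tag in mt_species:
            depths = mt_coverage.depths(tag, MT_CHROM_NAME)
            vec = depths > self.depth_threshold
            covered_vec[tag] = vec
            fractions[tag] = float(vec.mean()) if vec.size else 0.0

        full = [t for t, f in fractions.items() if f >= self.full_threshold]
        absent = [t for t, f in fractions.items() if f <= self.absent_threshold]
        partial = [t for t in mt_species if t not in full and t not in absent]

        if not full and not partial:
            return MitotypeCall(fractions, "none")
        if partial:
            kind = self._recombinant_or_incomplete(partial, full, covered_vec, fractions)
            donors = sorted(partial + full, key=lambda t: -fractions[t])
            return MitotypeCall(fractions, kind, donors)
        if len(full) == 1:
            return MitotypeCall(fractions, "homoplasmic", full)
        return MitotypeCall(fractions, "heteroplasmic", sorted(full))

    def _recombinant_or_incomplete(self, partial, full, covered_vec, fractions):
        # recombinant: a partially covered molecule forms one contiguous
        # block and a second species covers a complementary contiguous block
        for a in partial:
            ok_a, first_a, last_a = _covered_block(covered_vec[a], self.gap_tolerance)
            if not ok_a:
                continue
            n_a = covered_vec[a].size
            a_prefix = first_a <= self.gap_tolerance
            a_suffix = last_a >= n_a - 1 - self.gap_tolerance
            for b in partial + full:
                if b == a:
                    continue
                ok_b, first_b, last_b = _covered_block(
                    covered_vec[b], self.gap_tolerance
                )
                if not ok_b:
                    continue
                n_b = covered_vec[b].size
                b_prefix = first_b <= self.gap_tolerance
                b_suffix = last_b >= n_b - 1 - self.gap_tolerance
                opposite_ends = (a_prefix and b_suffix) or (a_suffix and b_prefix)
                complementary = abs(fractions[a] + fractions[b] - 1.0) <= max(
                    0.15, 2.0 / max(n_a, 1)
                )
                if opposite_ends and complementary:
                    return "recombinant"
        return "incomplete"


def classify_mitotype(
    mt_coverage: WindowedCoverage,
    reference: CombinedReference,
    full_thr: float = 0.9,
    absent_thr: float = 0.1,
    depth_threshold: float = 2.0,
) -> MitotypeCall:
    """Classify mitochondrial inheritance; see :class:`MitotypeClassifier`."""
    clf = MitotypeClassifier(
        full_threshold=full_thr,
        absent_threshold=absent_thr,
        depth_threshold=depth_threshold,
    )
    return clf.fit().predict(mt_coverage, reference)
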