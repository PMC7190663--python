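"""Synthetic allopolyploid cohorts with known ground truth.

The generator walks a crossing pedigree: founders are euploid diploids of
one species each; a hybrid child starts from the elementwise sum of its
parents' karyotypes (whole-genome fusion, no meiosis) and then suffers
stochastic per-copy chromosome losses, per-copy gains, and per-chromosome
arm-level unbalanced translocations; an evolved isolate applies one round
of the same event process to its ancestor.  Every event is logged, so the
downstream caller and aberration accountant can be checked against truth.

From each node's true karyotype the generator emits the observables the
real study measured: windowed nuclear coverage (lognormal window noise,
mappability dropout), mitochondrial coverage reflecting homoplasmic /
heteroplasmic / recombinant inheritance, G1 fluorescence proportional to
DNA content, logistic OD growth curves, and cell areas scaling with genome
size to the 2/3 power (spherical cells, volume proportional to DNA).

Reproducibility: every node draws from its own PRNG substream derived from
(seed, node id, stream label), so outputs are independent of traversal
order and identical for identical seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .karyotype import Karyotype, SegmentCall
from .kinetics import GrowthCurve
from .reference import MT_CHROM_NAME, CombinedReference, Pedigree, WindowedCoverage

__all__ = [
    "SimParams",
    "MtState",
    "GroundTruth",
    "simulate_pedigree_karyotypes",
    "simulate_coverage",
    "simulate_mt_coverage",
    "simulate_fcm",
    "simulate_fcm_reference",
    "simulate_growth_curve",
    "simulate_cell_areas",
]


@dataclass
class SimParams:
    """Generator knobs; rates are per chromosome copy (loss, gain) or per
    chromosome (translocation) per cross.

    The study reports outcomes, not per-cross rates, so the event rates are
    free parameters: the defaults give an expected handful of new events per
    cross of high-ploidy hybrids, losses outnumbering gains, and occasional
    heteroplasmy — the qualitative regime the downstream analyses face.
    """

    depth_per_copy: float = 15.0  # 30x over a euploid diploid founder
    noise_sigma: float = 0.2  # lognormal sd of window depth
    mappability_dropout: float = 0.02  # fraction of windows forced to 0
    loss_rate: float = 0.05
    gain_rate: float = 0.02
    transloc_rate: float = 0.01
    heteroplasmy_prob: float = 0.05
    mt_bias: float = 0.8  # probability the first parent's mitotype fixes
    mt_recomb_prob: float = 0.0
    fcm_cv: float = 0.05  # fluorescence coefficient of variation
    od_noise_sd: float = 0.002
    area_sigma: float = 0.1  # lognormal sd of cell areas
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mappability_dropout",
            "loss_rate",
            "gain_rate",
            "transloc_rate",
            "heteroplasmy_prob",
            "mt_bias",
            "mt_recomb_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth_per_copy <= 0:
            raise ValueError("depth_per_copy must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


FCM_UNITS_PER_BP = 1e-5  # arbitrary fluorescence scale


def _rng(params: SimParams, *labels) -> np.random.Generator:
    """PRNG substream keyed on (seed, labels); independent of call order."""
    key = tuple(zlib.crc32(str(x).encode()) for x in labels)
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=key))


@dataclass(frozen=True)
class MtState:
    """Mitochondrial inheritance state: donor species and, for a
    recombinant molecule, the fractional breakpoint (donor A covers
    [0, f), donor B the complement)."""

    donors: tuple[str, ...]
    breakpoint_fraction: float | None = None

    @property
    def kind(self) -> str:
        if not self.donors:
            return "none"
        if self.breakpoint_fraction is not None:
            return "recombinant"
        return "homoplasmic" if len(self.donors) == 1 else "heteroplasmic"


@dataclass
class GroundTruth:
    """Per-node true karyotypes, mitochondrial states and the event log."""

    karyotypes: dict[str, Karyotype]
    mt_states: dict[str, MtState]
    event_log: dict[str, dict[str, list]]

    def event_totals(self, node: str) -> dict[str, int]:
        log = self.event_log[node]
        return {
            "losses": len(log["losses"]),
            "gains": len(log["gains"]),
            "translocations": len(log["translocations"]),
        }


def _apply_events(
    base: Karyotype, reference: CombinedReference, params: SimParams, rng
) -> tuple[Karyotype, dict[str, list]]:
    """One round of loss -> gain -> translocation on a base karyotype."""
    copies = dict(base.copies)
    log: dict[str, list] = {"losses": [], "gains": [], "translocations": []}
    slots = reference.nuclear_slots()
    lost_here: set = set()
    for slot in slots:  # losses: each present copy lost independently
        c = copies.get(slot, 0)
        if c > 0 and params.loss_rate > 0:
            n_lost = int(rng.binomial(c, params.loss_rate))
            copies[slot] = c - n_lost
            log["losses"].extend([slot] * n_lost)
            if n_lost:
                lost_here.add(slot)
    gained_here: set = set()
    for slot in slots:  # gains duplicate existing material only; a
        # chromosome never both loses and gains within one cross (only the
        # net change is identifiable from coverage anyway)
        c = copies.get(slot, 0)
        if c > 0 and params.gain_rate > 0 and slot not in lost_here:
            n_gain = int(rng.binomial(c, params.gain_rate))
            copies[slot] = c + n_gain
            log["gains"].extend([slot] * n_gain)
            if n_gain:
                gained_here.add(slot)
    segments: list[SegmentCall] = []
    for slot in slots:
        # translocations skip chromosomes that gained or lost this cross:
        # a gain plus a -1-arm segment is indistinguishable in coverage from
        # a +1-arm segment alone, so only exclusive events are identifiable
        if slot in lost_here or slot in gained_here:
            continue
        c = copies.get(slot, 0)
        if c > 0 and params.transloc_rate > 0 and rng.random() < params.transloc_rate:
            tag, chrom = slot
            length = reference.chrom_length(tag, chrom)
            # breakpoint uniform in the middle 60% of the chromosome
            bp = int(rng.uniform(0.2, 0.8) * length)
            delta = 1 if rng.random() < 0.5 else -1
            if c + delta < 0:
                delta = 1
            arm_left = rng.random() < 0.5
            seg = SegmentCall(
                species=tag,
                chromosome=chrom,
                breakpoint=bp,
                left_copies=c + delta if arm_left else c,
                right_copies=c if arm_left else c + delta,
            )
            segments.append(seg)
            log["translocations"].append(seg)
            # the chromosome's whole-copy level is the majority arm: that is
            # what a coverage median reports and what a cross passes on
            # (segments themselves are not propagated through crosses)
            copies[slot] = (
                seg.left_copies if bp >= length - bp else seg.right_copies
            )
    kar = Karyotype(copies=copies, segments=segments)
    return kar, log


def _inherit_mt(
    parent_states: list[MtState], params: SimParams, rng
) -> MtState:
    pool: list[str] = []
    for st in parent_states:
        pool.extend(st.donors)
    pool = list(dict.fromkeys(pool))  # unique, order-preserving
    if not pool:
        return MtState(donors=())
    if len(pool) == 1:
        return MtState(donors=(pool[0],))
    if rng.random() < params.heteroplasmy_prob:
        return MtState(donors=tuple(pool[:2]))
    if params.mt_recomb_prob > 0 and rng.random() < params.mt_recomb_prob:
        return MtState(
            donors=tuple(pool[:2]), breakpoint_fraction=float(rng.uniform(0.2, 0.8))
        )
    # biased fixation: the first parent's mitotype tends to win
    winner = pool[0] if rng.random() < params.mt_bias else pool[1]
    return MtState(donors=(winner,))


def simulate_pedigree_karyotypes(
    pedigree: Pedigree,
    reference: CombinedReference,
    params: SimParams,
    founder_species: dict[str, str] | None = None,
) -> GroundTruth:
    """Walk the pedigree and generate every node's true karyotype.

    Founders are euploid diploids; by default a founder node's id must equal
    its species tag (override with ``founder_species``).  Hybrid children
    sum their parents' karyotypes, evolved isolates copy their ancestor;
    both then receive one stochastic round of losses, gains and arm-level
    translocations from a substream keyed on (seed, node id).
    """
    founder_species = founder_species or {}
    karyotypes: dict[str, Karyotype] = {}
    mt_states: dict[str, MtState] = {}
    event_log: dict[str, dict[str, list]] = {}
    for node in pedigree.topological_order():
        role = pedigree.roles[node]
        if role == "founder":
            tag = founder_species.get(node, node)
            if tag not in reference.tags:
                raise ValueError(
                    f"founder {node!r} does not map to a reference species"
                )
            karyotypes[node] = Karyotype.euploid(reference, tag, ploidy=2)
            mt_states[node] = MtState(donors=(tag,))
            event_log[node] = {"losses": [], "gains": [], "translocations": []}
            continue
        parents = list(pedigree.parents[node])
        base = Karyotype.from_sum([karyotypes[p] for p in parents])
        rng = _rng(params, node, "karyotype")
        kar, log = _apply_events(base, reference, params, rng)
        karyotypes[node] = kar
        event_log[node] = log
        mt_states[node] = _inherit_mt(
            [mt_states[p] for p in parents], params, _rng(params, node, "mt")
        )
    return GroundTruth(karyotypes=karyotypes, mt_states=mt_states, event_log=event_log)


def _window_frame(reference, tag, chrom, depths):
    bounds = reference.window_bounds(tag, chrom)
    return pd.DataFrame(
        {
            "species": tag,
            "chromosome": chrom,
            "start": bounds[:, 0],
            "end": bounds[:, 1],
            "depth": depths,
        }
    )


def simulate_coverage(
    karyotype: Karyotype,
    reference: CombinedReference,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> WindowedCoverage:
    """Windowed nuclear coverage for one strain.

    Window mean = copies x depth_per_copy x lognormal(0, noise_sigma);
    a ``mappability_dropout`` fraction of windows is zeroed; segments of an
    unbalanced translocation use their own copy numbers.
    """
    rng = rng if rng is not None else _rng(params, "coverage")
    frames = []
    for tag, chrom in reference.nuclear_slots():
        n = reference.n_windows(tag, chrom)
        seg = karyotype.segment_for(tag, chrom)
        if seg is None:
            level = np.full(n, float(karyotype.get(tag, chrom)))
        else:
            starts = reference.window_bounds(tag, chrom)[:, 0]
            level = np.where(
                starts < seg.breakpoint, float(seg.left_copies), float(seg.right_copies)
            )
        depths = level * params.depth_per_copy
        if params.noise_sigma > 0:
            depths = depths * rng.lognormal(0.0, params.noise_sigma, size=n)
        if params.mappability_dropout > 0:
            depths[rng.random(n) < params.mappability_dropout] = 0.0
        frames.append(_window_frame(reference, tag, chrom, depths))
    return WindowedCoverage(pd.concat(frames, ignore_index=True))


def simulate_mt_coverage(
    mt_state: MtState,
    reference: CombinedReference,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> WindowedCoverage:
    """Windowed coverage over every species' mitochondrial genome.

    Homoplasmic: the donor mt fully covered, all others zero.
    Heteroplasmic: each retained mt fully covered.  Recombinant with
    breakpoint fraction f: donor A covered on [0, f*L), donor B on the
    complementary block of its own molecule.
    """
    rng = rng if rng is not None else _rng(params, "mtcoverage")
    frames = []
    for sp in reference.species:
        if sp.mt_length is None:
            continue
        bounds = reference.window_bounds(sp.tag, MT_CHROM_NAME)
        n = len(bounds)
        covered = np.zeros(n, dtype=bool)
        if sp.tag in mt_state.donors:
            f = mt_state.breakpoint_fraction
            if f is None:
                covered[:] = True
            else:
                cut = f * sp.mt_length
                if mt_state.donors.index(sp.tag) == 0:
                    covered = bounds[:, 0] < cut
                else:
                    covered = bounds[:, 0] >= cut
        depths = np.where(covered, params.depth_per_copy, 0.0)
        if params.noise_sigma > 0:
            depths = depths * rng.lognormal(0.0, params.noise_sigma, size=n)
        frames.append(_window_frame(reference, sp.tag, MT_CHROM_NAME, depths))
    if not frames:
        raise ValueError("reference has no mitochondrial genomes")
    return WindowedCoverage(pd.concat(frames, ignore_index=True))


def simulate_fcm(
    genome_size_bp: float,
    params: SimParams,
    n_events: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """G1 fluorescence values proportional to DNA content with
    multiplicative Gaussian noise of coefficient of variation ``fcm_cv``."""
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    rng = rng if rng is not None else _rng(params, "fcm")
    base = FCM_UNITS_PER_BP * genome_size_bp
    if params.fcm_cv == 0:
        return np.full(n_events, base)
    return base * (1.0 + rng.normal(0.0, params.fcm_cv, size=n_events))


def simulate_fcm_reference(
    haploid_genome_size_bp: float,
    params: SimParams,
    n_events: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fluorescence sample of a haploid laboratory reference strain."""
    rng = rng if rng is not None else _rng(params, "fcm-ref")
    return simulate_fcm(haploid_genome_size_bp, params, n_events, rng)


def simulate_growth_curve(
    mu_true: float,
    lag_h: float,
    carrying_capacity: float,
    background: float,
    params: SimParams,
    rng: np.random.Generator | None = None,
    inoculum: float | None = None,
    duration_h: float = 48.0,
    interval_h: float = 0.25,
) -> GrowthCurve:
    """Logistic OD trajectory sampled every 15 min with additive noise and a
    constant background.

    The logistic rate is rescaled by 1/(1 - N0/K) so the noiseless curve's
    steepest log-slope equals ``mu_true`` exactly at the end of lag.
    """
    if mu_true < 0:
        raise ValueError("mu_true must be non-negative")
    rng = rng if rng is not None else _rng(params, "growth")
    k = float(carrying_capacity)
    # default inoculum at K/20: the OD a saturated culture reaches after the
    # usual ~1:200 back-dilution, comfortably above plate-reader noise
    n0 = k / 20.0 if inoculum is None else float(inoculum)
    t = np.arange(0.0, duration_h + 1e-9, interval_h)
    if mu_true == 0:
        od = np.full_like(t, n0)
    else:
        r = mu_true / (1.0 - n0 / k)
        te = np.maximum(t - lag_h, 0.0)
        growth = np.exp(r * te)
        od = k * n0 * growth / (k + n0 * (growth - 1.0))
    od = od + background
    if params.od_noise_sd > 0:
        od = od + rng.normal(0.0, params.od_noise_sd, size=t.size)
    return GrowthCurve(times=t, od=od, background=background)


def simulate_cell_areas(
    genome_size_bp: float,
    ref_size_bp: float,
    ref_area: float,
    params: SimParams,
    n: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cell areas lognormal around ref_area x (genome ratio)^(2/3): cell
    volume tracks genome size and cells are treated as spheres."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = rng if rng is not None else _rng(params, "areas")
    center = ref_area * (genome_size_bp / ref_size_bp) ** (2.0 / 3.0)
    if params.area_sigma == 0:
        return np.full(n, center)
    return center * rng.lognormal(0.0, params.area_sigma, size=n)


def params_to_dict(params: SimParams) -> dict:
    return asdict(params)
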