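"""Karyotype state: integer copy numbers per (species, chromosome) and
arm-level segment calls for unbalanced translocations."""

from __future__ import annotations

from dataclasses import dataclass, field

from .reference import CombinedReference

__all__ = ["SegmentCall", "Karyotype", "write_karyotype", "read_karyotype"]

FLAG_WHOLE = "whole"
FLAG_ABSENT = "absent"
FLAG_RECOMBINANT = "recombinant-candidate"


@dataclass(frozen=True)
class SegmentCall:
    """An arm-level copy-number step within one chromosome.

    ``breakpoint`` is a 0-based bp coordinate strictly inside the chromosome;
    the left segment [0, breakpoint) carries ``left_copies`` and the right
    segment carries ``right_copies``.
    """

    species: str
    chromosome: str
    breakpoint: int
    left_copies: int
    right_copies: int

    def __post_init__(self) -> None:
        if self.left_copies == self.right_copies:
            raise ValueError("segment call with equal copies on both sides")
        if self.left_copies < 0 or self.right_copies < 0:
            raise ValueError("negative segment copy number")
        if self.breakpoint <= 0:
            raise ValueError("breakpoint must be strictly inside the chromosome")


@dataclass
class Karyotype:
    """Integer copy number per (species tag, chromosome) slot.

    ``copies`` maps every reference slot to a non-negative integer.  For a
    chromosome with an internal copy change the slot holds the rounded
    whole-chromosome call and ``segments`` carries the arm-level detail.
    """

    copies: dict[tuple[str, str], int]
    segments: list[SegmentCall] = field(default_factory=list)
    flags: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for slot, c in self.copies.items():
            if c < 0 or c != int(c):
                raise ValueError(f"copy number at {slot} must be a non-negative integer")
            self.copies[slot] = int(c)

    def get(self, tag: str, chrom: str) -> int:
        return self.copies.get((tag, chrom), 0)

    def segment_for(self, tag: str, chrom: str) -> SegmentCall | None:
        for seg in self.segments:
            if seg.species == tag and seg.chromosome == chrom:
                return seg
        return None

    @classmethod
    def euploid(
        cls, reference: CombinedReference, tag: str, ploidy: int = 2
    ) -> "Karyotype":
        """Euploid karyotype of one species over the full combined reference:
        ``ploidy`` copies of every own chromosome, 0 elsewhere."""
        copies = {slot: 0 for slot in reference.nuclear_slots()}
        for name, _ in reference.get_species(tag).chromosomes:
            copies[(tag, name)] = ploidy
        return cls(copies=copies)

    @classmethod
    def from_sum(cls, parents: list["Karyotype"]) -> "Karyotype":
        """Elementwise sum of parental copy numbers (whole-genome fusion)."""
        if not parents:
            raise ValueError("no parents given")
        slots: dict[tuple[str, str], int] = {}
        for p in parents:
            for slot, c in p.copies.items():
                slots[slot] = slots.get(slot, 0) + c
        return cls(copies=slots)


def write_karyotype(karyotype: Karyotype, path) -> None:
    """Write a karyotype TSV: species, chromosome, copies, flag, breakpoint,
    left, right (the last three empty unless a segment call exists)."""
    import pandas as pd

    rows = []
    for (tag, chrom), c in karyotype.copies.items():
        seg = karyotype.segment_for(tag, chrom)
        rows.append(
            {
                "species": tag,
                "chromosome": chrom,
                "copies": c,
                "flag": karyotype.flags.get((tag, chrom), ""),
                "breakpoint": seg.breakpoint if seg else "",
                "left": seg.left_copies if seg else "",
                "right": seg.right_copies if seg else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_karyotype(path) -> Karyotype:
    """Read a karyotype TSV written by :func:`write_karyotype`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"species": str, "chromosome": str})
    copies, flags, segments = {}, {}, []
    for r in df.itertuples():
        slot = (str(r.species), str(r.chromosome))
        copies[slot] = int(r.copies)
        if isinstance(r.flag, str) and r.flag:
            flags[slot] = r.flag
        if pd.notna(r.breakpoint) and str(r.breakpoint).strip():
            segments.append(
                SegmentCall(
                    species=slot[0],
                    chromosome=slot[1],
                    breakpoint=int(float(r.breakpoint)),
                    left_copies=int(float(r.left)),
                    right_copies=int(float(r.right)),
                )
            )
    return Karyotype(copies=copies, segments=segments, flags=flags)
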