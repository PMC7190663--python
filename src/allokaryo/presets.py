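"""Canonical study-sized fixtures: a six-parent *Saccharomyces*-like
combined reference (plus a non-parent decoy species) and the three-scheme
crossing pedigree that stacks them into a six-species hybrid."""

from __future__ import annotations

from .reference import CombinedReference, Pedigree, SpeciesGenome

# S. cerevisiae chromosome lengths in kb (sums to ~12.07 Mb); the other
# species' chromosomes are scaled versions, mirroring the genus' 16
# mostly-syntenic chromosomes of similar total size.
_SCER_CHROM_KB = [
    230, 813, 316, 1532, 577, 270, 1091, 562,
    440, 746, 667, 1078, 924, 784, 1091, 948,
]

# per-species genome-size scale and mt genome length (kb)
_SPECIES = {
    "Scer": (1.00, 86),
    "Spar": (0.99, 80),
    "Smik": (0.98, 76),
    "Sarb": (0.97, 70),
    "Skud": (0.96, 75),
    "Suva": (0.97, 74),
    "Seub": (0.98, 64),  # decoy: in the reference, never a founder
}

PARENT_TAGS = ["Scer", "Spar", "Smik", "Sarb", "Skud", "Suva"]
DECOY_TAG = "Seub"


def default_reference(
    window_size: int = 10_000, include_decoy: bool = True, with_mt: bool = True
) -> CombinedReference:
    """Six parent species (16 nuclear chromosomes each, ~12 Mb genomes)
    plus an optional decoy species present in the reference only."""
    tags = PARENT_TAGS + ([DECOY_TAG] if include_decoy else [])
    species = []
    for tag in tags:
        scale, mt_kb = _SPECIES[tag]
        chroms = [
            (f"chr{i + 1:02d}", int(round(kb * scale * 1000)))
            for i, kb in enumerate(_SCER_CHROM_KB)
        ]
        if with_mt:
            chroms.append(("mt", mt_kb * 1000))
        species.append(SpeciesGenome(tag=tag, chromosomes=chroms))
    return CombinedReference(species=species, window_size=window_size)


def default_pedigree() -> Pedigree:
    """Eleven nodes: six founders, three two-species hybrids, one
    four-species and one six-species hybrid."""
    roles = {t: "founder" for t in PARENT_TAGS}
    parents: dict[str, tuple[str, ...]] = {t: () for t in PARENT_TAGS}
    crosses = {
        "h2_ScerSpar": ("Scer", "Spar"),
        "h2_SmikSarb": ("Smik", "Sarb"),
        "h2_SkudSuva": ("Skud", "Suva"),
        "h4": ("h2_ScerSpar", "h2_SmikSarb"),
        "h6": ("h4", "h2_SkudSuva"),
    }
    for node, par in crosses.items():
        roles[node] = "hybrid"
        parents[node] = par
    return Pedigree(roles=roles, parents=parents)
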