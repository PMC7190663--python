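"""Combined multi-species reference model and shared file readers/writers.

An allopolyploid hybrid is sequenced against a *combined* reference: the
concatenation of every candidate parent species' nuclear genome (plus,
optionally, each species' mitochondrial genome).  Chromosomes are addressed
by a ``tag-chrom`` key, e.g. ``Scer-chrIV``: the species tag comes first and
may not contain a hyphen, so the key splits unambiguously on the first
hyphen.

All internal coordinates are 0-based half-open.  Per-base depth input (the
``genomeCoverageBed -d`` dialect) is 1-based and converted on read.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MT_CHROM_NAME = "mt"

__all__ = [
    "SpeciesGenome",
    "CombinedReference",
    "WindowedCoverage",
    "Pedigree",
    "read_reference_index",
    "read_coverage_windows",
    "write_coverage_windows",
    "windows_from_per_base_depth",
    "read_pedigree",
    "split_chrom_key",
]


class ReferenceError(ValueError):
    """Raised for malformed reference indexes, coverage tables or pedigrees."""


def split_chrom_key(key: str) -> tuple[str, str]:
    """Split a ``tag-chrom`` key on its first hyphen."""
    tag, sep, chrom = key.partition("-")
    if not sep or not tag or not chrom:
        raise ReferenceError(f"malformed chromosome key {key!r}; expected 'tag-chrom'")
    return tag, chrom


@dataclass
class SpeciesGenome:
    """One parent species' genome within the combined reference.

    ``chromosomes`` lists nuclear chromosomes in reference order as
    ``(name, length_bp)``.  A chromosome named ``mt`` is treated as the
    mitochondrial genome: it is stored in ``mt_length`` and excluded from the
    nuclear genome size ``Gs``.
    """

    tag: str
    chromosomes: list[tuple[str, int]]
    centromere_pos: dict[str, int] = field(default_factory=dict)
    mt_length: int | None = None

    def __post_init__(self) -> None:
        if "-" in self.tag:
            raise ReferenceError(f"species tag {self.tag!r} may not contain '-'")
        nuclear = []
        for name, length in self.chromosomes:
            if length <= 0:
                raise ReferenceError(
                    f"{self.tag}-{name}: non-positive length {length}"
                )
            if name == MT_CHROM_NAME:
                self.mt_length = int(length)
            else:
                nuclear.append((name, int(length)))
        names = [n for n, _ in nuclear]
        if len(set(names)) != len(names):
            raise ReferenceError(f"duplicate chromosome names in species {self.tag}")
        self.chromosomes = nuclear

    @property
    def genome_size(self) -> int:
        """Total nuclear length Gs in bp (sum of chromosome lengths)."""
        return sum(length for _, length in self.chromosomes)

    def chrom_length(self, name: str) -> int:
        if name == MT_CHROM_NAME:
            if self.mt_length is None:
                raise KeyError(f"{self.tag} has no mitochondrial genome")
            return self.mt_length
        for n, length in self.chromosomes:
            if n == name:
                return length
        raise KeyError(f"unknown chromosome {self.tag}-{name}")


@dataclass
class CombinedReference:
    """Ordered collection of species genomes plus the analysis window size."""

    species: list[SpeciesGenome]
    window_size: int = 10_000

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ReferenceError(f"window size must be positive, got {self.window_size}")
        tags = [sp.tag for sp in self.species]
        if len(set(tags)) != len(tags):
            raise ReferenceError("duplicate species tags in combined reference")

    def get_species(self, tag: str) -> SpeciesGenome:
        for sp in self.species:
            if sp.tag == tag:
                return sp
        raise KeyError(f"unknown species tag {tag!r}")

    @property
    def tags(self) -> list[str]:
        return [sp.tag for sp in self.species]

    def nuclear_slots(self) -> list[tuple[str, str]]:
        """All (species tag, chromosome) pairs, in reference order."""
        return [(sp.tag, name) for sp in self.species for name, _ in sp.chromosomes]

    def chrom_length(self, tag: str, chrom: str) -> int:
        return self.get_species(tag).chrom_length(chrom)

    def n_windows(self, tag: str, chrom: str) -> int:
        length = self.chrom_length(tag, chrom)
        return -(-length // self.window_size)  # ceil division

    def window_bounds(self, tag: str, chrom: str) -> np.ndarray:
        """(n_windows, 2) array of 0-based half-open window coordinates."""
        length = self.chrom_length(tag, chrom)
        ws = self.window_size
        starts = np.arange(0, length, ws, dtype=np.int64)
        ends = np.minimum(starts + ws, length)
        return np.column_stack([starts, ends])


@dataclass
class WindowedCoverage:
    """Tiled mean read depths per (species, chromosome, window).

    Backed by a DataFrame with columns ``species``, ``chromosome``,
    ``start``, ``end``, ``depth``.  Windows are 0-based half-open and tile
    each chromosome contiguously; the last window may be short.
    """

    records: pd.DataFrame

    COLUMNS = ("species", "chromosome", "start", "end", "depth")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ReferenceError(f"coverage table missing columns {sorted(missing)}")
        self.records = self.records.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        depth = self.records["depth"].to_numpy(dtype=float)
        if not np.all(np.isfinite(depth)) or np.any(depth < 0):
            raise ReferenceError("depths must be finite and non-negative")
        bad = self.records["start"] >= self.records["end"]
        if bad.any():
            row = self.records[bad].iloc[0]
            raise ReferenceError(
                f"window start >= end at {row.species}-{row.chromosome}:{row.start}"
            )

    def chromosome(self, tag: str, chrom: str) -> pd.DataFrame:
        mask = (self.records["species"] == tag) & (self.records["chromosome"] == chrom)
        return self.records[mask].sort_values("start").reset_index(drop=True)

    def depths(self, tag: str, chrom: str) -> np.ndarray:
        return self.chromosome(tag, chrom)["depth"].to_numpy(dtype=float)

    def validate_tiling(self, reference: CombinedReference) -> None:
        """Check every chromosome's windows tile it contiguously and in order."""
        for (tag, chrom), grp in self.records.groupby(
            ["species", "chromosome"], sort=False
        ):
            try:
                length = reference.chrom_length(tag, chrom)
            except KeyError as exc:
                raise ReferenceError(str(exc)) from exc
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            if starts[0] != 0:
                raise ReferenceError(
                    f"{tag}-{chrom}: tiling gap before position {starts[0]}"
                )
            gaps = np.nonzero(starts[1:] != ends[:-1])[0]
            if gaps.size:
                i = gaps[0]
                if starts[i + 1] < ends[i]:
                    raise ReferenceError(
                        f"{tag}-{chrom}: overlapping windows at position {starts[i + 1]}"
                    )
                raise ReferenceError(
                    f"{tag}-{chrom}: tiling gap at position {ends[i]}"
                )
            if ends[-1] != length:
                if ends[-1] > length:
                    raise ReferenceError(
                        f"{tag}-{chrom}: window end {ends[-1]} beyond length {length}"
                    )
                raise ReferenceError(
                    f"{tag}-{chrom}: tiling gap at position {ends[-1]} (chromosome "
                    f"length {length})"
                )

    def covered_mass(self) -> float:
        """Total Σ(mean depth × window length) in read·bp."""
        r = self.records
        return float(np.sum(r["depth"].to_numpy() * (r["end"] - r["start"]).to_numpy()))


def _strain_role(role: str) -> str:
    role = role.strip().lower()
    if role not in {"founder", "hybrid", "evolved"}:
        raise ReferenceError(f"unknown pedigree role {role!r}")
    return role


@dataclass
class Pedigree:
    """DAG of strains: founders (no parents), hybrids (2 parents),
    evolved isolates (1 ancestor)."""

    roles: dict[str, str]
    parents: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for node, role in self.roles.items():
            par = self.parents.get(node, ())
            n_expected = {"founder": 0, "hybrid": 2, "evolved": 1}[_strain_role(role)]
            if len(par) != n_expected:
                raise ReferenceError(
                    f"node {node!r} with role {role!r} has {len(par)} parents, "
                    f"expected {n_expected}"
                )
            for p in par:
                if p not in self.roles:
                    raise ReferenceError(f"node {node!r}: unknown parent {p!r}")
        try:
            self._topo = tuple(
                graphlib.TopologicalSorter(
                    {n: set(self.parents.get(n, ())) for n in self.roles}
                ).static_order()
            )
        except graphlib.CycleError as exc:
            raise ReferenceError(f"pedigree contains a cycle: {exc.args[1]}") from exc

    @property
    def nodes(self) -> list[str]:
        return list(self.roles)

    def topological_order(self) -> list[str]:
        """Nodes ordered so every parent precedes its children."""
        return list(self._topo)

    def founders(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == "founder"]


# ---------------------------------------------------------------------------
# Readers / writers


def read_reference_index(path, window_size: int | None = None) -> CombinedReference:
    """Read a reference index TSV with columns species, chromosome, length
    and optional centromere.

    The window size may be given as a ``#window_size=<bp>`` header comment or
    via the ``window_size`` argument (the argument wins).
    """
    header_ws = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("window_size"):
                header_ws = int(stripped.split("=", 1)[1])
        elif line.strip():
            body.append(line)
    if not body:
        raise ReferenceError(f"{path}: no chromosomes in reference index")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t", dtype={"species": str})
    required = {"species", "chromosome", "length"}
    if not required <= set(df.columns):
        raise ReferenceError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise ReferenceError(f"{path}: no chromosomes in reference index")
    dup = df.duplicated(subset=["species", "chromosome"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ReferenceError(
            f"duplicate (species, chromosome): {row.species}-{row.chromosome}"
        )
    species: list[SpeciesGenome] = []
    for tag in df["species"].drop_duplicates():
        sub = df[df["species"] == tag]
        chroms = [(str(r.chromosome), int(r.length)) for r in sub.itertuples()]
        cen = {}
        if "centromere" in sub.columns:
            for r in sub.itertuples():
                if pd.notna(r.centromere):
                    cen[str(r.chromosome)] = int(r.centromere)
        species.append(SpeciesGenome(tag=str(tag), chromosomes=chroms, centromere_pos=cen))
    ws = window_size if window_size is not None else (header_ws or 10_000)
    return CombinedReference(species=species, window_size=ws)


def read_coverage_windows(path, reference: CombinedReference) -> WindowedCoverage:
    """Read a windowed-coverage TSV (chrom-key, start, end, mean depth).

    The chrom-key column uses the ``tag-chrom`` convention.  Tiling against
    the reference is validated; unknown chromosomes are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if len(cols) < 4:
        raise ReferenceError(f"{path}: expected 4 columns (key, start, end, depth)")
    df = df.rename(
        columns={cols[0]: "key", cols[1]: "start", cols[2]: "end", cols[3]: "depth"}
    )
    keys = df["key"].map(split_chrom_key)
    df["species"] = [k[0] for k in keys]
    df["chromosome"] = [k[1] for k in keys]
    cov = WindowedCoverage(df[["species", "chromosome", "start", "end", "depth"]])
    cov.validate_tiling(reference)
    return cov


def write_coverage_windows(cov: WindowedCoverage, path) -> None:
    """Write coverage in the 4-column TSV dialect read by
    :func:`read_coverage_windows` (round-trip safe)."""
    out = cov.records.copy()
    out["key"] = out["species"] + "-" + out["chromosome"]
    out[["key", "start", "end", "depth"]].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def windows_from_per_base_depth(
    path, reference: CombinedReference, window_size: int | None = None
) -> WindowedCoverage:
    """Aggregate a per-base depth table into windowed mean coverage.

    The input dialect is the sparse ``genomeCoverageBed -d`` form:
    (chrom-key, 1-based position, depth); absent positions imply depth 0.
    The final short window is averaged over its actual length, not padded.
    """
    ws = window_size if window_size is not None else reference.window_size
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["key", "pos", "depth"]
    )
    if not df.empty and (df["depth"] < 0).any():
        raise ReferenceError("negative depth in per-base input")
    sums: dict[tuple[str, str], np.ndarray] = {}
    for key, grp in df.groupby("key", sort=False):
        tag, chrom = split_chrom_key(str(key))
        try:
            length = reference.chrom_length(tag, chrom)
        except KeyError as exc:
            raise ReferenceError(str(exc)) from exc
        pos = grp["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
        if (pos < 0).any() or (pos >= length).any():
            raise ReferenceError(
                f"{tag}-{chrom}: position outside chromosome of length {length}"
            )
        n_win = -(-length // ws)
        acc = np.bincount(pos // ws, weights=grp["depth"].to_numpy(float), minlength=n_win)
        sums[(tag, chrom)] = acc
    rows = []
    for sp in reference.species:
        chrom_list = list(sp.chromosomes)
        if sp.mt_length is not None:
            chrom_list.append((MT_CHROM_NAME, sp.mt_length))
        for chrom, length in chrom_list:
            acc = sums.get((sp.tag, chrom))
            n_win = -(-length // ws)
            if acc is None:
                acc = np.zeros(n_win)
            starts = np.arange(n_win, dtype=np.int64) * ws
            ends = np.minimum(starts + ws, length)
            means = acc / (ends - starts)
            for s, e, m in zip(starts, ends, means):
                rows.append((sp.tag, chrom, int(s), int(e), float(m)))
    return WindowedCoverage(
        pd.DataFrame(rows, columns=list(WindowedCoverage.COLUMNS))
    )


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV with columns node, role, parent1, parent2."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"node", "role"}
    if not required <= set(df.columns):
        raise ReferenceError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    roles: dict[str, str] = {}
    parents: dict[str, tuple[str, ...]] = {}
    for r in df.itertuples():
        node = str(r.node)
        if node in roles:
            raise ReferenceError(f"duplicate pedigree node {node!r}")
        roles[node] = _strain_role(str(r.role))
        par = []
        for col in ("parent1", "parent2"):
            val = getattr(r, col, None)
            if val is not None and pd.notna(val) and str(val).strip():
                par.append(str(val).strip())
        parents[node] = tuple(par)
    return Pedigree(roles=roles, parents=parents)
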