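"""File formats and domain types shared by every analysis stage.

Coordinate convention: all mitochondrial positions are 1-based on the
revised Cambridge Reference Sequence (rCRS, NC_012920; 16,569 bp), written
``m.NNNN`` in the field's notation.  Conversion to 0-based indexing happens
only inside read matching (:mod:`mitoleak.motif_counting`).

The package bundles the published four-trio count table and the gamete
copy-number summary statistics so every downstream stage is runnable
offline; see :func:`load_trio_counts`, :func:`load_motifs` and
:func:`reference_gamete_counts`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

RCRS_LENGTH = 16_569
VALID_BASES = frozenset("ACGT")
ROLES = ("mother", "father", "child")

#: Trio -> motif whose maternal/paternal alleles discriminate that trio's
#: lineages (the "expected motif" of the bundled study data).
TRIO_DEFINING_MOTIFS = {"Trio1": "A", "Trio2": "B", "Trio3": "C", "Trio4": "D"}


class ConfigError(ValueError):
    """A motif/count/gamete input failed validation; message names the field."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSite:
    """One discriminating position with its maternal and paternal allele."""

    position: int
    maternal: str
    paternal: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ConfigError(
                f"site position {self.position} outside rCRS range 1..{RCRS_LENGTH}"
            )
        for name in ("maternal", "paternal"):
            allele = getattr(self, name)
            if allele not in VALID_BASES:
                raise ConfigError(
                    f"{name} allele {allele!r} at m.{self.position} is not one of A/C/G/T"
                )
        if self.maternal == self.paternal:
            raise ConfigError(
                f"maternal and paternal alleles identical ({self.maternal}) at m.{self.position}"
            )


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered set of nearby rCRS sites defining 2**k allele permutations.

    ``flank`` is the number of reference bases of context kept on each side
    of the outermost sites when building exact-match strings.
    """

    motif_id: str
    amplicon_id: str
    sites: tuple[MotifSite, ...]
    flank: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if len(self.sites) < 1:
            raise ConfigError(f"motif {self.motif_id}: needs at least one site")
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ConfigError(
                f"motif {self.motif_id}: positions must be strictly increasing, got {positions}"
            )
        if self.flank < 0:
            raise ConfigError(f"motif {self.motif_id}: flank must be >= 0")

    @property
    def k(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)

    @property
    def span(self) -> int:
        """Inclusive number of bases between the outermost sites."""
        return self.sites[-1].position - self.sites[0].position + 1

    def window(self) -> tuple[int, int]:
        """1-based inclusive (start, end) of the match window with flanks."""
        return self.sites[0].position - self.flank, self.sites[-1].position + self.flank

    def permutation_labels(self) -> list[str]:
        """All 2**k allele combinations, joined with '-' in site order."""
        return [
            "-".join(alleles)
            for alleles in product(*[(s.maternal, s.paternal) for s in self.sites])
        ]

    @property
    def maternal_label(self) -> str:
        return "-".join(s.maternal for s in self.sites)

    @property
    def paternal_label(self) -> str:
        return "-".join(s.paternal for s in self.sites)


@dataclass
class HaplotypeCounts:
    """Per-individual, per-motif read counts for each allele permutation."""

    individual_id: str
    motif_id: str
    permutation_counts: dict[str, int]
    aligned_reads: int

    def __post_init__(self) -> None:
        for label, count in self.permutation_counts.items():
            if not isinstance(count, (int,)) or count < 0:
                raise ConfigError(
                    f"{self.individual_id}/{self.motif_id}: count for {label!r} "
                    f"must be a non-negative integer, got {count!r}"
                )
        if self.aligned_reads < 0:
            raise ConfigError(
                f"{self.individual_id}/{self.motif_id}: aligned_reads must be >= 0"
            )
        if sum(self.permutation_counts.values()) > self.aligned_reads:
            raise ConfigError(
                f"{self.individual_id}/{self.motif_id}: permutation counts exceed aligned_reads"
            )

    @property
    def total(self) -> int:
        return sum(self.permutation_counts.values())


@dataclass
class TrioCountTable:
    """A collection of trios with their per-motif haplotype counts.

    ``trios`` maps trio id -> {"mother"|"father"|"child" -> individual id};
    ``counts`` maps (individual id, motif id) -> :class:`HaplotypeCounts`.
    """

    trios: dict[str, dict[str, str]]
    counts: dict[tuple[str, str], HaplotypeCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trio_id, roles in self.trios.items():
            if set(roles) != set(ROLES):
                raise ConfigError(
                    f"trio {trio_id}: roles must be exactly {ROLES}, got {sorted(roles)}"
                )
            if len(set(roles.values())) != 3:
                raise ConfigError(f"trio {trio_id}: the three individuals must be distinct")

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for roles in self.trios.values():
            for ind in roles.values():
                seen.setdefault(ind)
        return list(seen)

    def individual(self, trio_id: str, role: str) -> str:
        return self.trios[trio_id][role]

    def get(self, individual_id: str, motif_id: str) -> HaplotypeCounts:
        try:
            return self.counts[(individual_id, motif_id)]
        except KeyError:
            raise KeyError(
                f"no counts for individual {individual_id!r}, motif {motif_id!r}"
            ) from None

    def add(self, counts: HaplotypeCounts) -> None:
        key = (counts.individual_id, counts.motif_id)
        if key in self.counts:
            raise ConfigError(f"duplicate counts for individual/motif pair {key}")
        self.counts[key] = counts


@dataclass(frozen=True)
class GameteSample:
    """Per-cell mtDNA copy numbers for one gamete type.

    Either raw per-cell values, or their summary moments (mean, sd, n) when
    the raw measurements are unavailable.
    """

    mean: float
    sd: float
    n: int
    values: tuple[float, ...] | None = None

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GameteSample":
        vals = tuple(float(v) for v in values)
        if not vals:
            raise ConfigError("gamete sample needs at least one value")
        if any(v <= 0 for v in vals):
            raise ConfigError("gamete copy numbers must be strictly positive")
        mean = sum(vals) / len(vals)
        if len(vals) > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        else:
            sd = 0.0
        return cls(mean=mean, sd=sd, n=len(vals), values=vals)

    @classmethod
    def from_moments(cls, mean: float, sd: float, n: int) -> "GameteSample":
        if mean <= 0:
            raise ConfigError(f"gamete mean must be positive, got {mean}")
        if sd < 0:
            raise ConfigError(f"gamete sd must be >= 0, got {sd}")
        if n < 1:
            raise ConfigError(f"gamete sample size must be >= 1, got {n}")
        return cls(mean=float(mean), sd=float(sd), n=int(n))


@dataclass(frozen=True)
class GameteCountSet:
    """Sperm and oocyte per-cell mtDNA copy-number data."""

    sperm: GameteSample
    oocyte: GameteSample


# ---------------------------------------------------------------------------
# motif config (YAML; JSON parses as a YAML subset)
# ---------------------------------------------------------------------------

def read_motif_config(path: str | Path) -> list[MotifDefinition]:
    """Read motif definitions from the YAML config dialect.

    Expected layout::

        motifs:
        - motif_id: A
          amplicon_id: amp1
          flank: 20
          sites:
          - {position: 11299, maternal: T, paternal: C}
          - {position: 11467, maternal: A, paternal: G}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "motifs" not in doc:
        raise ConfigError(f"{path}: expected a top-level 'motifs' list")
    motifs = []
    for entry in doc["motifs"]:
        try:
            sites = tuple(
                MotifSite(
                    position=int(s["position"]),
                    maternal=str(s["maternal"]).upper(),
                    paternal=str(s["paternal"]).upper(),
                )
                for s in entry["sites"]
            )
            motifs.append(
                MotifDefinition(
                    motif_id=str(entry["motif_id"]),
                    amplicon_id=str(entry.get("amplicon_id", "")),
                    sites=sites,
                    flank=int(entry.get("flank", 20)),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: motif entry missing field {exc}") from None
    if not motifs:
        raise ConfigError(f"{path}: no motifs defined")
    return motifs


def write_motif_config(motifs: Iterable[MotifDefinition], path: str | Path) -> None:
    doc = {
        "motifs": [
            {
                "motif_id": m.motif_id,
                "amplicon_id": m.amplicon_id,
                "flank": m.flank,
                "sites": [
                    {"position": s.position, "maternal": s.maternal, "paternal": s.paternal}
                    for s in m.sites
                ],
            }
            for m in motifs
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# count tables (TSV)
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["trio", "role", "individual", "motif", "permutation", "count", "aligned_reads"]


def read_count_table(path: str | Path) -> TrioCountTable:
    """Read a trio count table from TSV (one row per permutation count)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ConfigError(f"{path}: no records")
        missing = set(_COUNT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ConfigError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)
    if not rows:
        raise ConfigError(f"{path}: no records")

    trios: dict[str, dict[str, str]] = {}
    grouped: dict[tuple[str, str], dict] = {}
    for row in rows:
        trio_id, role, ind = row["trio"], row["role"], row["individual"]
        if role not in ROLES:
            raise ConfigError(f"{path}: unknown role {role!r} for individual {ind}")
        roles = trios.setdefault(trio_id, {})
        if roles.get(role, ind) != ind:
            raise ConfigError(f"{path}: trio {trio_id} has two individuals for role {role}")
        roles[role] = ind
        try:
            count = int(row["count"])
            aligned = int(row["aligned_reads"])
        except ValueError:
            raise ConfigError(
                f"{path}: non-integer count for {ind}/{row['motif']}"
            ) from None
        key = (ind, row["motif"])
        entry = grouped.setdefault(key, {"aligned": aligned, "perms": {}})
        if entry["aligned"] != aligned:
            raise ConfigError(f"{path}: inconsistent aligned_reads for {key}")
        if row["permutation"] in entry["perms"]:
            raise ConfigError(
                f"{path}: duplicate row for {ind}/{row['motif']}/{row['permutation']}"
            )
        entry["perms"][row["permutation"]] = count

    table = TrioCountTable(trios=trios)
    for (ind, motif_id), entry in grouped.items():
        table.add(
            HaplotypeCounts(
                individual_id=ind,
                motif_id=motif_id,
                permutation_counts=entry["perms"],
                aligned_reads=entry["aligned"],
            )
        )
    return table


def write_count_table(table: TrioCountTable, path: str | Path) -> None:
    """Write a trio count table as TSV; integer-exact round-trip partner of
    :func:`read_count_table`."""
    role_of: dict[str, tuple[str, str]] = {}
    for trio_id, roles in table.trios.items():
        for role, ind in roles.items():
            role_of[ind] = (trio_id, role)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COUNT_COLUMNS)
        for (ind, motif_id), counts in table.counts.items():
            trio_id, role = role_of[ind]
            for label, count in counts.permutation_counts.items():
                writer.writerow(
                    [trio_id, role, ind, motif_id, label, count, counts.aligned_reads]
                )


# ---------------------------------------------------------------------------
# gamete counts (TSV: columns cell_type, copy_number)
# ---------------------------------------------------------------------------

def read_gamete_counts(path: str | Path) -> GameteCountSet:
    """Read per-cell gamete copy numbers from TSV (cell_type, copy_number)."""
    sperm: list[float] = []
    oocyte: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cell_type = row["cell_type"].strip().lower()
            value = float(row["copy_number"])
            if cell_type == "sperm":
                sperm.append(value)
            elif cell_type == "oocyte":
                oocyte.append(value)
            else:
                raise ConfigError(f"{path}: unknown cell_type {row['cell_type']!r}")
    if not sperm or not oocyte:
        raise ConfigError(f"{path}: need at least one sperm and one oocyte value")
    return GameteCountSet(
        sperm=GameteSample.from_values(sperm),
        oocyte=GameteSample.from_values(oocyte),
    )


def write_gamete_counts(gametes: GameteCountSet, path: str | Path) -> None:
    if gametes.sperm.values is None or gametes.oocyte.values is None:
        raise ConfigError("cannot write a gamete set that holds only summary moments")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cell_type", "copy_number"])
        for v in gametes.sperm.values:
            writer.writerow(["sperm", repr(v)])
        for v in gametes.oocyte.values:
            writer.writerow(["oocyte", repr(v)])


# ---------------------------------------------------------------------------
# reference sequence (FASTA)
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> str:
    """Read the first record of a FASTA file as an upper-case string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ConfigError(f"{path}: no FASTA records")
    return str(record.seq).upper()


# ---------------------------------------------------------------------------
# bundled study data
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("mitoleak.data").joinpath(name)


def load_motifs() -> list[MotifDefinition]:
    """The four discriminating motifs (A–D) of the bundled study dataset."""
    with resources.as_file(_data_path("motifs.yaml")) as path:
        return read_motif_config(path)


def load_trio_counts() -> TrioCountTable:
    """The bundled four-trio, twelve-individual deep-sequencing count table."""
    with resources.as_file(_data_path("trio_counts.tsv")) as path:
        return read_count_table(path)


def reference_gamete_counts() -> GameteCountSet:
    """Published summary moments of per-cell gamete mtDNA copy numbers.

    Sperm: mean 77.2, SD 53.9 over 43 cells; oocytes: mean 1.22e6,
    SD 1.83e5 over 3 cells.  Raw per-cell values are not distributed, so
    only moments are returned; downstream stages substitute a gamma
    emulator for sperm resampling (see :mod:`mitoleak.synthetic_data`).
    """
    return GameteCountSet(
        sperm=GameteSample.from_moments(77.2, 53.9, 43),
        oocyte=GameteSample.from_moments(1.22e6, 1.83e5, 3),
    )
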