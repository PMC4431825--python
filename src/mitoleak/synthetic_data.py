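"""Generators for gamete counts, trio count tables and raw reads.

Every generator is a pure function of (seed, config): identical inputs
reproduce identical outputs bit for bit.  Defaults encode the study
conditions the analysis targets: sperm copy numbers with mean 77.2 and SD
53.9 (n = 43 cells), oocyte copy numbers with mean 1.22e6 and SD 1.83e5
(n = 3 cells), per-read background discordant-haplotype rates of a few
1e-5, and an optional paternal spike-in around the 1e-5 to 1.8e-4 range a
passive-dilution model predicts.

The raw per-cell sperm measurements behind the published moments are not
distributed, so sperm copy numbers are emulated with a gamma distribution
matched to the moments (non-negative, right-skewed); oocyte copy numbers
are drawn from a normal distribution with non-positive draws rejected,
mirroring the bootstrap recipe of the ratio stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_config import (
    ConfigError,
    GameteCountSet,
    GameteSample,
    HaplotypeCounts,
    MotifDefinition,
    TrioCountTable,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    background_rate is the per-read probability that an individual's reads
    show the full discordant motif (PCR/sequencing background, lambda0);
    paternal_fraction is the true paternal heteroplasmy in the child (0
    under strict maternal inheritance).
    """

    seed: int = 0
    sperm_mean: float = 77.2
    sperm_sd: float = 53.9
    n_sperm: int = 43
    oocyte_mean: float = 1.22e6
    oocyte_sd: float = 1.83e5
    n_oocyte: int = 3
    background_rate: float = 5e-5
    coverage: int = 300_000
    paternal_fraction: float = 0.0
    read_length: int = 250
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 <= self.background_rate < 1:
            raise ConfigError("background_rate must be in [0, 1)")
        if not 0 <= self.paternal_fraction < 1:
            raise ConfigError("paternal_fraction must be in [0, 1)")
        if self.coverage < 0:
            raise ConfigError("coverage must be >= 0")
        if self.sperm_sd < 0 or self.oocyte_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.sperm_mean <= 0 or self.oocyte_mean <= 0:
            raise ConfigError("gamete means must be positive")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# gamete copy numbers
# ---------------------------------------------------------------------------

def draw_sperm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Gamma-distributed sperm copy numbers matching (mean, sd).

    shape = (mean/sd)**2, scale = sd**2/mean; sd == 0 degenerates to a
    constant sample.
    """
    if mean <= 0 or sd < 0:
        raise ConfigError("sperm moments must satisfy mean > 0, sd >= 0")
    if sd == 0:
        return np.full(size, float(mean))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def draw_oocytes(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal oocyte copy numbers with non-positive draws rejected."""
    if mean <= 0 or sd < 0:
        raise ConfigError("oocyte moments must satisfy mean > 0, sd >= 0")
    if sd == 0:
        return np.full(size, float(mean))
    values = rng.normal(mean, sd, size=size)
    bad = values <= 0
    while bad.any():  # negligible probability at realistic moments
        values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = values <= 0
    return values


def simulate_gamete_counts(cfg: SimulationConfig) -> GameteCountSet:
    """Draw per-cell copy numbers for n_sperm sperm and n_oocyte oocytes."""
    rng = np.random.default_rng(cfg.seed)
    sperm = draw_sperm(rng, cfg.sperm_mean, cfg.sperm_sd, cfg.n_sperm)
    oocytes = draw_oocytes(rng, cfg.oocyte_mean, cfg.oocyte_sd, cfg.n_oocyte)
    return GameteCountSet(
        sperm=GameteSample.from_values(sperm.tolist()),
        oocyte=GameteSample.from_values(oocytes.tolist()),
    )


# ---------------------------------------------------------------------------
# trio count tables
# ---------------------------------------------------------------------------

def simulate_trio_counts(
    cfg: SimulationConfig, motifs: Sequence[MotifDefinition]
) -> tuple[TrioCountTable, dict]:
    """Generate one synthetic trio per motif plus the generating truth.

    Parents' discordant counts are Poisson(coverage * background_rate);
    the child's discordant count adds an independent
    Binomial(coverage, paternal_fraction) spike-in.  The concordant count
    is coverage minus the discordant draw, so each individual's motif
    coverage is exactly ``cfg.coverage``.
    """
    if cfg.coverage <= 0:
        raise ConfigError("coverage must be > 0 to simulate counts")
    if cfg.paternal_fraction + cfg.background_rate >= 1:
        raise ConfigError("paternal_fraction + background_rate must be < 1")
    rng = np.random.default_rng(cfg.seed)
    lam = cfg.coverage * cfg.background_rate

    trios: dict[str, dict[str, str]] = {}
    table = TrioCountTable(trios=trios)
    for motif in motifs:
        trio_id = f"sim-{motif.motif_id}"
        roles = {role: f"{trio_id}-{role}" for role in ("mother", "father", "child")}
        trios[trio_id] = roles
        for role, ind in roles.items():
            discordant = int(min(rng.poisson(lam), cfg.coverage))
            if role == "child":
                spike = int(rng.binomial(cfg.coverage, cfg.paternal_fraction))
                discordant = min(discordant + spike, cfg.coverage)
            concordant = cfg.coverage - discordant
            if role == "father":
                # the father carries the paternal motif; his discordant
                # reads show the maternal alleles
                perms = {motif.paternal_label: concordant, motif.maternal_label: discordant}
            else:
                perms = {motif.maternal_label: concordant, motif.paternal_label: discordant}
            table.add(
                HaplotypeCounts(
                    individual_id=ind,
                    motif_id=motif.motif_id,
                    permutation_counts=perms,
                    aligned_reads=cfg.coverage,
                )
            )
    truth = {
        "paternal_fraction": cfg.paternal_fraction,
        "background_rate": cfg.background_rate,
        "coverage": cfg.coverage,
        "seed": cfg.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# raw reads
# ---------------------------------------------------------------------------

def random_reference(seed: int, length: int, motifs: Sequence[MotifDefinition] = ()) -> str:
    """A random A/C/G/T sequence carrying each motif's maternal alleles.

    Convenience for tests and demos: a stand-in reference with the right
    coordinate geometry, not the real mitochondrial sequence.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    for motif in motifs:
        for site in motif.sites:
            if site.position > length:
                raise ConfigError(
                    f"reference of length {length} does not cover m.{site.position}"
                )
            seq[site.position - 1] = site.maternal
    return "".join(seq)


def simulate_reads(
    cfg: SimulationConfig,
    motif: MotifDefinition,
    reference: str,
    composition: Mapping[str, int],
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Emit reads spanning the motif window with a known haplotype mix.

    ``composition`` maps permutation label -> read count.  Each read covers
    the full motif window (sites + flanks), is reverse-complemented with
    probability 1/2, and accumulates substitution errors at ``error_rate``
    per base everywhere except the motif sites themselves.  Returns
    ``(reads, truth)`` where reads are (read_id, sequence) pairs in a
    deterministic order and truth echoes the composition.
    """
    rng = np.random.default_rng(cfg.seed)
    win_start, win_end = motif.window()
    if win_start < 1 or win_end > len(reference):
        raise ConfigError(
            f"motif {motif.motif_id}: window {win_start}..{win_end} outside reference"
        )
    window = win_end - win_start + 1
    if window > cfg.read_length:
        raise ConfigError(
            f"motif {motif.motif_id}: window of {window} bp exceeds read length {cfg.read_length}"
        )
    labels = set(motif.permutation_labels())
    for label, count in composition.items():
        if label not in labels:
            raise ConfigError(f"unknown permutation label {label!r} for motif {motif.motif_id}")
        if count < 0:
            raise ConfigError(f"composition count for {label!r} must be >= 0")

    slack = cfg.read_length - window
    bases = "ACGT"
    site_positions = set(motif.positions)
    reads: list[tuple[str, str]] = []
    serial = 0
    for label, count in composition.items():
        alleles = label.split("-")
        for _ in range(count):
            # random placement of the window inside the read, clipped to
            # the reference ends
            offset = int(rng.integers(0, slack + 1)) if slack else 0
            start = max(1, min(win_start - offset, len(reference) - cfg.read_length + 1))
            seq = list(reference[start - 1 : start - 1 + cfg.read_length])
            for site, allele in zip(motif.sites, alleles):
                seq[site.position - start] = allele
            if cfg.error_rate > 0:
                errors = rng.random(len(seq)) < cfg.error_rate
                for i in np.flatnonzero(errors):
                    if start + int(i) in site_positions:
                        continue
                    current = seq[int(i)]
                    seq[int(i)] = rng.choice([b for b in bases if b != current])
            read = "".join(seq)
            if rng.random() < 0.5:
                read = reverse_complement(read)
            reads.append((f"{motif.motif_id}:{label}:{serial}", read))
            serial += 1
    return reads, dict(composition)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ (constant Q40)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
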