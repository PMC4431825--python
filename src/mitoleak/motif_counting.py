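"""Exact motif-haplotype counting in raw reads and background summaries.

A read supports an allele permutation when it contains, as an exact
substring in either orientation, the reference context around the motif
sites with that permutation's alleles substituted.  Exact matching mirrors
the command-line grep procedure used with deep amplicon data: a sequencing
error anywhere inside the window leaves the read uncounted rather than
misassigned, and misassignment would require simultaneous errors at the
motif sites themselves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .io_config import (
    ConfigError,
    HaplotypeCounts,
    MotifDefinition,
    TrioCountTable,
)
from .synthetic_data import reverse_complement


@dataclass(frozen=True)
class MatchQuery:
    """Forward and reverse-complement match strings for one permutation."""

    motif_id: str
    label: str
    forward_string: str
    reverse_string: str

    def __post_init__(self) -> None:
        if len(self.forward_string) != len(self.reverse_string):
            raise ConfigError("forward and reverse strings must have equal length")
        if reverse_complement(self.forward_string) != self.reverse_string:
            raise ConfigError("reverse_string is not the reverse complement of forward_string")


def build_queries(motif: MotifDefinition, reference: str) -> list[MatchQuery]:
    """Build the 2**k exact-match queries for a motif.

    The reference must cover the motif window and carry one of the two
    alleles at every site (otherwise the motif definition does not belong
    to this reference).
    """
    win_start, win_end = motif.window()
    if win_start < 1 or win_end > len(reference):
        raise ConfigError(
            f"motif {motif.motif_id}: window {win_start}..{win_end} outside the reference"
        )
    for site in motif.sites:
        ref_base = reference[site.position - 1].upper()
        if ref_base not in (site.maternal, site.paternal):
            raise ConfigError(
                f"motif {motif.motif_id}: reference base {ref_base!r} at m.{site.position} "
                f"matches neither allele {site.maternal}/{site.paternal}"
            )
    template = list(reference[win_start - 1 : win_end].upper())
    queries = []
    for alleles in product(*[(s.maternal, s.paternal) for s in motif.sites]):
        seq = template.copy()
        for site, allele in zip(motif.sites, alleles):
            seq[site.position - win_start] = allele
        forward = "".join(seq)
        queries.append(
            MatchQuery(
                motif_id=motif.motif_id,
                label="-".join(alleles),
                forward_string=forward,
                reverse_string=reverse_complement(forward),
            )
        )
    return queries


def count_motifs(
    reads: Iterable[str],
    queries: Sequence[MatchQuery],
    individual_id: str = "sample",
    aligned_reads: int | None = None,
) -> HaplotypeCounts:
    """Count reads matching each permutation query, orientation-summed.

    A read increments a permutation when it contains the query's forward
    or reverse string as an exact substring; queries built from one motif
    are mutually exclusive, so each read counts at most once.  When
    ``aligned_reads`` is not supplied (FASTQ mode), it is set to the number
    of reads scanned.
    """
    if not queries:
        raise ConfigError("no queries supplied")
    motif_id = queries[0].motif_id
    counts = {q.label: 0 for q in queries}
    scanned = 0
    for read in reads:
        scanned += 1
        seq = read.upper()
        for q in queries:
            if q.forward_string in seq or q.reverse_string in seq:
                counts[q.label] += 1
                break
    return HaplotypeCounts(
        individual_id=individual_id,
        motif_id=motif_id,
        permutation_counts=counts,
        aligned_reads=scanned if aligned_reads is None else aligned_reads,
    )


def sequences_from_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip allowed)."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.sequence


def sequences_from_sam(path: str | Path) -> Iterator[str]:
    """Yield read sequences from SAM/BAM; alignment positions are unused."""
    import pysam

    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh.fetch(until_eof=True):
                if rec.query_sequence:
                    yield rec.query_sequence
    finally:
        pysam.set_verbosity(save)


# ---------------------------------------------------------------------------
# background heteroplasmy
# ---------------------------------------------------------------------------

def estimate_background_rate(
    counts: HaplotypeCounts, expected_motif: str, discordant_motif: str
) -> float:
    """Discordant-read fraction discordant / (expected + discordant)."""
    expected = counts.permutation_counts[expected_motif]
    discordant = counts.permutation_counts[discordant_motif]
    denominator = expected + discordant
    if denominator == 0:
        raise ConfigError(
            f"{counts.individual_id}/{counts.motif_id}: expected + discordant counts are zero"
        )
    return discordant / denominator


def truncate_sig(x: float, digits: int = 2) -> float:
    """Truncate (not round) ``x`` to ``digits`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    quantum = 10.0 ** (exponent - digits + 1)
    # epsilon guard so exactly-representable mantissas do not fall below
    # the truncation boundary
    return math.trunc(x / quantum * (1 + 1e-12)) * quantum


def format_rate(x: float, digits: int = 2) -> str:
    """Format a rate truncated to ``digits`` significant figures, e.g. '4.3e-05'."""
    if x == 0:
        return "0"
    exponent = math.floor(math.log10(abs(x)))
    quantum = 10.0 ** (exponent - digits + 1)
    mantissa = math.trunc(x / quantum * (1 + 1e-12))
    return f"{mantissa / 10 ** (digits - 1):.{digits - 1}f}e{exponent:+03d}"


# ---------------------------------------------------------------------------
# haplotype-class summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSummary:
    """Pooled minor-haplotype frequency for motifs with ``k`` variant sites."""

    k: int
    frequency: float
    minor_reads: int
    total_reads: int
    ratio_to_power_of_single: float | None
    ratio_to_root_of_single: float | None


def haplotype_class_summary(
    table: TrioCountTable,
    motifs: Sequence[MotifDefinition],
    roles: Sequence[str] = ("mother",),
) -> dict[int, ClassSummary]:
    """Minor-haplotype frequency pooled by motif class (1-, 2-, 3-site).

    For each selected individual and motif the minor count is the total
    minus the most abundant permutation; frequencies are pooled per class.
    If single-site motifs are present, each multi-site class also reports
    its frequency relative to p1**k (the independent per-site error
    prediction) and relative to p1**(1/k), so both candidate scalings of
    the single-site frequency can be inspected rather than assumed.
    """
    individuals = [
        table.trios[trio_id][role]
        for trio_id in table.trios
        for role in roles
    ]
    pooled: dict[int, list[int]] = {}
    for motif in motifs:
        bucket = pooled.setdefault(motif.k, [0, 0])
        for ind in individuals:
            try:
                counts = table.get(ind, motif.motif_id)
            except KeyError:
                continue
            total = counts.total
            if total == 0:
                continue
            minor = total - max(counts.permutation_counts.values())
            bucket[0] += minor
            bucket[1] += total
    classes = {k: v for k, v in pooled.items() if v[1] > 0}
    for k in sorted(set(pooled) - set(classes)):
        warnings.warn(f"no reads available for {k}-site motifs; class omitted")
    p1 = None
    if 1 in classes:
        minor, total = classes[1]
        p1 = minor / total
    summary: dict[int, ClassSummary] = {}
    for k, (minor, total) in sorted(classes.items()):
        freq = minor / total
        ratio_power = ratio_root = None
        if p1 is not None and p1 > 0 and k > 1:
            ratio_power = freq / p1**k
            ratio_root = freq / p1 ** (1 / k)
        summary[k] = ClassSummary(
            k=k,
            frequency=freq,
            minor_reads=minor,
            total_reads=total,
            ratio_to_power_of_single=ratio_power,
            ratio_to_root_of_single=ratio_root,
        )
    return summary
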