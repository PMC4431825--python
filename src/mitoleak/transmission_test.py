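"""Bootstrap hypothesis test for paternal mtDNA transmission in a trio.

Null hypothesis: the child's discordant-motif reads arise from passive
paternal leakage at the sperm:oocyte copy ratio measured on individual
gametes, on top of the same background noise seen in the mother.  Each
bootstrap replicate draws one ratio from the ratio bootstrap, simulates a
child discordant count Binomial(n_child, ratio) plus Poisson background at
the mother's observed discordant rate, simulates a mother count as pure
Poisson background, and records the difference in proportions.  The
p-value is the (lower-tail, +1-corrected) percentile rank of the observed
difference: a child deficit of discordant reads relative to leakage is
evidence against paternal transmission.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .gamete_ratio import RatioDistribution
from .io_config import (
    ConfigError,
    MotifDefinition,
    TrioCountTable,
)


class ObservedDifference(NamedTuple):
    d_obs: float
    n_child: int
    n_mother: int
    c_child: int
    c_mother: int


@dataclass(frozen=True)
class TransmissionTestResult:
    trio_id: str
    motif_id: str
    n_child: int
    n_mother: int
    c_child: int
    c_mother: int
    d_obs: float
    B: int
    p_value: float
    seed: int
    maternal_rate: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def observed_difference(
    table: TrioCountTable, trio_id: str, motif: MotifDefinition
) -> ObservedDifference:
    """Observed mother-child difference in discordant-haplotype proportion.

    The discordant count c is the paternal-motif reads of mother and child;
    n is the motif coverage, i.e. the sum of the maternal- and
    paternal-motif counts (recombinant permutations are negligible and
    excluded).  Returns d_obs = c_child/n_child - c_mother/n_mother.
    """
    mother = table.get(table.individual(trio_id, "mother"), motif.motif_id)
    child = table.get(table.individual(trio_id, "child"), motif.motif_id)

    def split(counts):
        c = counts.permutation_counts.get(motif.paternal_label, 0)
        n = c + counts.permutation_counts.get(motif.maternal_label, 0)
        return c, n

    c_mother, n_mother = split(mother)
    c_child, n_child = split(child)
    if n_mother == 0 or n_child == 0:
        raise ConfigError(
            f"{trio_id}/{motif.motif_id}: zero motif coverage in mother or child"
        )
    return ObservedDifference(
        d_obs=c_child / n_child - c_mother / n_mother,
        n_child=n_child,
        n_mother=n_mother,
        c_child=c_child,
        c_mother=c_mother,
    )


def bootstrap_transmission_test(
    table: TrioCountTable,
    trio_id: str,
    motif: MotifDefinition,
    ratios: RatioDistribution,
    B: int = 100_000,
    seed: int = 0,
) -> TransmissionTestResult:
    """Percentile-rank bootstrap test of the passive-leakage null.

    The maternal discordant rate c_mother/n_mother is treated as a fixed
    plug-in; the same per-read rate drives the Poisson background of both
    simulated individuals, scaled by each one's own coverage.
    """
    if ratios.samples.size == 0:
        raise ConfigError("empty ratio distribution")
    if B < 1_000:
        warnings.warn(f"B={B} gives a coarse p-value resolution; use B >= 1000")
    obs = observed_difference(table, trio_id, motif)
    rate = obs.c_mother / obs.n_mother
    rng = np.random.default_rng(seed)
    r = rng.choice(ratios.samples, size=B, replace=True)
    child = rng.binomial(obs.n_child, r) + rng.poisson(rate * obs.n_child, size=B)
    mother = rng.poisson(rate * obs.n_mother, size=B)
    d = child / obs.n_child - mother / obs.n_mother
    p_value = (int(np.count_nonzero(d <= obs.d_obs)) + 1) / (B + 1)
    return TransmissionTestResult(
        trio_id=trio_id,
        motif_id=motif.motif_id,
        n_child=obs.n_child,
        n_mother=obs.n_mother,
        c_child=obs.c_child,
        c_mother=obs.c_mother,
        d_obs=obs.d_obs,
        B=B,
        p_value=p_value,
        seed=seed,
        maternal_rate=rate,
    )


def defining_motif(
    table: TrioCountTable, trio_id: str, motifs: Sequence[MotifDefinition]
) -> MotifDefinition:
    """The motif whose paternal alleles dominate this trio's father.

    In a trio informative for a motif, the father carries the paternal
    motif at high coverage; off-target motifs show only background counts.
    """
    father = table.individual(trio_id, "father")
    best, best_count = None, -1
    for motif in motifs:
        try:
            counts = table.get(father, motif.motif_id)
        except KeyError:
            continue
        pat = counts.permutation_counts.get(motif.paternal_label, 0)
        mat = counts.permutation_counts.get(motif.maternal_label, 0)
        if pat > mat and pat > best_count:
            best, best_count = motif, pat
    if best is None:
        raise ConfigError(f"no motif with a paternal-dominant father found for {trio_id}")
    return best


def run_all_trios(
    table: TrioCountTable,
    motifs: Sequence[MotifDefinition],
    ratios: RatioDistribution,
    B: int = 100_000,
    seed: int = 0,
    trio_motifs: dict[str, str] | None = None,
) -> list[TransmissionTestResult]:
    """Run the transmission test on every trio's defining motif.

    ``trio_motifs`` maps trio id -> motif id; when omitted the defining
    motif is inferred from the father's counts.  Per-trio seeds are
    derived deterministically from ``seed``.
    """
    by_id = {m.motif_id: m for m in motifs}
    results = []
    for index, trio_id in enumerate(table.trios):
        if trio_motifs is not None:
            motif = by_id[trio_motifs[trio_id]]
        else:
            motif = defining_motif(table, trio_id, motifs)
        trio_seed = (seed * 1_000_003 + index) % 2**31
        results.append(
            bootstrap_transmission_test(table, trio_id, motif, ratios, B=B, seed=trio_seed)
        )
    return results


def write_results(results: Sequence[TransmissionTestResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
        fh.write("\n")


def summarize_results(
    results: Sequence[TransmissionTestResult], alpha: float = 0.05
) -> str:
    """Human-readable per-trio summary of the transmission test."""
    lines = [
        f"{'trio':<8}{'motif':<7}{'n_child':>10}{'c_child':>9}{'n_mother':>10}"
        f"{'c_mother':>10}{'d_obs':>12}{'p':>9}  decision"
    ]
    for r in results:
        decision = (
            "reject leakage" if r.p_value <= alpha else "cannot reject leakage"
        )
        lines.append(
            f"{r.trio_id:<8}{r.motif_id:<7}{r.n_child:>10}{r.c_child:>9}"
            f"{r.n_mother:>10}{r.c_mother:>10}{r.d_obs:>12.3e}{r.p_value:>9.4f}  {decision}"
        )
    return "\n".join(lines)
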