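import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoleak.io_config import ConfigError, HaplotypeCounts, MotifDefinition, MotifSite
from mitoleak.motif_counting import (
    build_queries,
    count_motifs,
    estimate_background_rate,
    format_rate,
    haplotype_class_summary,
    sequences_from_fastq,
    sequences_from_sam,
    truncate_sig,
)
from mitoleak.synthetic_data import (
    SimulationConfig,
    random_reference,
    reverse_complement,
    simulate_reads,
    simulate_trio_counts,
    write_fastq,
)

MOTIF2 = MotifDefinition(
    "A", "amp1", (MotifSite(11299, "T", "C"), MotifSite(11467, "A", "G")), flank=20
)
MOTIF3 = MotifDefinition(
    "C",
    "amp2",
    (MotifSite(15452, "G", "A"), MotifSite(15454, "T", "C"), MotifSite(15607, "G", "A")),
    flank=20,
)


def naive_scan(reads, queries):
    """Independent oracle: explicit per-read, per-offset character comparison."""
    counts = {q.label: 0 for q in queries}
    for _, read in reads:
        read = read.upper()
        assigned = None
        for q in queries:
            for needle in (q.forward_string, q.reverse_string):
                w = len(needle)
                for start in range(len(read) - w + 1):
                    if all(read[start + i] == needle[i] for i in range(w)):
                        assigned = q.label
                        break
                if assigned:
                    break
            if assigned:
                break
        if assigned:
            counts[assigned] += 1
    return counts


class TestBuildQueries:
    @pytest.mark.parametrize("motif, expected", [(MOTIF2, 4), (MOTIF3, 8)])
    def test_query_count_is_two_to_the_k(self, reference, motif, expected):
        queries = build_queries(motif, reference)
        assert len(queries) == expected
        strings = {q.forward_string for q in queries}
        assert len(strings) == expected  # pairwise distinct
        for q in queries:
            assert q.reverse_string == reverse_complement(q.forward_string)
            assert len(q.forward_string) == motif.span + 2 * motif.flank

    def test_single_site_motif(self):
        motif = MotifDefinition("X", "amp", (MotifSite(500, "A", "G"),), flank=10)
        ref = random_reference(seed=3, length=1000, motifs=[motif])
        assert len(build_queries(motif, ref)) == 2

    def test_reference_allele_mismatch_names_position(self):
        motif = MotifDefinition("X", "amp", (MotifSite(500, "A", "G"),), flank=10)
        ref = list(random_reference(seed=3, length=1000, motifs=[motif]))
        ref[499] = "C"  # neither allele
        with pytest.raises(ConfigError, match="m.500"):
            build_queries(motif, "".join(ref))

    def test_window_outside_reference_rejected(self, reference):
        motif = MotifDefinition("X", "amp", (MotifSite(16_560, "A", "G"),), flank=20)
        ref = reference[:16_559] + "A" + reference[16_560:]
        with pytest.raises(ConfigError, match="outside"):
            build_queries(motif, ref)


class TestCountMotifs:
    def test_error_free_reads_recovered_exactly(self, reference):
        cfg = SimulationConfig(seed=21, error_rate=0.0)
        composition = {MOTIF2.maternal_label: 100, MOTIF2.paternal_label: 5}
        reads, _ = simulate_reads(cfg, MOTIF2, reference, composition)
        queries = build_queries(MOTIF2, reference)
        counts = count_motifs((seq for _, seq in reads), queries)
        assert counts.permutation_counts[MOTIF2.maternal_label] == 100
        assert counts.permutation_counts[MOTIF2.paternal_label] == 5
        assert counts.aligned_reads == 105

    def test_orientation_invariance(self, reference):
        cfg = SimulationConfig(seed=22, error_rate=1e-3)
        reads, _ = simulate_reads(
            cfg, MOTIF2, reference, {MOTIF2.maternal_label: 300, MOTIF2.paternal_label: 7}
        )
        queries = build_queries(MOTIF2, reference)
        direct = count_motifs((seq for _, seq in reads), queries)
        flipped = count_motifs((reverse_complement(seq) for _, seq in reads), queries)
        assert direct.permutation_counts == flipped.permutation_counts

    @pytest.mark.parametrize("motif", [MOTIF2, MOTIF3])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_naive_scan_oracle(self, reference, motif, seed):
        cfg = SimulationConfig(seed=seed, error_rate=5e-3)
        composition = {motif.maternal_label: 120, motif.paternal_label: 15}
        reads, _ = simulate_reads(cfg, motif, reference, composition)
        queries = build_queries(motif, reference)
        counts = count_motifs((seq for _, seq in reads), queries)
        assert counts.permutation_counts == naive_scan(reads, queries)

    def test_duplication_linearity_and_bound(self, reference):
        cfg = SimulationConfig(seed=23, error_rate=1e-3)
        reads, _ = simulate_reads(
            cfg, MOTIF2, reference, {MOTIF2.maternal_label: 200, MOTIF2.paternal_label: 4}
        )
        queries = build_queries(MOTIF2, reference)
        single = count_motifs((seq for _, seq in reads), queries)
        doubled = count_motifs((seq for _, seq in reads + reads), queries)
        for label in single.permutation_counts:
            assert doubled.permutation_counts[label] == 2 * single.permutation_counts[label]
        assert single.total <= len(reads)

    def test_error_rate_miss_probability_envelope(self, reference):
        # a read is lost when any of its window bases is hit by an error
        cfg = SimulationConfig(seed=24, error_rate=1e-3)
        n = 10_000
        reads, _ = simulate_reads(cfg, MOTIF2, reference, {MOTIF2.maternal_label: n})
        queries = build_queries(MOTIF2, reference)
        counts = count_motifs((seq for _, seq in reads), queries)
        recovered = counts.permutation_counts[MOTIF2.maternal_label]
        w = MOTIF2.span + 2 * MOTIF2.flank
        p_keep_min = (1 - cfg.error_rate) ** w  # >= because site errors are suppressed
        se = math.sqrt(n * p_keep_min * (1 - p_keep_min))
        assert recovered >= n * p_keep_min - 4 * se
        assert recovered <= n

    def test_fastq_and_sam_readers(self, reference, tmp_path):
        cfg = SimulationConfig(seed=25, error_rate=0.0)
        reads, _ = simulate_reads(
            cfg, MOTIF2, reference, {MOTIF2.maternal_label: 40, MOTIF2.paternal_label: 3}
        )
        queries = build_queries(MOTIF2, reference)

        fastq = tmp_path / "reads.fastq"
        write_fastq(reads, fastq)
        from_fastq = count_motifs(sequences_from_fastq(fastq), queries)
        assert from_fastq.permutation_counts[MOTIF2.maternal_label] == 40

        sam = tmp_path / "reads.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for read_id, seq in reads:
                fh.write(f"{read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
        from_sam = count_motifs(sequences_from_sam(sam), queries)
        assert from_sam.permutation_counts == from_fastq.permutation_counts


class TestBackgroundRate:
    @pytest.mark.parametrize(
        "expected, discordant, formatted",
        [
            (252906, 11, "4.3e-05"),  # Trio 1 mother
            (412320, 25, "6.0e-05"),  # Trio 2 mother
            (86457, 5, "5.7e-05"),  # Trio 3 mother
        ],
    )
    def test_study_rates_formatted_by_truncation(self, expected, discordant, formatted):
        counts = HaplotypeCounts(
            "M", "X", {"mat": expected, "pat": discordant}, expected + discordant
        )
        rate = estimate_background_rate(counts, "mat", "pat")
        assert rate == discordant / (expected + discordant)
        assert format_rate(rate) == formatted

    def test_zero_discordant_and_zero_denominator(self):
        counts = HaplotypeCounts("M", "X", {"mat": 1000, "pat": 0}, 1000)
        assert estimate_background_rate(counts, "mat", "pat") == 0.0
        empty = HaplotypeCounts("M", "X", {"mat": 0, "pat": 0}, 0)
        with pytest.raises(ConfigError, match="zero"):
            estimate_background_rate(empty, "mat", "pat")

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(min_value=1e-12, max_value=1e6))
    def test_truncation_never_exceeds_and_stays_close(self, x):
        t = truncate_sig(x, 2)
        assert t <= x * (1 + 1e-9)
        assert t > x * 0.89  # two significant figures: at most 10% below


class TestClassSummary:
    def _binomial_table(self, error=0.005, coverage=10_000_000, seed=6):
        """Counts following independent per-site errors: minor rate error**k."""
        from mitoleak.io_config import TrioCountTable

        motifs = [
            MotifDefinition("one", "amp", (MotifSite(500, "A", "G"),), flank=5),
            MotifDefinition(
                "two", "amp", (MotifSite(600, "A", "G"), MotifSite(610, "C", "T")), flank=5
            ),
            MotifDefinition(
                "three",
                "amp",
                (MotifSite(700, "A", "G"), MotifSite(710, "C", "T"), MotifSite(720, "G", "A")),
                flank=5,
            ),
        ]
        rng = np.random.default_rng(seed)
        table = TrioCountTable(trios={"T": {"mother": "M", "father": "F", "child": "C"}})
        for motif in motifs:
            minor = int(rng.binomial(coverage, error**motif.k))
            table.add(
                HaplotypeCounts(
                    "M",
                    motif.motif_id,
                    {motif.maternal_label: coverage - minor, motif.paternal_label: minor},
                    coverage,
                )
            )
        return table, motifs

    def test_independent_errors_follow_product_law(self):
        table, motifs = self._binomial_table()
        summary = haplotype_class_summary(table, motifs)
        assert set(summary) == {1, 2, 3}
        assert summary[1].frequency == pytest.approx(0.005, rel=0.05)
        assert summary[2].frequency == pytest.approx(0.005**2, rel=0.25)
        assert summary[1].frequency > summary[2].frequency > summary[3].frequency
        # under independence the k-th class sits at p1**k, far below p1**(1/k)
        assert summary[2].ratio_to_power_of_single == pytest.approx(1.0, rel=0.3)
        assert summary[2].ratio_to_root_of_single < 0.01

    def test_bundled_mothers_have_low_multisite_frequencies(self, table, motifs):
        summary = haplotype_class_summary(table, motifs, roles=("mother",))
        assert set(summary) == {2, 3}
        for cls in summary.values():
            assert cls.frequency <= 1e-4

    def test_absent_class_warns(self, table, motifs):
        empty_motif = MotifDefinition("Z", "amp", (MotifSite(42, "A", "G"),), flank=5)
        with pytest.warns(UserWarning, match="omitted"):
            summary = haplotype_class_summary(table, list(motifs) + [empty_motif])
        assert 1 not in summary
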