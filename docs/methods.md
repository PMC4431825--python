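# Methods

This note documents the models, parameter choices and numerical
conventions behind `mitoleak`, and what the synthetic-data suite does and
does not establish about real data.

## Data model

A *motif* is an ordered set of k ≥ 1 mtDNA positions (1-based rCRS
coordinates, NC_012920) at which the maternal and paternal lineages of a
trio carry different alleles, all within one sequencing read. Its 2ᵏ
allele permutations are labelled by the concatenated allele string in site
order (e.g. `T-A` / `C-G` for the two-site motif at m.11299/m.11467). A
count table records, per individual and motif, the reads supporting each
permutation plus the total aligned reads of the source amplicon. The
bundled study table covers four trios, each informative for one motif
(A–D; A has two sites, B–D three).

## Motif counting

`build_queries` substitutes each permutation's alleles into the reference
context spanning [first site − flank, last site + flank] and pairs every
string with its reverse complement; `count_motifs` counts reads containing
either orientation as an *exact* substring. Exact matching is deliberate:
a read with any error inside the window is dropped, not reassigned, and
misassignment between permutations would require simultaneous errors at
the motif sites themselves. The per-read retention probability is
(1 − e)^w for error rate e and window w, which matters for absolute counts
but cancels in the rate and proportion comparisons downstream. The default
flank of 20 bp gives windows of ~100–210 bp for the bundled motifs —
long enough that chance matches elsewhere in the mitochondrial genome are
not a practical concern. Counts are integer-exact; queries from one motif
are mutually exclusive by construction, so each read increments at most
one permutation.

The background (discordant) rate for an individual is
c/(c + m), where c is the discordant-motif and m the expected-motif count.
Following the convention of the source dataset, rates are *truncated* (not
rounded) to two significant figures for display; `estimate_background_rate`
itself returns the exact ratio. On the bundled table the four mothers'
rates are 4.349, 6.063, 5.783 and 7.591 ×10⁻⁵; truncation displays these
as 4.3, 6.0, 5.7 and 7.5 ×10⁻⁵. The last value was published as 7.6×10⁻⁵,
which matches rounding instead; no single significant-figure rule
reproduces all four published values from the published counts, and we
keep the exact ratios everywhere computations depend on them.

The haplotype-class summary pools minor-haplotype frequencies by motif
size k. Under independent per-site errors the k-site discordant frequency
is ~p₁ᵏ for single-site frequency p₁; because the published prose is
ambiguous about whether the two-site frequency scales as the square or the
square root of p₁, the summary reports the observed frequency against both
p₁ᵏ and p₁^(1/k) rather than hard-coding either reading (the data follow
the product law).

## Gamete ratio bootstrap

Each of B replicates (default 10⁵) draws one sperm and one oocyte copy
number and records r = s/o, the paternal proportion a single fertilization
would produce under passive dilution. Oocyte draws are
normal(1.22×10⁶, 1.83×10⁵) with non-positive values rejected and redrawn
(rejection probability ~10⁻¹¹ at these moments). Sperm draws resample the
raw per-cell values with replacement when they are provided; the 43 raw
values behind the published moments (mean 77.2, SD 53.9) are not
distributed, so by default sperm are drawn from a gamma distribution with
shape (mean/sd)² ≈ 2.05 and scale sd²/mean ≈ 37.6. Gamma was chosen over
lognormal as the stand-in because it is non-negative and right-skewed with
both moments matched, and its 2.5th/97.5th ratio percentiles land close to
the published prediction interval (we obtain ~8×10⁻⁶ .. 1.84×10⁻⁴ against
the published 10⁻⁵ .. 1.8×10⁻⁴). The substitution is recorded in the
output (`sperm_source: gamma`). Percentiles are empirical order statistics
with linear interpolation (`numpy.percentile` default), fixed here for
bit-reproducibility.

The headline "1:X" ratio is the ratio of means, X = mean(oocyte)/mean(sperm)
= 15,803 from the published moments (the published 1:15,860 used unrounded
raw means; the 0.4% residual is rounding of the printed sperm mean). The
mean of per-replicate ratios E[s/o] ≈ 6.5×10⁻⁵ differs slightly (Jensen)
and diverges strongly for heavy-tailed sperm distributions; the ratio of
means is what the package reports as the mean ratio.

## Skellam power

With equal motif coverage N in mother and child, discordant counts are
M ~ Poisson(N·λ₀) and C ~ Poisson(N·(λ₀+f)); D = C − M is
Skellam(N(λ₀+f), Nλ₀). The test rejects when D ≥ c, with c the smallest
integer whose null upper-tail probability is ≤ α; α defaults to 0.05,
one-sided toward child excess, a conservative integer cut. Power is the
alternative upper tail at c. These choices are declared in the grid output
so curves are comparable. Degenerate means (λ₀ = 0 or f = 0) fall back to
pure Poisson limits. At the four observed background rates and
f = 1/15,860, coverage of 300,000× yields power 0.82–0.94; the test's size
under f = 0 is ≤ α by discreteness. For large means the power agrees with
the normal approximation Φ((μ₁−μ₂−c+½)/√(μ₁+μ₂)) to within 0.02.

## Transmission test

For a trio and its defining motif, n is the motif coverage (maternal +
paternal permutation counts; recombinant permutations are negligible and
excluded) and c the paternal-motif count; the statistic is
d_obs = c_child/n_child − c_mother/n_mother. Under the leakage null, each
of B replicates draws r_b from the ratio bootstrap and simulates

- child: Binomial(n_child, r_b) + Poisson(λ̂₀·n_child)
- mother: Poisson(λ̂₀·n_mother)

where λ̂₀ = c_mother/n_mother is the observed maternal discordant rate,
treated as a fixed plug-in and applied as the same *per-read* rate scaled
by each individual's own coverage (proportions, not expected counts, are
compared). The p-value is the lower-tail percentile rank
(#{d_b ≤ d_obs}+1)/(B+1); the +1 keeps it strictly positive. The lower
tail is the scientifically one-sided direction: a deficit of child
discordant reads contradicts leakage. Per-trio seeds in `run_all_trios`
derive deterministically from the run seed.

On the bundled table (B = 10⁵) the test gives p ≈ 0.004 (Trio 1/A),
0.015 (Trio 2/B), 0.15 (Trio 3/C) and 0.12 (Trio 4/D): the two deeply
covered trios reject passive leakage, the two shallower ones cannot — their
p-values are dominated by the width of the ratio distribution, not by
evidence of transmission. Trio 3's p-value is the most sensitive to the
shape of the sperm stand-in distribution (its observed difference sits in
a region of strong count discreteness), and is somewhat below the value
obtained with the raw sperm measurements. An alternative reading of the
procedure would plug in only the interval endpoints of the ratio rather
than its full bootstrap distribution; the full distribution is implemented,
as it is the better-specified recipe.

Calibration: when trios are generated under the test's own null (a true
spike-in at a ratio drawn from the same distribution plus Poisson
background), the rejection rate at α is within Monte-Carlo error of α
(checked at 200 simulations × B = 2,000). Against f = 0 the test's power
depends on coverage through the lower tail of the ratio distribution:
~10⁶-fold coverage rejects only about half the time, ~10⁷-fold almost
always — the reason the analysis stresses coverage depth.

## Synthetic data

The generators emulate: gamma sperm / rejected-normal oocyte copy numbers
at the published moments; trio count tables with parental discordant
counts Poisson(coverage·λ₀) and a child binomial spike-in at a chosen f;
and error-bearing reads over a motif window with ~half the reads
reverse-complemented, substitution errors at a uniform per-base rate
outside the motif sites, and exact truth bookkeeping. They do *not*
emulate alignment artifacts, indels, chimeric PCR reads, strand-specific
error profiles, position-dependent quality, or nuclear-pseudogene (NUMT)
contamination — passing tests therefore demonstrate the statistical
machinery, not robustness to those real-data failure modes, which the
amplicon design (>2 kb amplicons, high-fidelity polymerase, exact motif
matching) addresses upstream of this package.

Default problem sizes used by the test suite and acceptance script —
B = 10⁵ bootstrap replicates, coverage 3×10⁵–10⁷ for synthetic tables,
10⁴ reads for counting checks, 200 simulations for calibration — were
chosen so every claim is testable at comfortable Monte-Carlo error on a
single CPU.

## Known limitations

- Only moments of the gamete measurements ship with the package; every
  quantity that depends on the sperm distribution's shape (interval
  bounds, borderline p-values) carries stand-in uncertainty beyond its
  Monte-Carlo error.
- The maternal background rate is a plug-in, not resampled; for mothers
  with very few discordant reads (Trio 4: 2 reads) the rate itself is
  noisy, and the test inherits that noise.
- Exact matching undercounts all permutations equally but does not model
  systematic, site-specific error processes; a recurrent PCR artifact at a
  motif site would inflate the background rather than the paternal signal.
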