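# Methods

## Assignment model

Parentage assignment assumes sexual reproduction with known parent sexes,
codominant markers, and error-free genotypes: allele transmission from
parent to offspring is treated as certain, with no mutation and no null
alleles. Under these assumptions the likelihood of a candidate sire×dam
pair for one offspring is the product over loci of the Mendelian
transmission probability

P(g_off | g_sire, g_dam) = Σ over the four equiprobable gamete
combinations (one allele from each parent, weight ¼) that produce the
offspring's unordered pair.

Because every candidate pair of the full-factorial design is evaluated and
the model is error-free, population allele frequencies do not enter the
likelihood: they would multiply every pair's score identically only under
frequency-based priors, which this exclusion-compatible model deliberately
omits. The per-locus probabilities form a proper distribution over
offspring genotype space (verified by enumeration in the test suite), so
log-likelihoods of different pairs are directly comparable.

**Missing data.** A locus with a missing genotype in any member of the
trio is skipped (contributes factor 1) and does not count toward
`n_loci_used`. Offspring with fewer than `min_loci` usable loci against a
pair are not scored against it; the default `min_loci = 5` of 9 keeps at
least five informative exclusions behind every assignment.

**Ties.** Pairs within relative tolerance `tie_tol = 1e-9` of the maximum
log-likelihood are reported as *ambiguous* with the full tie list, never
silently broken: with an error-free model, distinct compatible pairs can
have exactly equal likelihoods, and auditability matters more than forcing
a call. *Unassigned* means no compatible pair at all (or too few usable
loci). A consequence of the no-error assumption is fragility: a single
allele miscall typically excludes the true pair. The simulator's
`error_rate` exists to quantify exactly this (substitution errors move
records toward unassigned or ambiguous; they never crash the pipeline).

## Contribution skew

Assigned offspring (only; ambiguous records are excluded rather than
fractionally allocated) are tabulated into the dam×sire family matrix.
Equality of contribution within a sex is tested with the chi-square
goodness-of-fit statistic over **all k candidates** of that sex, zero
contributors included — expectation N/k, d.f. = k−1. Counting
non-contributors in the null is deliberate: the question is whether the
tank's candidates shared reproduction equally, not whether the spawners
did. Percentages are reported both as exact fractions and rounded
half-up to 1 decimal place, matching the convention of printed
contribution tables. Family counts are the number of strictly positive
matrix cells.

## Effective population size

Ne = 4(N−2) / ((Kₛ + Vₛ/Kₛ) + (K_d + V_d/K_d) − 2), where N is the number
of assigned offspring and Kₛ, Vₛ (K_d, V_d) are the mean and variance of
sire (dam) family sizes over the full candidate list. Variances are
**population** variances (divisor k). This convention has the testable
identity K + V/K = Σx²/Σx, making Ne invariant to padding the candidate
list with non-contributors — only realized family sizes matter — and it
reproduces the reference values for the shipped crosses (10.16 and 13.49)
where the sample-variance convention does not. Limits behave classically:
equal contributions by 10+10 parents give Ne → 20 (census) as N grows,
and a single contributing pair gives Ne → 2.

## Diversity statistics

Per locus: A = number of distinct alleles; Ho = fraction of non-missing
genotypes that are heterozygous; He = Nei's unbiased gene diversity
(2n/(2n−1))·(1−Σp²) with n non-missing individuals — equal to the
probability that two distinct gene copies differ, which the tests verify
by enumeration; f = 1 − Ho/He, undefined (NaN/null) at monomorphic loci.
Means over loci are unweighted; mean f averages polymorphic loci only.
Parent→offspring loss is (X_parents − X_offspring)/X_parents on per-locus
values and on the means, alongside the explicit list of parental alleles
absent from the offspring. The estimator choice matters at n = 20 parents
(the 2n/(2n−1) factor is a 2.6% inflation), so absolute diversity values
from other software may differ slightly; ratio-type loss statistics are
much less sensitive.

## Simulator

`SimConfig` defaults emulate the target study design: 9 loci, ~7 alleles
per locus on a dinucleotide size ladder, 10 sires × 10 dams drawn under
Hardy–Weinberg from uniform (optionally Dirichlet-sampled or explicit)
allele frequencies, and cohorts of hundreds of offspring. Families are
sampled per offspring with probability w_dam·w_sire (independent mating);
weights come from an equal model, per-sex symmetric Dirichlet(α) skew, or
explicit vectors; a full dam×sire weight matrix supports non-independent
mating for exact scenario replication. `nonspawner_fraction_*` forces that
share of candidates to weight zero before normalization. `missing_rate`
masks whole locus calls; `error_rate` substitutes single gene copies with
a uniformly chosen other registry allele. All randomness flows through one
`numpy.random.Generator` seeded from the config, so runs are bit
reproducible.

What the simulator does **not** emulate: genotype-dependent survival,
linkage between loci, mutation, null alleles, allele-size binning error,
and batch effects in scoring. Passing recovery tests on simulated data
therefore demonstrate correctness of the inference under its own model,
not robustness to real-world genotyping artifacts beyond the explicit
error/missingness processes.

Preset scenarios: `cross1_like` (mild Dirichlet skew, 9 of 10 dams
spawning, 810 offspring) and `cross3_like` (explicit weights: one dam at
~99.7%, five contributing sires, 570 offspring) bracket the well-behaved
and collapsed regimes observed in practice.

## Shipped count matrices

The four packaged dam×sire matrices come from real 10×10 mass spawnings
genotyped at nine microsatellites. They are stored cell-by-cell; marginals
are always recomputed from cells on load. Known quirks, reported rather
than patched:

- Family counts derived from positive cells (52/42/6/8) exceed the
  narrative counts quoted alongside the originals for three crosses
  (51/40/5); this package reports the matrix-derived counts.
- The cross-4 table's printed row totals are internally shifted relative
  to its cells; the cells are self-consistent with the printed column
  totals and N = 563 and are what ships here. The widely quoted 36.6%
  "dominant pair" share equals the sire-5 column marginal (206/563); the
  pair cell itself is 205/563 = 36.4%.
- Some chi-square values quoted alongside the originals (cross-1 dams 92,
  cross-2 sires 291, cross-4 sires 8594) are not recoverable from the
  matrices under Σ(O−E)²/E (direct computation gives 914.2, 215.2 and
  895.3); likewise the quoted Ne of crosses 3–4 (3.2/3.1 vs computed
  2.46/3.20). The reproducible values (cross-1 sires 617.8≈618, cross-3
  dams 5054.1, cross-4 dams 5007.2, Ne 10.16 and 13.49) anchor the test
  suite; the rest are documented here and excluded from value-level tests.

## Problem sizes and numerical choices

The test suite's simulation scale — 500-offspring crosses for assignment
recovery, 10⁴ draws for HWE calibration checks, 100-replicate sweeps for
the Ne-vs-skew monotonicity, 1000 replicates for the chi-square null
calibration — was chosen so each statistical check has comfortable power
while the whole suite stays interactive on a laptop. Chi-square p-values
come from `scipy.stats.chisquare`; the uniformity of null p-values is
checked by Kolmogorov–Smirnov at α = 0.01 with fixed seeds. Genotype
serialization is canonical smaller/larger allele order, which makes both
the CSV and Genepop round-trips byte-stable. Percent rounding uses
decimal half-up (not banker's) to match printed tables.

## Limitations

- Single-parent assignment, sibship reconstruction and genotyping-error-
  aware likelihoods (CERVUS-style Δ) are out of scope; the error-free
  model is exactly as brittle as its assumption.
- Diversity statistics are within-cohort; no F-statistics across
  populations, HWE exact tests or linkage disequilibrium.
- The Ne formula is the family-size-variance estimator only; no
  inbreeding/variance-Ne distinction, overlapping generations or
  sex-ratio corrections beyond what the formula carries.
- Alleles are assumed pre-binned to integer fragment sizes; raw
  chromatogram calling and size binning are upstream concerns.
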