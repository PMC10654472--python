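# Methods

`domescan` implements two complementary ways of reading domestication out
of population genetic data for farmed fish (gilthead seabream, European
seabass, and comparable aquaculture species): an individual-based
candidate-gene track and a pooled-sequencing chromosome-scan track, with
a drift null and a depth-calibration simulation supporting them.  This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic data can and cannot establish.

## Gene-level track

**Data model.** Diploid genotypes at one or a few candidate SNPs, sampled
in small population samples (typically 2–9 individuals), each population
labelled with origin (farmed / wild) and collection period (binary:
2004–2007 vs 2012–2016).

**Frequencies.** Allele and genotype frequencies are tabulated per
population × locus; populations left empty after dropping missing
genotypes are excluded with a logged warning.

**Wilcoxon test.** Farmed and wild groups are compared at the population
level (the sampling unit is the population frequency, not the
individual), two-sided.  For combined group sizes ≤ 12 the p-value is
computed by exact permutation enumeration of all C(n, n₁) group
assignments using midranks, which handles ties without an approximation;
above that, the normal approximation with tie correction
(`scipy.stats.mannwhitneyu`) is used.  Whether the per-population value
is an allele frequency or a genotype-class frequency is a flag
(`mode="allele"` default; `mode="genotype"` compares one genotype class).

**Hardy–Weinberg.** The default is the exact conditional test: the
distribution of the heterozygote count given the allele counts,
p-value = sum of probabilities of outcomes no more likely than the
observed one.  The exact test is the right default at the sample sizes
here (n ≈ 30–60 per origin group after pooling populations); the 1-df
chi-square is available by flag.  Tests are exposed per locus per origin
group; no cross-locus pooling is attempted.

**GLM and model selection.** Per population, the response is the
two-column count (reference allele, other allele), with the reference
level fixed to the most frequent allele among farmed populations (ties
broken lexicographically and logged).  A binomial GLM with logit link
(statsmodels) is fitted over the model lattice {1, origin, time,
origin+time, origin×time}, and AIC = −2·logL + 2·npar drives a
bidirectional stepwise search starting from the full interaction model.
AIC ties are broken toward fewer parameters.  Complete separation is
detected (fitted probabilities at the boundary or extreme coefficients)
and flagged rather than raised, since separated fits still order models
usefully.

A calibration fact worth knowing: AIC stepwise selection is not
consistent.  Under a pure null each superfluous term survives with
probability ≈ P(χ²₁ > 2) ≈ 0.16, so the intercept-only model wins only
about 55–60% of null replicates across this lattice.  The test suite
asserts that calibration (intercept modal, interaction rarely chosen),
not a near-certain intercept win.

## Bottleneck null (false-positive rate)

Farmed stocks of both species went through documented hatchery
bottlenecks: effective size dropping from ~10⁶ (seabream) / ~10⁴
(seabass) to ~100 individuals, roughly 5–10 generations ago.  The null
asks: with no selection at all, how often does the farmed-vs-wild test
reject?

* **Demography.** Instantaneous drop to `nb` (default 100) held for `G`
  generations (default 8, the midpoint of the documented 5–10), then
  sampling.  Pre-bottleneck drift at the wild effective size is skipped:
  its per-generation variance is ~1/(2·10⁶) and immaterial.  Mutation is
  ignored (conserved candidate genes, few generations); 0 and 1 are
  absorbing.
* **Update rule.** Binomial resampling of 2·nb chromosomes per
  generation, giving the standard Wright–Fisher variance
  p(1−p)(1−(1−1/(2nb))^G), which the tests verify empirically.
* **Per replicate.** The wild frequency is drifted; a farmed sample of
  2·n_f alleles is drawn at the post-drift frequency and a wild sample of
  2·n_w alleles at the ancestral frequency (defaults n_f=37, n_w=54, the
  candidate-gene design); the two-sided Fisher exact test is applied to
  the 2×2 allele-count table.  FPR(α) = fraction of replicates with
  p < α.  Comparing against fixed expected wild counts instead of a fresh
  wild sample is a flag (`compare="observed-wild"`); a genotype-level 3×2
  exact contrast (Freeman–Halton, direct enumeration) is also available.

With no drift the exact test is conservative (FPR ≤ α by discreteness);
the bottleneck inflates the 5% FPR several-fold while the 1% FPR stays
low — the pattern that motivates stricter thresholds for farmed-vs-wild
contrasts.

## Depth calibration

In Pool-Seq each read is one draw from the pooled individuals.  The
calibration simulates: draw `depth` reads uniformly with replacement over
`pool_size` diploid individuals, count distinct individuals, repeat
(default 10⁶ replicates).  The closed-form mean P(1−(1−1/P)^D) anchors
the simulation in tests.  For the reference design (P = D = 25) the mean
is 15.99 and the 2.5% quantile is 13 — i.e. 25 reads represent more than
half the pool even at the lower 95% confidence limit, which is the
justification for the depth-25 site filter.  "Samples" are interpreted as
diploid individuals, not chromosomes; the lower "95% confidence limit" is
the 2.5% quantile of the simulated distribution (a one-sided 5% quantile
is a flag).  `choose_min_depth` scans depths upward and returns the first
whose lower bound covers `ceil(target_fraction · pool_size)`.

## Pool-Seq ingestion and SNP calling

Two per-position count dialects are parsed exactly: bam-readcount-style
(`chrom pos ref depth base:count[:extras…]`, extras ignored) and
PoPoolation2 sync (`A:T:C:G:N:del` per pool; N and deletions parsed but
never called as alleles).  Technical replicates are merged by summing
counts per position (outer join; conflicting reference bases are an
error).

Biallelic calling, per site: drop the site if any pool's total depth
(A+C+G+T) is below `min_depth` (default 25) — pairwise statistics
downstream need every pool covered; a per-pool masking mode is a flag.
Base frequencies are then computed on counts pooled across populations
(per-pool mode by flag), bases under `min_allele_freq` (default 1%,
a sequencing-error guard) are discarded, and the site is emitted iff
exactly two bases survive.  Major = more frequent base overall, ties
alphabetical and logged.  Coordinates are 1-based inclusive throughout;
BED exports convert to 0-based half-open.

## Scan statistics

* **Pooled π.** (1 − p² − q²)·C/(C−1) from read frequencies at depth C;
  undefined below depth 2.  The C/(C−1) factor is the finite-depth
  correction used by Pool-Seq diversity estimators.
* **FST.** (π_T − mean(π_A, π_B))/π_T with π_T from the pools' summed
  counts.  Reported two ways per SNP: the mean over all farmed×wild pool
  pairs, and the combined-pool value (counts summed per origin), the
  headline column.  Because of the C/(C−1) correction, identical pools
  give a small negative value of order −1/C rather than exactly zero;
  negatives are reported as computed (an optional clamp exists for
  plotting).  Sites monomorphic across both pools are masked (NaN).
* **Fisher exact.** Two-sided hypergeometric-sum test on summed farmed vs
  wild counts, implemented over a cached log-factorial table (the scan
  runs tens of thousands of tables per chromosome); probabilities within
  a 1e-7 relative tolerance of the observed table count as "as extreme"
  (the R convention).
* **CMH.** χ² = (|Σ_k (a_k − E a_k)| − ½)² / Σ_k V_k over K farmed/wild
  pool-pair strata, p from χ²₁.  The continuity correction is on by
  default and the numerator is not clamped at zero, matching R's
  `mantelhaen.test` (which the field's reference tooling calls);
  verified against statsmodels to 1e-8.  Default pairing: i-th farmed
  with i-th wild pool after sorting pool ids; an explicit stratum column
  in the manifest overrides it.
* **BH adjustment.** Step-up with monotonicity enforcement, applied
  across all SNPs of the scanned chromosome.
* **Rolling track.** Centred moving mean over a window counted in SNPs
  (default 5000), edges truncated, masked values skipped.
* **Peaks.** Global maximum of the track; within the winning window, the
  SNP maximising the per-SNP statistic, its BH-adjusted p, significance
  stars at 0.05/0.01/0.001, and genes whose spans intersect ±`flank`
  (default 50 kbp) around the peak.

BayPass's XtX statistic is deliberately not reimplemented; the scan
tables are structured so an external XtX column can sit alongside.

## Synthetic data

`generate_gene_level` defaults to the candidate-gene sampling layout
(11 wild populations totalling 54 individuals, 9 farmed totalling 37,
split over the two collection periods); genotypes are two independent
Bernoulli draws at the population frequency (Hardy–Weinberg).  Farmed
frequencies are either fixed or produced by an independent bottleneck
pass per farmed population (independent hatcheries).

`generate_poolseq` defaults: 4 farmed + 4 wild pools of 25 individuals
with 2 technical replicates, 20,000 SNPs on a 20 Mb chromosome, mean
depth 60.  Per SNP: wild frequency ~ Beta(0.8, 0.8) (a mildly U-shaped
spectrum typical of site-frequency data; the real spectrum is unknown,
so this is a modelling choice, not an inference), farmed frequency = wild
passed through one shared bottleneck (so the null carries realistic drift
noise; `farmed_null="identical"` gives a pure null), and inside an
optional selected region the farmed frequency is the wild one shifted by
δ toward the more distant boundary, making the truth-table divergence
exactly δ.  Pool counts: binomial draw of 2n chromosomes, read depth
negative-binomial (mean 60, dispersion 5 — overdispersion mimics real
coverage), read counts binomial at the sampled frequency, reads split
uniformly over replicates with exact conservation.  SNP positions are
uniform without replacement, sorted.  A truth table and a minimal GFF3
(gene features with ID/Name only, plus a gene centred in the selected
region) accompany every dataset.

**What the generator does not model:** linkage disequilibrium between
SNPs, sequencing error, mapping artefacts, unequal DNA contribution of
pooled individuals, or read-level data.  Passing recovery tests therefore
show that the statistics find the kind of signal they were designed for
at realistic depth and pool sizes — not that the pipeline is robust to
alignment or library artefacts, which are upstream of its inputs.

## Problem sizes used in the checks

The recovery analysis runs 20 seeded replicates of the default Pool-Seq
configuration with a δ=0.3 region spanning ~500 SNPs, asks the rolling
combined-FST track (window 500 SNPs, matched to the injected region's
SNP count) for its global peak, and requires ≥90% of peaks inside the
region plus enrichment of BH-significant CMH SNPs there.  The bottleneck
null calibration uses 2000 replicates; the depth calibration 10⁵
replicates in tests and 10⁶ in the reproduction script.  A 5000-SNP
window — the right scale for chromosome-length scans of ~10⁵–10⁶ SNPs —
would dilute a 500-SNP region 10:1 by construction, so window choice
should track the scale of the signal sought.

## Known limitations

* The CMH pairing of farmed and wild pools is arbitrary under the
  default (sorted order); when a meaningful pairing exists (shared
  country, batch), pass it via the manifest.
* The per-SNP Fisher test on summed counts treats reads as independent
  allele draws, ignoring that reads within a pool share the pool's
  sampling noise; the CMH over pool pairs is the more honest test and is
  the one used for peak significance.
* Gene-level GLM aggregates allele counts per population (proportions
  model); individual-level random effects are out of scope.
* The stepwise search is over a 5-model lattice only; there is no
  general formula interface.
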