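# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
`sproutval`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Phenotype

The germination index of a plot is `GI = (6·n3 + 3·n6)/(6·N)` with `n3`
seeds germinated by day 3, `n6` the *incremental* count germinating
between day 3 and day 6, and `N` seeds tested. Readers holding
cumulative day-6 counts must convert before constructing
`PlotGermination` records; the incremental convention is enforced
because the two cohorts carry different weights. Tests with `N ≠ 40`
are accepted with a logged warning — the statistic generalizes even
though the standard assay fixes `N = 40`. GI is carried at full float
precision everywhere; rounding (2 decimals, half away from zero,
`round_half_away`) happens only in rendered reports.

## Variance components, BLUPs, heritability

Within an environment the RCBD model `Y_ik = µ + g_i + r_k + ε_ik` is
fitted with genotype and block random (a fixed-block option exists:
`fit_within_env(..., replicate_fixed=True)`). Across environments all
effects of `Y_ijk = µ + g_i + e_j + r_k(e_j) + (g×e)_ij + ε_ijk` are
random.

Estimation is REML with non-negativity constraints:

* **Balanced data.** The REML likelihood factorises over the ANOVA
  strata: each stratum contributes `df·ln(θ) + SS/θ` with θ the
  expected mean square, a known non-negative linear combination of the
  components. The criterion is minimised with L-BFGS-B under bound
  constraints, started at the truncated expected-mean-squares (EMS)
  estimates. At an interior optimum this *is* the EMS solution, which
  doubles as the cross-check in the tests; on the boundary it is the
  constrained REML fit (negative moment estimates truncate to zero).
* **Unbalanced data** (missing plots) fall back to a dense-covariance
  REML criterion `ln|V| + ln|X'V⁻¹X| + y'Py` optimised on log-variances
  (Nelder–Mead); components below ~1e-7 of the phenotypic variance are
  snapped to zero. This path is O(n³) per evaluation and intended for
  the mildly incomplete designs that occur in practice, not for large
  heavily unbalanced data.

BLUPs solve Henderson's mixed-model equations at the estimated
components. A relative ridge of 1e-10 × var(y) on the residual keeps
the system well-posed when the residual variance estimate is zero; in
that regime shrinkage vanishes and BLUPs approach unshrunken group
means, which is the correct limit.

Heritability on an entry-mean basis is
`h² = σ²_g / (σ²_g + σ²_g×e/e + σ²_ε/(e·r))`; it errors when all three
variances are zero. `variance_shares` reports integer-percent shares of
the four-term total σ²_g + σ²_e + σ²_g×e + σ²_ε, computed from the
*unrounded* estimates (shares recomputed from already-rounded component
tables can differ by a point).

Environment means are compared on the per-environment genotype BLUPs
under the two-way fixed model `Y_ij = µ + g_i + e_j + ε_ij`; Tukey's
studentized-range test at α = 0.05 with the Kramer harmonic correction
when genotype coverage is unbalanced. Compact letters use the
insert-and-absorb construction; letters are assigned following the
display order (descending mean for environment tables, ascending for
haplotype tables, matching how such tables are conventionally printed).

## Marker QC

Rates follow inbred-panel conventions: missing rate over all genotypes,
heterozygosity among non-missing calls, MAF among homozygous calls only
(heterozygous calls in an inbred panel are seed mixtures or assay
artefacts, not genotypes). The exclusion cascade is missing →
heterozygosity → monomorphy → MAF, each marker labelled with the first
failing filter; it is idempotent on the retained set. Default cut-offs
`max_missing = 0.20`, `max_het = 0.05`, `min_maf = 0.03` — chosen so
that assays with moderate missingness (up to ~16 %) survive while
failed assays (≥ 70 % missing), grossly heterozygous assays (> 30 %)
and ultra-rare alleles (2 %) are excluded; all three are config-exposed
and logged.

Strand harmonization maps calls and allele labels of flagged markers
through A↔T, C↔G (an involution); it errors on non-nucleotide (indel)
alleles. Complete LD is declared when two markers' allele classes
partition the shared non-missing homozygous genotypes identically
(the class cross-table is a permutation pattern, i.e. squared allelic
correlation 1); both markers must be polymorphic on the shared set, and
grouping is closed transitively (union-find).

## Association and stability

Per marker and fit, OLS of genotype BLUP GI on a 0/1 allele indicator.
For a binary predictor the slope equals the difference of class means
and R² the squared point-biserial correlation — this closed form is the
test oracle. The tolerant allele is chosen *per fit* as the lower-mean
class (ties break lexicographically); the across-environment
orientation is the one reported. Significance is a two-sided t-test on
the slope at α = 0.05, no multiple-testing correction by default
(candidate-marker validation tests a small fixed panel; a Bonferroni
option would be a caller-side α adjustment). Genotypes missing a call
are dropped pairwise per marker. Stability = significant in ≥ 2
environments with the same tolerant allele in every significant
environment.

## All-subsets AIC

The candidate pool is the stable markers with one representative per
complete-LD group (first stable member in input order). All `2^p − 1`
non-empty subsets are fitted by OLS on tolerant-allele indicators over
a single complete-case genotype set (the union of pool markers), so
RSS-based AICs are comparable across subsets. `AIC = n·ln(RSS/n) +
2(k+1)`; the Gaussian constant is omitted as it cancels in rankings,
so absolute values are comparable only within a run. Rank-deficient
subsets are skipped with a log entry; AIC ties under 1e-9 break toward
the smaller subset, then lexicographic order. A guard refuses pools
above 20 markers. Note the selection behaviour inherent to AIC: a
spurious predictor joins the best model whenever its likelihood-ratio
improvement exceeds 2 (probability ≈ 0.16 per null marker), so the
rank-1 model frequently contains one extra small-effect marker; what is
reliable is that a real large effect is always included and dominates
the single-marker ranking.

## Haplotypes and selection efficiency

Genotypes with a missing or heterozygous call at any of a model's
markers are excluded; each observed allele combination forms a class,
classes of one genotype are flagged rare and excluded from mean
comparisons. The comparison model — haplotype, environment and their
interaction fixed, genotype within haplotype random — is evaluated via
its stratum decomposition, valid when every genotype has a BLUP in
every environment (which per-environment BLUP tables guarantee):
haplotype contrasts live in the genotype-within-haplotype stratum, so
Tukey–Kramer on class means of per-genotype across-environment means
with containment degrees of freedom (N_genotypes − k classes) is the
exact test, with no iterative df approximation. LSMeans are the class
means of genotype means.

Selection efficiency compares the best (lowest-LSMean) haplotype class
with the tolerant class of the best single marker: a two-sided Welch
t-test on member across-environment BLUPs (reported as NA when a class
has < 2 members), and each set's overlap with the top-20 % benchmark —
the ⌊0.2·n⌋ genotypes with lowest across-environment BLUP GI, ties
broken by genotype id and logged. Differences in overlap counts are
reported descriptively; no significance test is attached to them by
default.

## Synthetic data

The generator emulates a 200-genotype × 4-environment × 2-replicate
validation study with 40-seed germination tests and a 38-marker KASP
panel: 22 clean polymorphic markers (a large-effect dormancy locus at
tolerant-allele frequency 0.58 with effect −0.14 GI, several
small-effect loci at −0.07…−0.08 — magnitudes that produce ~−20 %
relative changes, typical of validated minor loci — two complete-LD
pairs, one emitted on the complementary strand, and 13 nulls), plus the
contamination block: six assays at 70–95 % missing, two at 32.5 % and
65.5 % heterozygosity, seven monomorphic, one at MAF 0.02.

Latent plot means are `m = µ + Σ marker effects (centred) + polygenic +
e_j + (g×e)_ij + r_k(j) + ε`, truncated to [0.02, 0.98] (the bounds
mirror observed GI ranges in such trials). Marker contributions are
centred on their population mean so µ (default 0.35) stays the grand
mean. Generating components default to σ²_g(total) = 0.031 split
between markers and a polygenic remainder, σ²_e = 0.015, σ²_g×e =
0.018, σ²_rep = 0.001 (small block variance typical of well-managed
trials; component tables in such studies usually omit it), σ²_ε =
0.003.

Germination counts are binomial given m: with equal day-3 and day-6
cohort probabilities, `E[GI] = π3(3 − π3)/2`, so `π3 = (3 − √(9 −
8m))/2` in closed form. A beta-binomial overdispersion switch exists
and is off by default. `exact_counts=True` realizes marker frequencies
and contamination rates as exact counts at seeded positions — used for
the QC fixture whose composition must be seed-independent; the default
is Bernoulli sampling, which is what real panels look like.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: partial LD between linked markers
(complete-LD pairs are copied, not recombined, so the inflation of
marginal effects by linkage to a major locus is absent), population
structure and kinship, dominance/heterozygosity effects (the panel is
inbred by construction), spatial field trends, and seed-to-seed
correlation within a test beyond the optional beta-binomial switch.
Two measurable consequences, quantified in the tests: the binomial
counting process adds `p(1−p)[(2−p)²+(1−p)]/(4N)` ≈ 0.0045 GI² to the
plot residual at N = 40, and truncation of extreme latent means
attenuates recovered genotypic variance by roughly 20 %; h² recovery is
nonetheless accurate to ~0.02 (median). With only four environments the
environment-variance draw itself scatters widely (3 df), so recovery
tests target the *realized* variances recorded in
`GroundTruth.realized_components`.

## Problem sizes and runtime

The default study size (200 × 4 × 2, 38 markers) runs the full pipeline
in a few seconds on one CPU. Property tests use 20–100 seeds at the
default size for parameter-recovery medians and smaller constructed
fixtures for exact oracles; the complete suite finishes in a few
minutes.

## Known limitations

* The unbalanced REML path is dense and slow beyond a few thousand
  plots.
* The haplotype mixed model's stratum shortcut assumes complete
  environment coverage of the response; with incomplete coverage it
  uses available-environment means and logs a warning rather than
  refitting a general mixed model.
* Tukey–Kramer letters for many small haplotype classes are
  conservative (wide intervals, heavily shared letters) — a property of
  the method, not a defect, but worth knowing when a top model contains
  four or more markers.
* Absolute AIC values depend on the omitted Gaussian constant and are
  not comparable across software.
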