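# Methods

`hybridtrace` re-implements, as one tested pipeline, the analytical chain
used to detect historical species replacement in a two-species newt contact
zone: design of a species-diagnostic SNP panel from transcriptome exon
matches, validation of that panel by chance-corrected agreement, detection
of admixture and of its population-genetic side effects (heterozygote
deficit, admixture linkage disequilibrium), Structure-style ancestry
inference with Evanno model choice, genotype ordination, and a two-species
climate distribution model with hindcasting. Every stage runs on synthetic
data whose generators are first-class, tested code.

## Data model

Genotypes live in a `GenotypeMatrix` of allele *dosages*: the per-individual
count of the species-M (*Triturus marmoratus*-diagnostic) allele, 0/1/2 at
diploid nuclear loci and 0/1 at the haploid mtDNA marker, with NaN as the
missing sentinel. Counting the M allele makes the admixture proportion Q_m
and the first PCA axis directly interpretable: dosage 0 is a pure
species-P homozygote. The mtDNA marker is excluded from diploid-only
statistics (Hardy-Weinberg, genotypic and admixture LD) automatically via
the per-locus ploidy flag, and enters the admixture likelihood with
ploidy 1.

## Synthetic generators

The generators reproduce the statistical structure the analyses assume,
not the biology that produced it:

* **Reference panels.** Two pure cohorts (defaults 118 and 120 individuals
  across 43 reference populations) genotyped at 60 nuclear SNPs of which 54
  are diagnostic (parental allele-frequency differential `delta`, default
  1.0, i.e. fixed differences) plus a fixed-difference haploid mtDNA
  marker; the remaining six nuclear loci carry a background differential of
  0.2, making them informative but not diagnostic. Missing calls are masked
  i.i.d. at 2.3%, the panel's empirical missing-data rate.
* **Admixed landscapes.** Each individual draws an admixture proportion q
  around its population mean (clipped normal, sd 0.02) and then draws every
  allele copy independently from the species-M pool with probability q —
  exactly the likelihood the admixture model assumes, so parameter recovery
  is a clean test. The default landscape is an admixed enclave (q = 0.93,
  mirroring the reported enclave Q_m of about 0.93) inside a pure
  species-P peninsula of 30 ponds with 11 individuals each. An optional
  introgression tail q(d) = q0·exp(−d/λ) imposes a geographically decaying
  footprint; the tail is imposed, not emerged — there is no forward-time
  migration/drift simulation. Family sampling (full-sib families sharing
  two simulated parents, offspring by Mendelian segregation) is the single
  mechanism that violates the allele-independence assumption; it produces
  the heterozygote deficits and admixture LD expected when larvae are
  sampled from small breeding ponds.
* **Environmental localities.** The driver (bio17, precipitation of the
  driest quarter, mm) is uniform on [0, 100]; species labels are Bernoulli
  with p_M = 1/(1 + exp(−0.156·bio17 + 7.767)), the published two-species
  model. Nuisance climate variables are monotone-plus-noise transforms of
  the driver, calibrated by bisection on the mixing weight to a target
  Spearman correlation within ±0.02 (a ±1 target returns an exact monotone
  transform).

What passing tests on these data do *not* show: robustness to genotyping
error, null alleles, non-equilibrium allele-frequency structure within
species, spatially autocorrelated climate residuals, or presence-only
sampling bias — none of which the generators emulate.

## Marker design

Each transcriptome contig contributes at most one candidate exon, chosen to
avoid untranslated sequence. Exons matching more than twice in the
reference gene model are priority 1 (with exactly three matches the central
exon is chosen; with more, a seeded uniform draw among interior exons —
never the first or last); two matches are priority 2 (longest exon); a
single match is priority 3, kept but deprioritised rather than excluded.
The interior-exon draw is seeded per contig (hash of seed and contig id),
so results do not depend on input order. Candidates outside 100–400 bp
(inclusive bounds — "minimum" and "maximum" naturally include their
endpoints) are dropped. Ranking to the target panel size (default 192)
removes multi-hit and duplicate-contig candidates, then sorts by priority,
e-value, percent identity (descending), gap count, and finally contig id;
the composite order is this package's choice — the underlying criteria are
standard BLAST hit metrics with no canonical ordering.

## Diagnosticity

Each observed allele copy in the reference panel is one observation whose
allele identity "predicts" its carrier's species; Cohen's κ of the 2×2
allele × species table is the diagnosticity score. Scoring is per allele
copy (heterozygotes contribute one count to each allele column; haploid
loci one copy per individual), a documented choice — a per-individual
variant is deliberately not provided. A marker is diagnostic at κ ≥ 0.9
(inclusive), informative if the species differ at all in allele frequency.
When both table margins are degenerate (expected agreement 1), κ is defined
as 1 for a diagonal table and 0 otherwise, so a fixed-difference marker
with no missing data scores exactly 1.

## Population-genetic tests

* **Hardy-Weinberg.** The exact conditional test for a biallelic locus,
  computed by full enumeration with exact integer weights
  n!/(n_MM! n_MP! n_PP!)·2^{n_MP}; the two-sided p-value sums
  configurations no more probable than the one observed. Integer
  arithmetic makes probability ties exact — there is no Monte-Carlo chain
  to tune.
* **Genotypic LD.** A G-test on the 3×3 genotype table of a locus pair with
  a permutation null, p = (1 + #{G* ≥ G})/(B + 1) (B defaults to 999; the
  minimum attainable p is 1/(B+1)). A monomorphic locus yields p = 1 by
  convention. Benjamini-Hochberg correction is applied per test family
  within population; pooled summaries are also reported.
* **Admixture LD.** Barton & Gale's mixing signal is estimated as the mean
  over locus pairs of the covariance of scaled dosages x = dosage/2, with
  pairwise deletion for missing calls and the maximum-likelihood (1/n)
  covariance, so a 50/50 mix of the two pure species at fixed loci gives
  exactly 0.25 per pair. The 95% CI is a percentile bootstrap over
  individuals (default 1,000 replicates, seeded and exactly reproducible);
  a population is flagged when the CI excludes zero. Percentile bootstraps
  of covariance-type statistics under-cover: under panmixia the nominal 95%
  CI covers zero in roughly 86% of ponds at n ≈ 30 and about 93–94% at
  n = 100–400 on the 54-locus panel (normal, basic and expanded-percentile
  intervals measure the same 93–95% under identical conditions, so the gap
  is intrinsic to bootstrapping this mean-of-covariances statistic, not a
  choice among interval types). The calibration test checks the coverage
  rate against the binomial acceptance band of the nominal level at
  n = 100; significance calls in very small ponds should be read as
  indicative.

## Admixture model

The admixture likelihood is
P(g_il) = Binomial(ploidy_l, Σ_k q_ik·p_kl): individual i draws each allele
copy from cluster k with probability q_ik and that copy is the species-M
allele with probability p_kl. Inference is maximum-likelihood EM on (Q, P)
— the same estimand as Structure's Bayesian MCMC under the admixture model,
but deterministic per seed and desk-scale. Missing genotypes are skipped in
the likelihood; Q is initialised Dirichlet(1), P uniform on (0.05, 0.95);
convergence at ΔlogL < 1e-6 (default cap 2,000 iterations); the EM
log-likelihood is non-decreasing by construction and asserted in tests.
Random restarts (default 10, best logL kept) stand in for MCMC replicates;
the replicate spread across restarts feeds the Evanno statistic
ΔK = mean(|L″(K)|)/sd(L(K)), L″(K) = L(K+1) − 2L(K) + L(K−1) on replicate
means, defined only for interior K. Degenerate replicates (sd = 0) raise an
error rather than dividing by zero; K = 1, which Evanno cannot evaluate, is
compared separately by log-likelihood. Individuals are classified from the
species-M cluster proportion: pure at Q_m > 0.95 or < 0.05 (strict), with
boundary values counted admixed. Per-population Q_m is the mean over
individuals. The species-M cluster is identified as the one with the higher
mean allele frequency, which is unambiguous whenever the panel is
M-oriented by the dosage convention.

## Ordination and score surfaces

PCA runs on the individuals × loci dosage matrix: column-mean centring,
column-mean imputation of missing calls (at ~2% missingness, imputation
shrinkage is negligible and preferable to dropping individuals), SVD, and a
deterministic sign rule (largest-magnitude loading positive). Group
summaries are per-group componentwise mean ± sd, the ellipse convention of
the original figures. The geographic surface of scores is weight-scaled
inverse-distance-squared interpolation, value = Σ w_i·d_i^{-2}·v_i / Σ
w_i·d_i^{-2}, with population sample size in the weight slot; a cell
coincident with a data point takes that point's value. The original
contouring software's algorithm is unpublished; weighted IDW is this
package's declared interpolation, and the surface is a convex combination
of the data values by construction.

## Two-species distribution model

Predictors are pruned for collinearity before selection: UPGMA
(average-linkage) clustering of 1 − |r_s| with the dendrogram cut at
|r_s| = 0.7, keeping per cluster the variable with the lowest mean |r_s| to
the variables outside its cluster (ties by name) — the representative rule
is this package's choice. Selection is forward stepwise logistic regression
under the likelihood-ratio criterion, p_in = 0.05 and p_out = 0.10, ties
broken by candidate order, with a state-hash guard against cycling (the
constraint p_in ≤ p_out is also enforced in the configuration). The
logistic primitive is Newton/IRLS maximum likelihood; complete separation
raises an explicit error. Fit is summarised by AUC in the Mann-Whitney
formulation (ties count one half) with the Hanley-McNeil standard error.
Hindcasting applies the fitted logistic to raster climate sets, thresholds
at p_M = 0.5 into binary maps, and sums the binaries into a cumulative grid
(0..n_sets) so the stepped scale counts how many climate reconstructions
support presence; nodata propagates through every step. The fitted model
prints in the published convention p_M = 1/(1 + exp(a·x + b)), where
(a, b) are the negated standard logit coefficients.

## Problem sizes and numerical choices

Simulation-backed tests use the study's scale where the quantity under test
depends on it (354 individuals × 54 loci for ancestry recovery; 10,000
localities for coefficient recovery; 5,000 per class for the AUC benchmark)
and smaller two-population landscapes (2 × 30 individuals, 30 loci) for the
K-selection pipeline, where cluster separation, not sample size, drives the
answer. Key defaults: EM tolerance 1e-6 logL units; bootstrap and
permutation counts 1,000 and 999; probability clipping at 1e-12 in the EM
likelihood; PCA sign rule as above. Per-individual ancestry estimates at L
fixed loci carry irreducible binomial noise of sd √(q(1−q)/2L) (~0.05 at
q = 0.5, L = 54), which bounds how tightly any per-individual recovery can
be asserted.

## Known limitations

Multi-allelic loci, genotyping error models, LOCPRIOR-style informed
priors, replicate alignment beyond best-logL selection (CLUMPP), kriging
or spline contouring, presence-background (Maxent-style) distribution
modelling, and geodetic reprojection are all out of scope. The stepwise
entry test is a per-candidate α = 0.05 likelihood-ratio test; with several
candidates the familywise entry rate is correspondingly higher, which is a
property of the published procedure itself.
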