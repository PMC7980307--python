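# Methods

`skyisland` re-implements, as one tested library, the integrated analysis
used in genetic-monitoring studies of sky-island mammals: population-genetic
summary statistics for mixed microsatellite + mtDNA data, circuit-theory
landscape genetics with mixed-model hypothesis ranking, approximate Bayesian
computation (ABC) over competing demographic scenarios, and range-change
accounting from binarized habitat-suitability maps. A synthetic-data module
generates complete five-site "sky-island" study systems with known ground
truth so every stage can be exercised and calibrated without field data.

## Population-genetic statistics (`skyisland.popgen`)

Haplotypes are exact sequence-identity classes; `N`/`-` are ordinary
mismatching states unless `ambiguous_merge` is set, in which case a sequence
is merged into the first haplotype it is compatible with and the more
resolved base is retained. Haplotype diversity is Nei's unbiased gene
diversity `n(1 - sum p_i^2)/(n-1)`; nucleotide diversity and Dxy use
pairwise deletion of gaps and ambiguous sites. Between-population sequence
differentiation is Hudson's `F_ST = 1 - mean(pi_within)/pi_between` with the
unweighted mean of the two within-population diversities; for identical
polymorphic pools the estimator's small-sample expectation is `-1/(n-1)`,
which the tests treat as "approximately zero" at moderate `n`.

Microsatellite expected heterozygosity is Nei's unbiased estimator on gene
counts (`N/(N-1)(1 - sum p^2)`, `N` = non-missing gene copies). Rarefied
allelic richness follows the hypergeometric formula
`Ar(g) = sum_i [1 - C(N - N_i, g)/C(N, g)]`, averaged over loci; the default
`g` is the smallest per-locus non-missing gene count over populations, and
loci with fewer than `g` copies in a population are dropped from `Ar` with a
warning. Private alleles are allele-by-locus combinations observed in
exactly one population.

Individual inbreeding is a maximum-likelihood coefficient `F` on `[0, 1]`
maximizing `prod_loci P(genotype | F)` with `P(hom_i) = p_i^2 + F p_i(1-p_i)`
and `P(het_ij) = 2 p_i p_j (1-F)`, using the individual's own population
allele frequencies (bounded scalar optimization plus explicit boundary
checks). This replaces triadic-likelihood relatedness estimators: it answers
the same monitoring question (relative inbreeding levels per population)
without the full pairwise-relatedness machinery, so absolute values are not
comparable with TrioML output.

Hardy–Weinberg tests are Monte-Carlo exact: gene copies are re-paired at
random within the population and the observed heterozygote count is compared
two-sidedly to its permutation distribution (`(1 + #extreme)/(n_perm + 1)`;
monomorphic loci return `p = 1` by convention; the seed is mandatory).
Null-allele frequency is Chakraborty's `r = (He - Ho)/(He + Ho)` floored at
zero. A locus is flagged for dropping when HWE is rejected at `alpha = 0.01`
or `r > 0.2` in more than half of the populations.

Multilocus `F_ST` is Weir & Cockerham's theta, `sum a / sum(a+b+c)` over
loci and alleles, reported raw (possibly negative) and clamped to `1e-6`
only before log-transformation in the landscape module. Jost's `D_est` uses
Nei–Chesser bias-corrected `Hs`/`Ht` per locus and a harmonic mean across
loci; because a harmonic mean is undefined for non-positive values,
per-locus `D` is floored at zero and any zero-`D` locus yields a multilocus
`D` of zero (identical populations then report `D = 0`, as they should).

## Landscape genetics (`skyisland.landscape`)

A resistance surface assigns each raster cell a movement cost in `[1, 100]`
via a cost scheme (categorical lookup or half-open value bins; unmapped
values raise). The raster graph connects 8-neighbours by default; the edge
conductance between cells `a, b` is `1/mean(r_a, r_b)`, divided by `sqrt 2`
on diagonals. Effective resistance between population cells is computed
exactly by sparse LU factorization of the grounded graph Laplacian (one
factorization per connected component, reused for all pairs); disconnected
pairs are infinite with a warning. Test oracles compare against the dense
Laplacian pseudo-inverse (`R_ab = L+_aa + L+_bb - 2 L+_ab`) to `1e-8`.
Current-density maps assign each cell half the sum of absolute currents on
its incident edges under a unit source/sink injection, summed over pairs, so
a cell on a single series path carries current 1.

MRDM regresses the vectorized lower triangle of a distance matrix on
predictor triangles; significance comes from simultaneous row/column
permutations of the response (p-values for `R^2` and per-coefficient `|t|`).
Cost-scheme selection ranks candidates by MRDM `R^2` against genetic
distance, breaking ties toward the lexicographically smallest scheme label.
Genetic distances are normalized for geography as
`ln(G_ij)/ln(E_ij)` with Euclidean distances in projected metres (values
`<= 1` are rejected; non-positive `G` clamped to `1e-6`).

The MLPE model is `y_ij = b0 + sum b_k x_k,ij + u_i + u_j + e_ij` with iid
population effects shared by all pairs containing the population. It is
fitted by full maximum likelihood (not REML) so likelihoods are comparable
across fixed-effect structures: the variance ratio
`lambda = sigma_u^2/sigma_e^2` is profiled (GLS for the coefficients, ML
residual variance) and optimized in one dimension over `log lambda` in
`[-12, 12]` with an explicit boundary check at `lambda = 0`. Predictors are
log-transformed; with two or more predictors, variables with VIF >= 4 are
dropped iteratively. Coefficient intervals are Wald 95% from the GLS
covariance. Model comparison uses
`AICc = -2LL + 2k + 2k(k+1)/(n-k-1)` and `BIC = -2LL + k ln n`, with `n` the
number of population pairs and `k` counting intercept, slopes and the two
variance components; evidence weights are `exp(-delta/2)` normalized.

## Demography and mutation (`skyisland.demography`)

Two sampled demes, S (south-east of the barrier) and N (north-west), merge
into an ancestor A at `t_split` generations; four scenario variants add
no change (1, with `N_A >= max(N_S, N_N)` — a large ancient population),
expansion (2, `N_A < min`), a recent decline in both demes (3) or in S only
(4) at `t_dec` with pre-decline sizes `N_S0` (`N_N0`). Priors (all
overridable): sizes uniform `[100, 100000]` diploids; `t_split` uniform
`[100, 100000]` generations (200–200,000 years at the 2-year generation
time); `t_dec` uniform `[10, 500]` generations (20–1,000 years); mean
microsatellite rate log-uniform `[1e-4, 1e-3]`; GSM geometric parameter `P`
uniform `[0, 0.3]`; mtDNA rate log-uniform `[1e-8, 1e-7]`/site/generation.
Scenario ordering constraints are enforced by rejection-resampling the whole
vector.

Genealogies come from a dedicated structured-coalescent simulator for this
scenario family (piecewise-constant sizes, one merge). The specialization is
deliberate: ABC reference tables need tens of thousands of independent
single-locus genealogies per analysis, and a general-purpose simulator's
per-replicate overhead dominates at that grain (~30x slower in our
profiling). The simulator's waiting times and sequence statistics are
cross-checked against msprime in the test suite. Autosomal loci use 2 gene
copies per diploid (pairwise E[T] = 2N); the maternally inherited haploid
mitochondrial genome uses an effective size of N/4 on the diploid scale,
i.e. a haploid pool of N/2 copies (pairwise E[T] = N/2). The 19
microsatellite loci get independent genealogies; the two mtDNA partitions
share one.

Microsatellite mutation is the generalized stepwise model: Poisson events on
branches, step magnitude geometric with success probability `1 - P` (mean
`1/(1-P)`; `P = 0` is the strict stepwise model), direction symmetric, and
allele sizes reflected (triangle-wave folding) into the repeat-number bounds
`[5, 50]`. mtDNA evolves under HKY via a normalized jump chain — every event
substitutes the base with probabilities proportional to `pi_j`, times
`kappa` for transitions — so the realized substitution rate per site equals
the site's rate. Site rates implement HKY+I on the 650 bp coding partition
(default proportion invariant 0.8) and HKY+Gamma on the 460 bp
hyper-variable partition (default shape 0.3), both scaled to preserve the
partition-mean rate; defaults `kappa = 10` and base frequencies
(0.30, 0.25, 0.15, 0.30) are typical mammalian mtDNA values. These defaults
stand in for substitution-model parameters that a real analysis would take
from model selection on its own alignment.

## ABC (`skyisland.abc`)

Eighteen summary statistics in fixed order: microsatellites — mean
alleles/locus, mean unbiased He, mean allele-size variance (each for S and
N), Weir–Cockerham `F_ST`, Goldstein's `(delta mu)^2`; mtDNA — haplotype
count, segregating sites, mean pairwise differences, Tajima's D (each for S
and N), Hudson `F_ST`, mean between-population pairwise differences.
Statistics undefined on monomorphic data are 0. The vectorized
implementations are asserted equal to the `popgen` module's generic ones in
the tests.

Reference tables are seeded per row from `(seed, scenario, row)` via
`SeedSequence` spawn keys, so chunked builds concatenate to the identical
table as a serial build. Model choice standardizes statistics by the table
SD, retains the `tolerance` fraction nearest in Euclidean distance, and
reports both the retained scenario frequencies and a distance-weighted
(Epanechnikov) polychotomous logistic regression evaluated at the observed
point; a weak ridge whose strength scales inversely with the total kernel
weight keeps the fit stable under separation and invariant to duplicating
rows. Parameter estimation is Beaumont local-linear adjustment on a latent
scale — the logit of each parameter's position within its prior support
(log scale for log-uniform priors) — which confines adjusted draws to the
support; summaries are Epanechnikov-weighted quantiles, with times also in
years and the decline ratio `N_S0/N_S` reported both as the posterior of
the per-draw ratio and via the ratio of medians.

Calibration uses pseudo-observed datasets: scenario confusion matrices with
type-1/type-2 error rates; a PCA posterior-predictive check (simulations
from the adjusted posterior, observation projected, 99% Mahalanobis
ellipsoid on the first two components); and relative mean bias /
relative median absolute deviation of posterior-median estimates.

A calibration result worth stating plainly: under the fully flexible size
priors above, the four scenarios are heavily nested, and a very recent
decline is largely absorbed by scenario 1's lower-dimensional prior
predictive (an Occam effect). Pods drawn from the full scenario-4 prior are
recovered at roughly the rates a global classifier achieves (confusion
diagonal ~0.4–0.6); pods forced to a ten-fold decline are recovered far less
often, because constant-size histories reproduce their summaries almost as
densely. Decisive scenario probabilities on real data therefore reflect the
data, not a guarantee of the machinery, and the test suite asserts the
calibration quantities it can honestly measure (confusion structure,
credible-interval coverage of ~94% for the split time) rather than forcing
the recovery rate.

## Range dynamics (`skyisland.range_dynamics`)

The binarization threshold maximizes sensitivity + specificity over the
union of presence and background scores; boundary cells count as suitable
("at or above", flippable), ties break toward the lowest threshold, and
degenerate all-equal scores raise. Ensembles of binary maps take a cell-wise
majority with ties suitable. The range report computes suitable cells, per
cent of study area and `100 (cells_t - cells_present)/cells_present`,
rounded to one decimal in the report.

## Synthetic worlds (`skyisland.synthetic`)

`make_world` builds a 100x100 (configurable) raster stack: a smooth sum of
five Gaussian peaks — two south-east and three north-west of a low-altitude
rift band along the grid diagonal — with altitude noise; ecoregion classes
as altitude strata (lowland < 2795 m, montane to 3600 m, alpine above,
echoing montane-woodland vs alpine-moorland capture strata); human footprint
and arable fraction decreasing with altitude; a suitability score increasing
with it; and the five site cells at the peaks. The true cost scheme maps
lowland to 100, montane to 20 and alpine to 1. All outputs regenerate bit
for bit from `(config, seed)` via spawn-keyed child RNGs.

`simulate_truth_genetics` runs the two-deme coalescent (southern deme = the
two south-eastern sites, northern = the other three; panmictic within a
side, which real mountain isolates are not — within-side structure is
deliberately absent) with the study's per-site sample sizes
(7, 9, 7, 12, 11) and records the ground truth in a manifest.
`inject_covariate_effect` measures arable cover in a buffer around each site
and synthesizes a diversity response `intercept + slope*arable + noise` —
it emulates the diversity~land-use association without rewiring the
coalescent, so regression tests probe the statistics, not a genetic
mechanism.

What passing tests on these worlds do not show: real microsatellite data
have genotyping error, null alleles and within-mountain substructure; real
suitability maps have spatial autocorrelation structure the noise model
lacks; and the synthetic landscape's covariates all derive from altitude, so
collinearity among real landscape variables is understated.

## Problem sizes and numerical choices

Simulations in the shipped tests are sized for a laptop-class single CPU:
reference tables of 2,500–6,000 rows per scenario (with the retained-row
count held at the full-scale analysis's ~400–500 by adjusting the tolerance),
200-pod coverage studies, 100-replicate AICc and 200-replicate MRDM/CI
calibrations, and 2,000-replicate mutation-model checks at three Monte-Carlo
standard errors. A production analysis scales the same calls up (e.g.
`10^5`–`10^6` rows per scenario via the chunk-parallel row seeding).
Degenerate inputs fail loudly: empty score lists, constant response
matrices, unmapped raster categories, sub-unit Euclidean distances and
missing seeds for permutation or HWE tests all raise instead of guessing.
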