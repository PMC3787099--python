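# Methods

This note documents the models, estimators and numerical choices behind
`msatrelict`, and what the synthetic-data generator does and does not
emulate.

## Study system and data model

The package targets a survey of rear-edge black alder populations: 19
North-African populations (7 Tunisian and 8 Algerian diploid, 4 Moroccan
autotetraploid; 551 trees) plus one Scottish post-glacial reference
population of 36 (PGM), genotyped at 11 microsatellite loci.  A genotype is
the *observed multiset* of allele sizes (fragment lengths in bp): up to two
alleles for diploids, up to four for tetraploids.  Tetraploid dosage is
ambiguous — an electropherogram reveals which alleles are present, not how
many copies of each — so a tetraploid genotype with fewer than four
distinct alleles is stored as its distinct set.  An empty multiset encodes
missing data; file sentinels are configurable (−9 in the CSV dialect, 0000
in GenePop, −5 in Structure output).

## Ploidy inference

An individual is called tetraploid iff it shows ≥ 3 distinct alleles at at
least one locus; the threshold is per-locus, not summed over loci, matching
the way distinct-allele histograms (Nal1a..Nal4a: individuals whose maximum
per-locus distinct count is 1..4) are tabulated.  Diploid-compatible
individuals missing ≥ 50% of the panel are flagged unreliable: absence of a
third allele in six genotyped loci is weak evidence.  Calls are confirmed
by simulation: draw `ploidy` allele copies i.i.d. from the population's
locus frequencies, count distinct alleles, sum over loci, and compare the
simulated distribution with the observed totals.  Tetraploid totals
stochastically dominate diploid ones for any polymorphic frequencies (the
diploid draw is a subsample of the tetraploid one), which is what makes the
confirmation informative.

## Dosage-ambiguous frequencies and pseudo-diploidisation

Allele frequencies in tetraploid populations use the **equal-dosage rule**:
a genotype with k distinct alleles contributes `4/k` copies of each.  This
is the unbiased assignment absent dosage information, and reduces exactly
to allele counting on diploid data.  Because the downstream ABC machinery
is diploid-only, a tetraploid population enters it via
**pseudo-diploidisation**: estimate its allele frequencies, then draw 30
two-allele genotypes per locus i.i.d. (Hardy-Weinberg / random mating).
The pseudo-sample preserves allele frequencies but discards
linkage/identity disequilibrium within individuals; this is a deliberate,
documented information loss.

## Diversity and rarefaction

Per-population gene diversity is `Hs = mean over loci of 1 − Σ p²` (the
plain estimator; a small-sample corrected variant is available behind
`bias_corrected=True`).  Because a tetraploid sample of n individuals holds
4n gene copies against 2n for diploids, Hs is not comparable across ploidy;
`rHs` recomputes gene diversity on g = 12 haploid genomes drawn *without
replacement* per locus from the population's copy pool (equal-dosage
expansion for ambiguous genotypes; fractional copy weights are decremented
by one per draw).  The published analysis does not state whether one
subsample or an average was used; we average over replicates (default
1000, seeded; the pipeline preset uses 200 as its reporting default) and
expose the Monte-Carlo standard error, because a single subsample makes
the estimate a lottery.  Rarefying a diploid population to its full copy
count reproduces Hs exactly.

Country contrasts use the tie-corrected Kruskal-Wallis H with a chi-square
p-value (delegated to scipy; an explicit rank-table implementation serves
as test oracle).  Lynch band-sharing distance between individuals is
`1 − mean over shared loci of 2|A∩B|/(|A|+|B|)` on distinct-allele sets.
Divergence times convert to years by an exact product with the generation
time (default 10 years, the standard assumption for alder), applied to
modes and quantiles alike.

## Divergence scenarios

Three sampled gene pools are indexed 0 (Moroccan, size N1), 1 (Tunisian,
N2), 2 (Scottish reference, N3).  Scenario 1 is a trichotomy: all three
diverge at time t from an ancestor of size Ns.  Scenarios 2–7 enumerate the
six "budding" dichotomies: the outgroup splits from the deep ancestor
(size Ns) at t3a, while the other two populations split at t2 and t1 from
an intermediate ancestor (size Ne) that budded off the deep ancestor at
t3b.  Backward in time, lineages of the most recent population join E at
t1, the second at t2, E joins S at t3b, the outgroup joins S at t3a.  The
prior constraint is t1 < t2 < t3a,b; t3a and t3b are unordered relative to
each other.  The id table is:

| id | outgroup (t3a) | second (t2) | most recent (t1) |
|----|----------------|-------------|------------------|
| 2  | 2 (PGM)        | 0           | 1                |
| 3  | 2 (PGM)        | 1           | 0                |
| 4  | 0 (Morocco)    | 1           | 2                |
| 5  | 0 (Morocco)    | 2           | 1                |
| 6  | 1 (Tunisia)    | 2           | 0                |
| 7  | 1 (Tunisia)    | 0           | 2                |

Ids 4 and 5 are fixed by the published analysis (5 = Moroccan pool out
first, Tunisian most recent — the best-supported history; 4 its order
swap); the remaining ids are an arbitrary but frozen enumeration.

**Priors.** Effective sizes Uniform[10, 20000] diploid individuals;
divergence times Uniform[1, 20000] generations with the ordering
constraint enforced by rejection resampling (acceptance probability 1/12).

## Coalescent engine

The simulator is a continuous-time (Kingman) structured coalescent over
five demes: within a deme of diploid size N, each lineage pair coalesces at
rate 1/(2N) per generation; at each split time the source deme's lineages
move into their ancestor.  The continuous-time approximation against a
discrete-generation model is negligible at the prior's minimum size
(N ≥ 10) and makes the engine fast.  The hot loop is numba-compiled; all
randomness derives from a single integer seed per dataset, making tables
bit-reproducible.  The engine is validated against closed forms —
E[T2] = 2N, E[TMRCA of n copies] = 4N(1 − 1/n) — and cross-checked against
an independent coalescent implementation (msprime) in the test suite.

**Mutation.** Generalized stepwise (GSM): mutations arrive as a Poisson
process at per-locus rate μ_i along branches; each changes the repeat count
by a geometric step, P(s) = (1−p_i)·p_i^(s−1) (mean 1/(1−p_i)), with
equiprobable sign.  p → 0 recovers the strict stepwise model, which at
equilibrium gives expected heterozygosity 1 − 1/√(1 + 8Nμ) — used as an
end-to-end engine check.  Genome-wide means are drawn
μ ~ U[1e-4, 1e-3] and p ~ U[0.1, 0.3]; per-locus values are
Gamma(shape 2) around these means, truncated to [1e-5, 1e-2] and
[0.01, 0.9] (truncation by resampling).  Optional flanking-sequence indels
(μ_SNI ~ Gamma(2) on [1e-9, 1e-3]) add ±1 bp off the repeat lattice and are
**off by default**.  The root allele sits at a fixed origin (200 bp); only
size differences matter for every statistic.  Allele sizes are unbounded by
default (no reflecting range constraint) — with ≤ 20000 generations and
these rates, excursions beyond a realistic 40-repeat window are too rare to
affect the statistics at the simulated scales.

**Tetraploid emission** (synthetic-study generation only) groups four gene
copies per individual in the same coalescent — i.e. a tetraploid population
of N1 diploid-genome equivalents; the ABC path itself always operates on
diploid data.

## Summary statistics

All size-based statistics work in repeat units (bp / motif length).  Per
population: mean distinct-allele count (NAL), mean unbiased allele-size
variance (VAR), mean M index k/(r+1) with r the size range in repeat units
(rounded up when indels break the lattice); a monomorphic locus contributes
k = 1, VAR = 0, M = 1.  Per pair: NAL and VAR pooled over the union
sample; Weir & Cockerham's θ from the a/b/c variance components summed
over alleles and loci (nan when no polymorphism, or when a sample holds a
single individual); the shared-allele distance (mean of 1 − shared/2 over
inter-population genotype pairs, shared = multiset intersection); and a
classification index — the symmetrised Rannala-Mountain mean log-likelihood
of one population's genotypes under the other's allele frequencies,
posterior-mean smoothed with a Dirichlet(1/k) prior,
`p = (count + 1/k)/(copies + 1)` with k the distinct-allele count of the
pooled pair at the locus.  The exact classification index of the original
DIYABC software is not published; this smoothing is our documented
approximation, chosen so that alleles absent from the reference population
keep finite likelihood.  Three populations give 9 within + 15 pairwise = 24
statistics in a fixed order produced by one code path for observed and
simulated data.

## ABC

**Normalisation.** Each statistic is centred by its reference-table median
and scaled by 1.4826 × MAD (falling back to the standard deviation, then
1, for degenerate columns); the constants are frozen into the table so
observed and simulated vectors are normalised identically.  Undefined
statistics are nan: columns undefined in the observed vector are excluded
from the distance, and nan table entries on used columns are neutralised at
the column centre.

**Rejection** keeps the n rows of smallest normalised Euclidean distance,
ties broken by row index (stable sort); it matches an exhaustive scan
exactly.

**Scenario choice** fits a multinomial logistic regression of the scenario
indicator on the centred statistics over the retained rows, weighted by an
Epanechnikov kernel in distance with bandwidth equal to the largest
retained distance.  The fit is a damped Newton iteration with a small
ridge (1e-6 × weight mass) for separable configurations; posterior
probabilities are the fitted class probabilities at the observed point and
their 95% intervals come from the delta method on the intercepts using the
observed information.  Scenarios absent from the retained set get P = 0
with a warning.

**Parameter estimation** is Beaumont-style local-linear adjustment:
parameters are log-transformed (positivity; prior-bounded logit available
in principle but log suffices for these priors), regressed linearly on the
centred statistics with the same Epanechnikov weights, and residuals are
shifted to the observed point.  The posterior mode is the argmax of a
weighted Gaussian KDE with Silverman bandwidth on the transformed scale
(evaluated on a 512-point grid), back-transformed; 5%/95% quantiles are
weighted quantiles (monotone back-transform).  A singular regression falls
back to the unadjusted rejection sample with a warning; forcing zero slopes
reproduces the rejection sample exactly.

**Scaled sizes.** The study-scale analysis used 1e7 simulations per
scenario, 7000 retained for model choice, and 10000 (0.1%) for estimation.
The package defaults scale these to desk size: the acceptance analyses use
a 1e5-row seven-scenario table with 700 retained for model choice, and a
1e5-row focal-scenario table with 0.1% retention for estimation; the
pipeline preset is smaller still (2000/scenario).  Retention for
estimation should stay comfortably above the regression dimension
(25 including the intercept) — below that the local regression
interpolates and the adjusted posterior collapses.

**Power and quality.** Confidence in scenario choice is measured by
classifying pseudo-observed datasets simulated from the priors: type I
error of a scenario is the fraction of its own datasets assigned elsewhere,
type II the fraction of other scenarios' datasets assigned to it.  The
characteristic result of this design is that the two same-outgroup
scenarios (4 and 5) are mutually confusable — about a third of datasets
assigned to scenario 5 were generated under scenario 4 — while scenarios
with a different outgroup almost never masquerade as 5.  Estimation quality
(relative bias, relative RMSE, factor-2 proportion) is measured on
pseudo-observed datasets with known truths; divergence times other than the
most recent are recovered within a factor 2 most of the time, t1 being the
hardest, and ancestral sizes (Ne, Ns) carry the least information.

## Synthetic-study generator

The generator emulates the survey design exactly in its bookkeeping — 20
populations, 587 individuals, the published per-site sample sizes,
countries and ploidies — and approximately in its genetics: each of the
three regional gene pools (Morocco; Tunisia+Algeria; Scotland) is a single
panmictic deme of the chosen scenario, and sampling-site labels partition
an exchangeable regional sample.  Real data have within-region
substructure, isolation by distance, genotyping error and ~0.2% missing
data, none of which is modelled; passing tests therefore validate the
inference machinery under its own assumptions, not robustness to those
violations.  Tetraploid genotypes are emitted dosage-ambiguous (distinct
alleles only), so the synthetic data exercise the same ambiguity handling
as real electropherogram calls.

## Degenerate inputs and tie-breaks

Monomorphic data: Hs = rHs = 0, M = 1, θ undefined (nan), classification
index exactly 0 for identical monomorphic populations.  Kruskal-Wallis on
all-identical values returns H = 0 with a warning.  Rejection ties break by
row index; KDE on a zero-spread sample returns the heaviest point.  The
Structure exporter pads ambiguous tetraploid genotypes deterministically
(3 observed → A B C C; 2 observed → A A B B, the symmetric choice among
genotype-compatible paddings; 1 observed → A A A A) and records the rule in
the file header.

## Known limitations

* The classification index and the normalisation constants are documented
  approximations of unpublished implementation details of the original
  ABC software; absolute statistic values may differ from it even though
  all within-package comparisons are consistent.
* Pseudo-diploidisation treats the tetraploid sample's equal-dosage
  frequencies as truth; dosage misassignment biases are not propagated.
* The coalescent has no migration, admixture or growth; scenarios are pure
  divergence with constant sizes, as in the study design.
* Rarefaction with fractional (equal-dosage) copy weights is an
  approximation of without-replacement sampling; it is exact on diploid
  data.
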