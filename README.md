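# msatrelict

Population-genetic analysis of mixed-ploidy microsatellite data and
coalescent-based demographic inference, built around the study system of
North-African rear-edge populations of black alder (*Alnus glutinosa*): 19
populations sampled across Tunisia, Algeria and Morocco plus one Scottish
post-glacial reference population (PGM), genotyped at 11 nuclear
microsatellites.  The Moroccan populations are natural autotetraploids,
which drives most of the package's design: genotypes carry up to four
alleles with ambiguous dosage, diversity must be rarefied to a common
number of haploid genomes before ploidy levels can be compared, and
tetraploid samples must be pseudo-diploidised before entering diploid-only
inference machinery.

## What it does

* **Data handling** (`genodata`): mixed-ploidy genotype tables read/written
  in a CSV dialect (four allele columns per locus), GenePop import for
  diploid data, and export to a Structure input file using the
  recessive-alleles coding for mixed 2x/4x datasets (a tetraploid genotype
  with observed alleles A,B,C is written `A B C C`; a diploid heterozygote
  `A B -5 -5`).
* **Ploidy** (`polyploid`): an individual showing three or more distinct
  alleles at any locus is called tetraploid; calls are confirmed by
  simulating the distribution of per-individual distinct-allele totals
  under each ploidy from the population's allele frequencies.  Frequencies
  from ambiguous tetraploid genotypes use the equal-dosage rule (each of k
  distinct alleles counts 4/k copies), and pseudo-diploid samples are drawn
  from them under Hardy-Weinberg.
* **Diversity** (`diversity`): Nei gene diversity `Hs = 1 - Σ p²` averaged
  over loci, its rarefied version `rHs` on 12 haploid genomes subsampled
  without replacement, a tie-corrected Kruskal-Wallis test for country
  contrasts, Lynch band-sharing distance between individuals, and
  generation-to-year conversion of divergence times.
* **Simulation** (`coalsim`): a structured-coalescent simulator for three
  sampled populations under seven divergence scenarios (one trichotomy and
  all six "budding" dichotomies), with generalized stepwise mutation —
  Poisson mutations whose repeat-count step is geometric,
  `P(s) = (1-p) p^(s-1)` — and hierarchical per-locus rates
  (Gamma-distributed around genome-wide means).  The hot path is
  numba-compiled; a full study-sized dataset (96 diploids x 11 loci)
  simulates in well under a millisecond.
* **Summary statistics** (`sumstats`): per population, mean allele number,
  mean allele-size variance and the Garza-Williamson `M = k/(r+1)`; per
  population pair, pooled allele number and size variance, a
  Rannala-Mountain genotype classification index, Weir & Cockerham's theta
  and the shared-allele distance — 24 statistics for three populations, in
  a fixed order shared by observed and simulated data.
* **ABC** (`abc`): reference tables of (scenario, parameters, statistics);
  rejection by normalised Euclidean distance; scenario choice by
  distance-weighted polychotomous logistic regression with delta-method
  confidence intervals (`ABCScenarioChoice`, a scikit-learn style
  classifier); Beaumont-style local-linear parameter estimation on log
  scale with weighted-KDE posterior modes (`ABCParameterEstimator`); and
  power/quality assessment from pseudo-observed datasets (type I/II error
  confusion matrices; relative bias, relative RMSE and factor-2
  proportions).
* **Pipeline** (`pipeline`, `msatrelict` CLI): a synthetic-study generator
  reproducing the survey design (20 populations, 587 individuals, Moroccan
  populations emitted tetraploid) and an end-to-end seeded analysis runner
  producing CSV report tables plus a JSON metadata sidecar.

## Worked example

```python
import numpy as np
from msatrelict import diversity, pipeline, polyploid
from msatrelict.datasets import alder_survey_table

# Published survey table: country contrast of rarefied gene diversity
t = alder_survey_table()
na = t[t.country != "Scotland"]
kw = diversity.kruskal_wallis(
    {c: g.rhs.to_list() for c, g in na.groupby("country")}
)
print(f"mean Hs = {na.hs.mean():.2f}, mean rHs = {na.rhs.mean():.2f}")
print(f"Kruskal-Wallis H = {kw.h:.2f}, df = {kw.df}, p = {kw.pvalue:.4f}")

# Synthetic analogue of the study, analysed end to end
cfg = pipeline.StudyConfig(seed=1, rarefaction_replicates=100,
                           abc_n_per_scenario=2000, abc_n_closest=200)
dataset, truth = pipeline.generate_synthetic_study(cfg)
rep = polyploid.infer_ploidy(dataset)
bundle = pipeline.run_full_analysis(dataset, cfg)
print(bundle["model_choice"].sort_values("posterior_p", ascending=False).head(3))
```

prints

```
mean Hs = 0.59, mean rHs = 0.57
Kruskal-Wallis H = 12.70, df = 2, p = 0.0017
 scenario  posterior_p  ci_low  ci_high
        5     0.828423     0.0 1.000000
        1     0.073993     0.0 0.622160
        4     0.047577     0.0 0.393718
```

The survey-level numbers are the published ones: North-African mean gene
diversity 0.59 (rarefied 0.57), significantly different between countries
(Morocco highest).  The synthetic study was generated under scenario 5
(the Moroccan pool diverging first, the Tunisian pool most recently); at
this modest reference-table size (2000 simulations per scenario) the ABC
stage already assigns it the highest posterior probability, with its
order-swapped sibling (scenario 4) among the runners-up — the
characteristic confusion pattern of the design.

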