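"""Ploidy inference and ambiguous-dosage allele handling for mixed 2x/4x
microsatellite datasets.

Autotetraploid genotypes scored from electropherograms reveal which alleles
are present but not their copy numbers ("ambiguous dosage").  This module
provides:

* ploidy inference from multilocus distinct-allele counts (an individual
  with three or more distinct alleles at any single locus cannot be
  diploid),
* the simulation used to confirm ploidy calls — the expected distribution
  of per-individual distinct-allele totals under a given ploidy and set of
  allele frequencies,
* allele-frequency estimation under the equal-dosage rule (a tetraploid
  genotype with k distinct alleles contributes 4/k copies of each), and
* pseudo-diploidisation — drawing Hardy-Weinberg diploid genotypes from
  tetraploid-derived allele frequencies so diploid-only inference machinery
  can be applied downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genodata import Genotype, Individual, Locus, MsatDataset, Population

__all__ = [
    "PloidyReport",
    "AlleleFreqs",
    "AlleleCountDistribution",
    "infer_ploidy",
    "simulate_allele_counts",
    "estimate_freqs_mixed",
    "sample_pseudo_diploids",
]


@dataclass
class PloidyReport:
    """Outcome of ploidy inference.

    ``nal_counts[pop]`` is the four-bin histogram of individuals whose
    maximum distinct-allele count at any locus is 1, 2, 3 or 4 — the
    N_al1a..N_al4a presentation; bins sum to the population sample size.
    """

    individual_max_distinct: dict[str, int]
    individual_total_distinct: dict[str, int]
    individual_ploidy: dict[str, int]
    unreliable: set[str]
    population_ploidy: dict[str, int]
    nal_counts: dict[str, list[int]]


def infer_ploidy(
    dataset: MsatDataset, unreliable_missing_threshold: float = 0.5
) -> PloidyReport:
    """Label individuals tetraploid iff >= 3 distinct alleles at >= 1 locus.

    Individuals with at most two distinct alleles everywhere are
    diploid-compatible and labelled diploid.  Individuals missing at least
    ``unreliable_missing_threshold`` of the panel are flagged unreliable
    (their diploid-compatible call may reflect lack of data rather than
    ploidy).  Population ploidy is the maximum over member individuals.
    """
    if not dataset.individuals:
        raise ValueError("empty dataset")
    max_d: dict[str, int] = {}
    tot_d: dict[str, int] = {}
    ploidy: dict[str, int] = {}
    unreliable: set[str] = set()
    nal: dict[str, list[int]] = {code: [0, 0, 0, 0] for code in dataset.populations}
    pop_ploidy: dict[str, int] = {code: 2 for code in dataset.populations}
    for ind in dataset.individuals:
        m = ind.max_distinct()
        t = sum(g.observed_distinct for g in ind.genotypes.values())
        max_d[ind.id] = m
        tot_d[ind.id] = t
        p = 4 if m >= 3 else 2
        ploidy[ind.id] = p
        if ind.missing_fraction(dataset.loci) >= unreliable_missing_threshold:
            unreliable.add(ind.id)
        if m >= 1:
            nal[ind.population][min(m, 4) - 1] += 1
        pop_ploidy[ind.population] = max(pop_ploidy[ind.population], p)
    return PloidyReport(
        individual_max_distinct=max_d,
        individual_total_distinct=tot_d,
        individual_ploidy=ploidy,
        unreliable=unreliable,
        population_ploidy=pop_ploidy,
        nal_counts=nal,
    )


@dataclass
class AlleleFreqs:
    """Per-locus allele relative frequencies for one population."""

    loci: list[Locus]
    freqs: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, f in self.freqs.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name}: frequencies sum to {total}, not 1")
            if any(v < 0 for v in f.values()):
                raise ValueError(f"{name}: negative frequency")

    def arrays(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        f = self.freqs[locus]
        alleles = np.array(sorted(f), dtype=np.int64)
        probs = np.array([f[a] for a in alleles], dtype=np.float64)
        return alleles, probs


def estimate_freqs_mixed(dataset: MsatDataset, population: str) -> AlleleFreqs:
    """Allele frequencies under the equal-dosage rule.

    Diploid genotypes contribute each allele copy with weight 1 (a
    single-entry diploid genotype counts as a homozygote).  An ambiguous
    polyploid genotype recorded as k distinct alleles contributes
    ``ploidy / k`` copies of each — the unbiased assignment absent dosage
    information.  On purely diploid data this is plain allele counting.
    Loci with no data in the population are omitted with a warning.
    """
    inds = dataset.population_individuals(population)
    freqs: dict[str, dict[int, float]] = {}
    kept: list[Locus] = []
    for locus in dataset.loci:
        weights: dict[int, float] = {}
        for ind in inds:
            g = ind.genotypes.get(locus.name)
            if g is None or g.is_missing:
                continue
            ploidy = ind.ploidy if ind.ploidy is not None else 2
            if ploidy == 2 and len(g.allele_sizes) == 1:
                alleles: tuple[int, ...] = (g.allele_sizes[0], g.allele_sizes[0])
            else:
                alleles = g.allele_sizes
            w = ploidy / len(alleles)
            for a in alleles:
                weights[a] = weights.get(a, 0.0) + w
        if not weights:
            warnings.warn(
                f"population {population}: no data at locus {locus.name}; omitted"
            )
            continue
        total = sum(weights.values())
        freqs[locus.name] = {a: w / total for a, w in weights.items()}
        kept.append(locus)
    if not kept:
        raise ValueError(f"population {population}: no typed loci")
    return AlleleFreqs(loci=kept, freqs=freqs)


@dataclass
class AlleleCountDistribution:
    """Empirical distribution of per-individual distinct-allele totals."""

    totals: np.ndarray
    ploidy: int

    @property
    def mean(self) -> float:
        return float(self.totals.mean())

    @property
    def min(self) -> int:
        return int(self.totals.min())

    @property
    def max(self) -> int:
        return int(self.totals.max())

    def histogram(self) -> dict[int, int]:
        values, counts = np.unique(self.totals, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


def simulate_allele_counts(
    freqs: AlleleFreqs,
    ploidy: int,
    n_individuals: int,
    rng: np.random.Generator | int | None = None,
) -> AlleleCountDistribution:
    """Expected distinct-allele totals under a ploidy hypothesis.

    For each simulated individual and locus, ``ploidy`` allele copies are
    drawn i.i.d. from the locus frequencies; the number of distinct alleles
    is summed over loci.  Comparing the observed totals with the simulated
    distributions under ploidy 2 and 4 confirms ploidy calls made from
    electropherogram allele counts.
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    rng = np.random.default_rng(rng)
    totals = np.zeros(n_individuals, dtype=np.int64)
    for locus in freqs.loci:
        alleles, probs = freqs.arrays(locus.name)
        if len(alleles) == 0:
            raise ValueError(f"degenerate locus {locus.name}")
        draws = rng.choice(len(alleles), size=(n_individuals, ploidy), p=probs)
        draws.sort(axis=1)
        distinct = 1 + (np.diff(draws, axis=1) != 0).sum(axis=1)
        totals += distinct
    return AlleleCountDistribution(totals=totals, ploidy=ploidy)


def sample_pseudo_diploids(
    freqs: AlleleFreqs,
    n: int = 30,
    rng: np.random.Generator | int | None = None,
    population_code: str = "PSD",
    country: str = "",
) -> MsatDataset:
    """Draw Hardy-Weinberg diploid multilocus genotypes from ``freqs``.

    Each pseudo-individual receives two i.i.d. allele draws per locus
    (random mating).  This is how dosage-ambiguous tetraploid samples enter
    the diploid-only ABC machinery: estimate frequencies with
    :func:`estimate_freqs_mixed`, then resample a diploid stand-in sample.
    """
    rng = np.random.default_rng(rng)
    loci = list(freqs.loci)
    individuals = []
    genotype_draws: dict[str, np.ndarray] = {}
    for locus in loci:
        alleles, probs = freqs.arrays(locus.name)
        genotype_draws[locus.name] = alleles[
            rng.choice(len(alleles), size=(n, 2), p=probs)
        ]
    for i in range(n):
        genotypes = {
            locus.name: Genotype(genotype_draws[locus.name][i].tolist())
            for locus in loci
        }
        individuals.append(
            Individual(
                id=f"{population_code}_{i + 1:03d}",
                population=population_code,
                genotypes=genotypes,
                ploidy=2,
            )
        )
    populations = {population_code: Population(code=population_code, country=country)}
    return MsatDataset(loci=loci, populations=populations, individuals=individuals)
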