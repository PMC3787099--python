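"""Gene diversity, rarefaction across ploidy levels, rank tests and
individual genetic distances.

Nei's gene diversity for one population is ``Hs = mean over loci of
1 - sum_a p_a**2``.  Because a tetraploid sample of n individuals carries
twice as many gene copies as a diploid one, raw Hs is not comparable across
ploidy levels; the rarefied variant rHs recomputes gene diversity on a
fixed number of haploid genomes (default 12) subsampled without replacement
from each population, making diploid and tetraploid populations (and
unequal sample sizes) directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .genodata import Individual, MsatDataset
from .polyploid import estimate_freqs_mixed

__all__ = [
    "DiversityResult",
    "KWResult",
    "gene_diversity_hs",
    "rarefied_diversity",
    "kruskal_wallis",
    "lynch_distance",
    "generations_to_years",
]


@dataclass
class DiversityResult:
    """Per-population diversity estimates."""

    population: str
    hs: float
    rhs: float
    rhs_se: float
    g: int
    replicates: int
    seed: int | None


def gene_diversity_hs(
    dataset: MsatDataset, population: str, bias_corrected: bool = False
) -> float:
    """Nei gene diversity averaged over loci with data.

    Frequencies come from the equal-dosage estimator so diploid and
    ambiguous tetraploid genotypes are handled uniformly.  The default is
    the plain ``1 - sum p**2`` estimator; ``bias_corrected`` applies the
    small-sample factor ``n/(n-1)`` with ``n`` the (possibly fractional)
    number of gene copies at the locus.
    """
    freqs = estimate_freqs_mixed(dataset, population)
    per_locus = []
    for locus in freqs.loci:
        _, p = freqs.arrays(locus.name)
        h = 1.0 - float(np.sum(p**2))
        if bias_corrected:
            n = _locus_copy_total(dataset, population, locus.name)
            if n > 1:
                h *= n / (n - 1.0)
        per_locus.append(h)
    return float(np.mean(per_locus))


def _locus_copy_pool(
    dataset: MsatDataset, population: str, locus_name: str
) -> tuple[np.ndarray, np.ndarray]:
    """(alleles, weights) gene-copy pool under the equal-dosage expansion."""
    weights: dict[int, float] = {}
    for ind in dataset.population_individuals(population):
        g = ind.genotypes.get(locus_name)
        if g is None or g.is_missing:
            continue
        ploidy = ind.ploidy if ind.ploidy is not None else 2
        alleles = g.allele_sizes
        if ploidy == 2 and len(alleles) == 1:
            alleles = (alleles[0], alleles[0])
        w = ploidy / len(alleles)
        for a in alleles:
            weights[a] = weights.get(a, 0.0) + w
    alleles_arr = np.array(sorted(weights), dtype=np.int64)
    w_arr = np.array([weights[a] for a in alleles_arr], dtype=np.float64)
    return alleles_arr, w_arr


def _locus_copy_total(dataset: MsatDataset, population: str, locus_name: str) -> float:
    _, w = _locus_copy_pool(dataset, population, locus_name)
    return float(w.sum())


def _draw_without_replacement(
    weights: np.ndarray, g: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw g gene copies without replacement from a weighted pool.

    Weights are (possibly fractional) copy counts per distinct allele;
    each draw removes one copy's worth of weight from the chosen allele.
    With integer weights this is exact sampling without replacement.
    """
    remaining = weights.astype(np.float64).copy()
    counts = np.zeros(len(weights), dtype=np.float64)
    for _ in range(g):
        total = remaining.sum()
        idx = rng.choice(len(remaining), p=remaining / total)
        take = min(1.0, remaining[idx])
        counts[idx] += 1.0
        remaining[idx] -= take
        remaining[idx] = max(remaining[idx], 0.0)
    return counts


def rarefied_diversity(
    dataset: MsatDataset,
    population: str,
    g: int = 12,
    replicates: int = 1000,
    rng: np.random.Generator | int | None = None,
    return_se: bool = False,
):
    """Gene diversity on ``g`` haploid genomes subsampled per locus.

    Per replicate and locus, ``g`` gene copies are drawn without
    replacement from the population's copy pool (ambiguous tetraploid
    genotypes contribute copies under the equal-dosage expansion) and
    ``1 - sum p_hat**2`` computed; the result is averaged over loci and
    replicates.  Loci holding fewer than ``g`` copies are skipped; an error
    is raised if no locus qualifies.  Rarefying a diploid population to its
    full copy count reproduces Hs exactly (the subsample is the sample).
    """
    rng = np.random.default_rng(rng)
    pools = []
    for locus in dataset.loci:
        alleles, w = _locus_copy_pool(dataset, population, locus.name)
        total = w.sum()
        if total == 0:
            continue
        if total + 1e-9 < g:
            warnings.warn(
                f"population {population}, locus {locus.name}: only {total:.4g} "
                f"gene copies (< g={g}); locus skipped in rarefaction"
            )
            continue
        pools.append((alleles, w))
    if not pools:
        raise ValueError(
            f"population {population}: no locus holds >= {g} gene copies"
        )
    rep_means = np.empty(replicates, dtype=np.float64)
    for r in range(replicates):
        acc = 0.0
        for _, w in pools:
            counts = _draw_without_replacement(w, g, rng)
            p_hat = counts / g
            acc += 1.0 - float(np.sum(p_hat**2))
        rep_means[r] = acc / len(pools)
    rhs = float(rep_means.mean())
    if return_se:
        se = float(rep_means.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0
        return rhs, se
    return rhs


@dataclass
class KWResult:
    """Kruskal-Wallis rank-sum test outcome (tie-corrected)."""

    h: float
    df: int
    pvalue: float
    group_mean_ranks: dict[str, float]


def kruskal_wallis(groups: dict[str, list[float] | np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value.

    ``groups`` maps a label (e.g. country) to its values.  All-identical
    values yield H = 0 with a warning.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; H = 0")
        return KWResult(
            h=0.0,
            df=len(samples) - 1,
            pvalue=1.0,
            group_mean_ranks={k: (len(pooled) + 1) / 2 for k in labels},
        )
    h, p = _scipy_stats.kruskal(*samples)
    ranks = _scipy_stats.rankdata(pooled)
    mean_ranks = {}
    offset = 0
    for k, s in zip(labels, samples):
        mean_ranks[k] = float(ranks[offset : offset + len(s)].mean())
        offset += len(s)
    return KWResult(h=float(h), df=len(samples) - 1, pvalue=float(p),
                    group_mean_ranks=mean_ranks)


def lynch_distance(ind_a: Individual, ind_b: Individual) -> float:
    """Lynch band-sharing distance between two individuals.

    Per locus typed in both individuals, similarity is
    ``2 |A & B| / (|A| + |B|)`` on distinct-allele sets; the distance is one
    minus the mean similarity over shared loci.  Symmetric, zero iff the
    distinct-allele profiles coincide on every shared locus.
    """
    sims = []
    for name, ga in ind_a.genotypes.items():
        gb = ind_b.genotypes.get(name)
        if gb is None or ga.is_missing or gb.is_missing:
            continue
        sa, sb = set(ga.distinct), set(gb.distinct)
        sims.append(2.0 * len(sa & sb) / (len(sa) + len(sb)))
    if not sims:
        raise ValueError(
            f"{ind_a.id} and {ind_b.id} share no typed locus; distance undefined"
        )
    return 1.0 - float(np.mean(sims))


def generations_to_years(t_generations, generation_time: float = 10.0):
    """Convert divergence times from generations to years.

    Exact product; applies elementwise to arrays (posterior modes and
    quantiles alike).  The default generation time of 10 years is the
    standard assumption for black alder.
    """
    t = np.asarray(t_generations, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    out = t * generation_time
    if np.isscalar(t_generations) or np.ndim(t_generations) == 0:
        return float(out)
    return out
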