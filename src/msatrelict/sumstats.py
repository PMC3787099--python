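"""DIYABC-style summary statistics for diploid microsatellite data.

Per population: mean number of alleles (NAL), mean allele-size variance
(VAR, in squared repeat units) and the mean M index (Garza-Williamson
``k / (r + 1)`` with ``r`` the allele-size range in repeat units).  Per
population pair: the same NAL and VAR pooled over the union sample, a
genotype classification index (LIK, a Rannala-Mountain mean log-likelihood
of one population's genotypes under the other's smoothed allele
frequencies, symmetrised), Weir & Cockerham's theta (FST) and the shared
allele distance (DAS, one minus the mean proportion of alleles shared
between inter-population genotype pairs).

For three populations the vector has 3x3 within + 3x5 pairwise = 24 entries
in a fixed, documented order; observed and simulated data are summarised by
the same code path so the ordering always matches.

Statistics that are undefined on a dataset (e.g. theta without any
polymorphism) are encoded as ``nan`` and masked symmetrically downstream.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numba import njit

from .genodata import MsatDataset

__all__ = [
    "WITHIN_NAMES",
    "PAIR_NAMES",
    "stat_names",
    "summarize",
    "summarize_matrix",
    "within_stats",
    "pairwise_fst",
    "shared_allele_distance",
    "classification_index",
    "to_diploid_matrix",
]

WITHIN_NAMES = ("NAL", "VAR", "M")
PAIR_NAMES = ("NAL2", "VAR2", "LIK", "FST", "DAS")


def stat_names(population_order: Sequence[str]) -> list[str]:
    """Statistic labels in vector order for a given population ordering."""
    names = [
        f"{stat}_{pop}" for stat in WITHIN_NAMES for pop in population_order
    ]
    n = len(population_order)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = population_order[i], population_order[j]
            names.extend(f"{stat}_{a}x{b}" for stat in PAIR_NAMES)
    return names


# ---------------------------------------------------------------------------
# Numba kernels (operate on an integer allele matrix in base pairs)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _locus_within(vals, motif):
    """(k, variance, M) for one locus sample of allele sizes in bp."""
    n = vals.shape[0]
    s = np.sort(vals)
    k = 1
    for i in range(1, n):
        if s[i] != s[i - 1]:
            k += 1
    mean = 0.0
    for i in range(n):
        mean += s[i]
    mean /= n
    var = 0.0
    if n > 1:
        for i in range(n):
            var += (s[i] - mean) ** 2
        var /= n - 1
    var /= motif * motif
    d = s[n - 1] - s[0]
    r = (d + motif - 1) // motif  # repeat units, rounded up for off-lattice
    m_index = k / (r + 1.0)
    return k, var, m_index


@njit(cache=True)
def _within_block(copies, lo, hi, motifs):
    """Mean-over-loci (NAL, VAR, M) for gene copies rows lo:hi."""
    n_loci = copies.shape[1]
    nal = 0.0
    var = 0.0
    m = 0.0
    for l in range(n_loci):
        k, v, mi = _locus_within(copies[lo:hi, l], motifs[l])
        nal += k
        var += v
        m += mi
    return nal / n_loci, var / n_loci, m / n_loci


@njit(cache=True)
def _pair_block(copies, a_lo, a_hi, b_lo, b_hi, motifs):
    """Pairwise statistics (NAL2, VAR2, LIK, FST, DAS) for two populations.

    Rows are gene copies; individuals are consecutive copy pairs (diploid).
    """
    n_loci = copies.shape[1]
    na = (a_hi - a_lo) // 2  # individuals
    nb = (b_hi - b_lo) // 2
    n1c = a_hi - a_lo  # gene copies
    n2c = b_hi - b_lo

    nal2 = 0.0
    var2 = 0.0
    fst_num = 0.0
    fst_den = 0.0
    lik_ab = 0.0  # sum of log-lik of A genotypes under B freqs
    lik_ba = 0.0
    das_sum = 0.0

    # Weir-Cockerham constants (r = 2 populations)
    nbar = (na + nb) / 2.0
    nc = (na + nb) - (na * na + nb * nb) / (na + nb)

    pooled = np.empty(n1c + n2c, dtype=np.int64)
    for l in range(n_loci):
        motif = motifs[l]
        # pooled within-stats on the union sample
        for i in range(n1c):
            pooled[i] = copies[a_lo + i, l]
        for i in range(n2c):
            pooled[n1c + i] = copies[b_lo + i, l]
        k, v, _ = _locus_within(pooled, motif)
        nal2 += k
        var2 += v

        # distinct alleles of the pooled sample
        su = np.sort(pooled)
        uals = np.empty(k, dtype=np.int64)
        uals[0] = su[0]
        ki = 1
        for i in range(1, su.shape[0]):
            if su[i] != su[i - 1]:
                uals[ki] = su[i]
                ki += 1

        # per-allele copy counts and heterozygote-carrier counts per pop
        c1 = np.zeros(k, dtype=np.float64)
        c2 = np.zeros(k, dtype=np.float64)
        h1 = np.zeros(k, dtype=np.float64)
        h2 = np.zeros(k, dtype=np.float64)
        for i in range(n1c):
            c1[np.searchsorted(uals, copies[a_lo + i, l])] += 1.0
        for i in range(n2c):
            c2[np.searchsorted(uals, copies[b_lo + i, l])] += 1.0
        for i in range(na):
            x = copies[a_lo + 2 * i, l]
            y = copies[a_lo + 2 * i + 1, l]
            if x != y:
                h1[np.searchsorted(uals, x)] += 1.0
                h1[np.searchsorted(uals, y)] += 1.0
        for i in range(nb):
            x = copies[b_lo + 2 * i, l]
            y = copies[b_lo + 2 * i + 1, l]
            if x != y:
                h2[np.searchsorted(uals, x)] += 1.0
                h2[np.searchsorted(uals, y)] += 1.0

        # Weir-Cockerham variance components summed over alleles; undefined
        # (left as nan via a zero denominator) when either sample holds a
        # single individual
        for ai in range(0 if nbar <= 1.0 else k):
            p1 = c1[ai] / n1c
            p2 = c2[ai] / n2c
            pbar = (na * p1 + nb * p2) / (na + nb)
            s2 = (na * (p1 - pbar) ** 2 + nb * (p2 - pbar) ** 2) / nbar
            hbar = (h1[ai] + h2[ai]) / (na + nb)
            a_comp = (nbar / nc) * (
                s2 - (pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
            )
            b_comp = (nbar / (nbar - 1.0)) * (
                pbar * (1.0 - pbar)
                - s2 / 2.0
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c_comp = hbar / 2.0
            fst_num += a_comp
            fst_den += a_comp + b_comp + c_comp

        # Rannala-Mountain classification log-likelihoods, both directions.
        # Smoothed reference frequency: (count + 1/k) / (copies + 1).
        inv_k = 1.0 / k
        for i in range(na):
            x = copies[a_lo + 2 * i, l]
            y = copies[a_lo + 2 * i + 1, l]
            px = (c2[np.searchsorted(uals, x)] + inv_k) / (n2c + 1.0)
            py = (c2[np.searchsorted(uals, y)] + inv_k) / (n2c + 1.0)
            if x == y:
                lik_ab += np.log(px * py)
            else:
                lik_ab += np.log(2.0 * px * py)
        for i in range(nb):
            x = copies[b_lo + 2 * i, l]
            y = copies[b_lo + 2 * i + 1, l]
            px = (c1[np.searchsorted(uals, x)] + inv_k) / (n1c + 1.0)
            py = (c1[np.searchsorted(uals, y)] + inv_k) / (n1c + 1.0)
            if x == y:
                lik_ba += np.log(px * py)
            else:
                lik_ba += np.log(2.0 * px * py)

        # shared-allele distance over inter-population genotype pairs
        for i in range(na):
            x1 = copies[a_lo + 2 * i, l]
            x2 = copies[a_lo + 2 * i + 1, l]
            for j in range(nb):
                y1 = copies[b_lo + 2 * j, l]
                y2 = copies[b_lo + 2 * j + 1, l]
                m11 = 1 if x1 == y1 else 0
                m22 = 1 if x2 == y2 else 0
                m12 = 1 if x1 == y2 else 0
                m21 = 1 if x2 == y1 else 0
                shared = max(m11 + m22, m12 + m21)
                das_sum += 1.0 - shared / 2.0

    nal2 /= n_loci
    var2 /= n_loci
    lik = 0.5 * (lik_ab / na + lik_ba / nb) / n_loci
    fst = fst_num / fst_den if fst_den != 0.0 else np.nan
    das = das_sum / (na * nb * n_loci)
    return nal2, var2, lik, fst, das


@njit(cache=True)
def _summarize_kernel(copies, starts, motifs, out):
    n_pops = starts.shape[0] - 1
    for p in range(n_pops):
        nal, var, m = _within_block(copies, starts[p], starts[p + 1], motifs)
        out[p] = nal
        out[n_pops + p] = var
        out[2 * n_pops + p] = m
    idx = 3 * n_pops
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            nal2, var2, lik, fst, das = _pair_block(
                copies, starts[i], starts[i + 1], starts[j], starts[j + 1], motifs
            )
            out[idx] = nal2
            out[idx + 1] = var2
            out[idx + 2] = lik
            out[idx + 3] = fst
            out[idx + 4] = das
            idx += 5


def summarize_matrix(
    copies: np.ndarray, starts: Sequence[int], motifs: np.ndarray
) -> np.ndarray:
    """Summary-statistic vector from a gene-copy allele matrix.

    ``copies`` is ``(total_copies, n_loci)`` integer allele sizes (bp) with
    populations in contiguous row blocks delimited by ``starts`` (length
    n_pops + 1); copy rows ``2i, 2i+1`` within a block form one diploid
    individual.
    """
    copies = np.ascontiguousarray(copies, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    motifs = np.asarray(motifs, dtype=np.int64)
    n_pops = len(starts) - 1
    out = np.empty(3 * n_pops + 5 * (n_pops * (n_pops - 1) // 2), dtype=np.float64)
    _summarize_kernel(copies, starts, motifs, out)
    return out


# ---------------------------------------------------------------------------
# Dataset-level interface
# ---------------------------------------------------------------------------


def to_diploid_matrix(
    dataset: MsatDataset, population_order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten diploid populations into the gene-copy matrix layout.

    Returns ``(copies, starts, motifs)``.  Individuals with any missing
    genotype at the panel loci are rejected (drop or impute upstream);
    single-entry genotypes are treated as homozygotes.
    """
    motifs = np.array([l.motif_length for l in dataset.loci], dtype=np.int64)
    blocks: list[np.ndarray] = []
    starts = [0]
    for code in population_order:
        inds = dataset.population_individuals(code)
        if not inds:
            raise ValueError(f"population {code!r} has no individuals")
        rows = np.empty((2 * len(inds), len(dataset.loci)), dtype=np.int64)
        for i, ind in enumerate(inds):
            if ind.ploidy not in (None, 2):
                raise ValueError(
                    f"{ind.id}: ploidy {ind.ploidy}; summary statistics operate "
                    "on diploid data (pseudo-diploidise tetraploids first)"
                )
            for j, locus in enumerate(dataset.loci):
                g = ind.genotypes.get(locus.name)
                if g is None or g.is_missing:
                    raise ValueError(
                        f"{ind.id}: missing genotype at {locus.name}; summary "
                        "statistics require complete diploid genotypes"
                    )
                alleles = g.allele_sizes
                if len(alleles) == 1:
                    alleles = (alleles[0], alleles[0])
                if len(alleles) != 2:
                    raise ValueError(
                        f"{ind.id}: {len(alleles)} alleles at {locus.name} in a "
                        "diploid genotype"
                    )
                rows[2 * i, j] = alleles[0]
                rows[2 * i + 1, j] = alleles[1]
        blocks.append(rows)
        starts.append(starts[-1] + rows.shape[0])
    return np.vstack(blocks), np.asarray(starts, dtype=np.int64), motifs


def summarize(dataset: MsatDataset, population_order: Sequence[str]) -> np.ndarray:
    """Full summary-statistic vector for a diploid dataset.

    The ordering follows :func:`stat_names` for ``population_order``;
    permuting the population order permutes the entries consistently.
    """
    if len(population_order) < 2:
        raise ValueError("need at least two populations")
    if len(set(population_order)) != len(population_order):
        raise ValueError("population_order contains duplicates")
    copies, starts, motifs = to_diploid_matrix(dataset, population_order)
    return summarize_matrix(copies, starts, motifs)


def within_stats(dataset: MsatDataset, population: str) -> tuple[float, float, float]:
    """(NAL, VAR, M) for one population, averaged over loci."""
    copies, starts, motifs = to_diploid_matrix(dataset, [population])
    return tuple(float(x) for x in _within_block(copies, 0, copies.shape[0], motifs))


def _pair(dataset: MsatDataset, pop_a: str, pop_b: str) -> tuple[float, ...]:
    copies, starts, motifs = to_diploid_matrix(dataset, [pop_a, pop_b])
    return _pair_block(copies, starts[0], starts[1], starts[1], starts[2], motifs)


def pairwise_fst(dataset: MsatDataset, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir & Cockerham theta; ``nan`` without polymorphism."""
    return float(_pair(dataset, pop_a, pop_b)[3])


def shared_allele_distance(dataset: MsatDataset, pop_a: str, pop_b: str) -> float:
    """Mean inter-population genotype distance 1 - (shared alleles)/2."""
    return float(_pair(dataset, pop_a, pop_b)[4])


def classification_index(dataset: MsatDataset, pop_a: str, pop_b: str) -> float:
    """Symmetrised Rannala-Mountain mean genotype log-likelihood.

    Reference allele frequencies are posterior-mean smoothed with a
    symmetric Dirichlet(1/k) prior, ``(count + 1/k) / (copies + 1)`` with
    ``k`` the number of distinct alleles in the pooled pair at the locus,
    so alleles absent from the reference population keep finite likelihood.
    """
    return float(_pair(dataset, pop_a, pop_b)[2])
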