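"""Summary statistics against hand-computed and brute-force oracles."""

import io

import numpy as np
import pytest

from msatrelict import coalsim as cs
from msatrelict import genodata
from msatrelict import sumstats as ss

from conftest import make_dataset


# -- independent pure-python oracles ---------------------------------------


def oracle_weir_cockerham(genos_a, genos_b):
    """Weir & Cockerham theta from explicit variance components a, b, c.

    ``genos_*``: list of (allele1, allele2) diploid genotypes, one locus
    per call handled by the caller stacking loci.
    """
    na, nb = len(genos_a), len(genos_b)
    nbar = (na + nb) / 2
    nc = (na + nb) - (na**2 + nb**2) / (na + nb)
    alleles = sorted({x for g in genos_a + genos_b for x in g})
    num = den = 0.0
    for al in alleles:
        p1 = sum(g.count(al) for g in genos_a) / (2 * na)
        p2 = sum(g.count(al) for g in genos_b) / (2 * nb)
        pbar = (na * p1 + nb * p2) / (na + nb)
        s2 = (na * (p1 - pbar) ** 2 + nb * (p2 - pbar) ** 2) / nbar
        h1 = sum(1 for g in genos_a if g[0] != g[1] and al in g)
        h2 = sum(1 for g in genos_b if g[0] != g[1] and al in g)
        hbar = (h1 + h2) / (na + nb)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num, den


def oracle_das(genos_a, genos_b):
    """Mean 1 - shared/2 over all inter-population genotype pairs."""
    total = 0.0
    for ga in genos_a:
        for gb in genos_b:
            shared = 0
            pool = list(gb)
            for x in ga:
                if x in pool:
                    pool.remove(x)
                    shared += 1
            total += 1 - shared / 2
    return total / (len(genos_a) * len(genos_b))


def _matrix(genos_by_pop):
    rows = []
    starts = [0]
    for genos in genos_by_pop:
        for g in genos:
            rows.append([g[0]])
            rows.append([g[1]])
        starts.append(len(rows))
    return np.asarray(rows, dtype=np.int64), np.asarray(starts), np.array([2])


class TestWithinStats:
    @pytest.mark.parametrize(
        "alleles, expected_k, expected_m",
        [
            ([100, 102, 104], 3, 1.0),   # k=3, range 2 repeat units
            ([100, 108], 2, 0.4),        # k=2, range 4 repeat units
            ([100, 100, 100], 1, 1.0),   # monomorphic
        ],
    )
    def test_m_index_formula(self, alleles, expected_k, expected_m):
        k, var, m = ss._locus_within(np.asarray(alleles, np.int64), 2)
        assert k == expected_k
        assert m == pytest.approx(expected_m)

    def test_variance_in_repeat_units(self):
        # bp sizes 100,104 at motif 2 are repeats 50,52: sample var = 2
        _, var, _ = ss._locus_within(np.array([100, 104]), 2)
        assert var == pytest.approx(2.0)

    def test_var_invariant_to_allele_shift(self, rng):
        vals = rng.integers(100, 140, size=20) * 2
        _, v1, _ = ss._locus_within(vals.astype(np.int64), 2)
        _, v2, _ = ss._locus_within((vals + 500).astype(np.int64), 2)
        assert v1 == pytest.approx(v2)

    def test_dataset_level_api(self, diploid_two_pop):
        nal, var, m = ss.within_stats(diploid_two_pop, "P1")
        # P1: La has alleles {100,102} (k=2), Lb {200,204} (k=2)
        assert nal == pytest.approx(2.0)
        assert 0 < m <= 1


class TestFst:
    def test_complete_fixation(self):
        genos_a = [(100, 100)] * 5
        genos_b = [(110, 110)] * 5
        m, starts, motifs = _matrix([genos_a, genos_b])
        v = ss.summarize_matrix(m, starts, motifs)
        assert v[ss.stat_names(["A", "B"]).index("FST_AxB")] == pytest.approx(1.0)

    def test_matches_component_oracle_on_fixture(self):
        genos_a = [(100, 102), (100, 100)]
        genos_b = [(102, 104), (104, 104)]
        num, den = oracle_weir_cockerham(genos_a, genos_b)
        m, starts, motifs = _matrix([genos_a, genos_b])
        v = ss.summarize_matrix(m, starts, motifs)
        got = v[ss.stat_names(["A", "B"]).index("FST_AxB")]
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_matches_oracle_on_random_multilocus_data(self, rng):
        for _ in range(5):
            n_loci = 3
            genos_a = [
                tuple(sorted(rng.integers(50, 55, 2) * 2)) for _ in range(8 * n_loci)
            ]
            genos_b = [
                tuple(sorted(rng.integers(52, 58, 2) * 2)) for _ in range(6 * n_loci)
            ]
            # stack into loci columns
            A = np.array(genos_a).reshape(8, n_loci, 2)
            B = np.array(genos_b).reshape(6, n_loci, 2)
            mat = np.vstack([
                A.transpose(0, 2, 1).reshape(16, n_loci),
                B.transpose(0, 2, 1).reshape(12, n_loci),
            ]).astype(np.int64)
            v = ss.summarize_matrix(mat, [0, 16, 28], np.full(n_loci, 2))
            num = den = 0.0
            for l in range(n_loci):
                ga = [tuple(mat[2 * i : 2 * i + 2, l]) for i in range(8)]
                gb = [tuple(mat[16 + 2 * i : 16 + 2 * i + 2, l]) for i in range(6)]
                nu, de = oracle_weir_cockerham(ga, gb)
                num += nu
                den += de
            got = v[ss.stat_names(["A", "B"]).index("FST_AxB")]
            assert got == pytest.approx(num / den, abs=1e-10)

    def test_random_split_of_panmictic_pool_centres_on_zero(self, rng):
        thetas = []
        for _ in range(80):
            pool = rng.integers(48, 56, size=(40, 2)) * 2
            perm = rng.permutation(40)
            genos = [tuple(sorted(pool[i])) for i in perm]
            m, starts, motifs = _matrix([genos[:20], genos[20:]])
            v = ss.summarize_matrix(m, starts, motifs)
            thetas.append(v[ss.stat_names(["A", "B"]).index("FST_AxB")])
        thetas = np.asarray(thetas)
        se = thetas.std(ddof=1) / np.sqrt(len(thetas))
        assert abs(thetas.mean()) < 3 * se + 1e-3


class TestSharedAlleleDistance:
    def test_examples(self):
        # {A,B} vs {B,C}: one shared allele -> distance 0.5
        m, starts, motifs = _matrix([[(100, 102)], [(102, 104)]])
        v = ss.summarize_matrix(m, starts, motifs)
        assert v[ss.stat_names(["A", "B"]).index("DAS_AxB")] == pytest.approx(0.5)

    def test_matches_multiset_oracle(self, rng):
        genos_a = [tuple(sorted(rng.integers(50, 54, 2) * 2)) for _ in range(7)]
        genos_b = [tuple(sorted(rng.integers(50, 54, 2) * 2)) for _ in range(9)]
        m, starts, motifs = _matrix([genos_a, genos_b])
        v = ss.summarize_matrix(m, starts, motifs)
        got = v[ss.stat_names(["A", "B"]).index("DAS_AxB")]
        assert got == pytest.approx(oracle_das(genos_a, genos_b), abs=1e-12)

    def test_symmetry(self, diploid_two_pop):
        assert ss.shared_allele_distance(
            diploid_two_pop, "P1", "P2"
        ) == pytest.approx(
            ss.shared_allele_distance(diploid_two_pop, "P2", "P1")
        )


class TestClassificationIndex:
    def test_monomorphic_identical_pops_score_zero(self):
        # k = 1 makes the smoothed frequency exactly (n + 1)/(n + 1) = 1
        m, starts, motifs = _matrix([[(100, 100)] * 4, [(100, 100)] * 4])
        v = ss.summarize_matrix(m, starts, motifs)
        assert v[ss.stat_names(["A", "B"]).index("LIK_AxB")] == pytest.approx(0.0)

    def test_disjoint_alleles_remain_finite(self):
        m, starts, motifs = _matrix([[(100, 100)] * 4, [(120, 120)] * 4])
        v = ss.summarize_matrix(m, starts, motifs)
        lik = v[ss.stat_names(["A", "B"]).index("LIK_AxB")]
        assert np.isfinite(lik) and lik < 0

    def test_smoothing_formula_on_single_genotype(self):
        # A = one heterozygote (100,102); B = two (100,100) homozygotes.
        # Pooled k = 2 distinct alleles; B holds 4 copies of 100, 0 of 102,
        # so the smoothed reference frequencies under B are
        # (4 + 1/2)/(4 + 1) = 0.9 and (0 + 1/2)/(4 + 1) = 0.1.
        m, starts, motifs = _matrix([[(100, 102)], [(100, 100), (100, 100)]])
        v = ss.summarize_matrix(m, starts, motifs)
        lik_ab = np.log(2 * 0.9 * 0.1)          # A's het under B
        lik_ba = np.log((1.5 / 3) ** 2)         # each B homozygote under A
        expected = 0.5 * (lik_ab + lik_ba)
        got = v[ss.stat_names(["A", "B"]).index("LIK_AxB")]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_self_likelihood_beats_cross_on_diverged_pops(self, rng):
        pv = cs.ParamVector(
            N1=2000, N2=2000, N3=2000, Ne=2000, Ns=2000,
            t1=4000, t2=8000, t3a=19000, t3b=15000,
        )
        mm = cs.MutationModel.fixed(6, 1e-3, 0.2)
        cfg = cs.SampleConfig(n_individuals=(12, 12, 12), ploidies=(2, 2, 2),
                              n_loci=6)
        wins = 0
        for _ in range(30):
            m = cs.simulate_allele_matrix(5, pv, mm, cfg, rng=rng)
            half = m[:24]
            other = m[24:48]
            self_v = ss.summarize_matrix(
                np.vstack([half[:12], half[12:]]), [0, 12, 24], np.full(6, 2)
            )
            cross_v = ss.summarize_matrix(
                np.vstack([half[:12], other[:12]]), [0, 12, 24], np.full(6, 2)
            )
            i = ss.stat_names(["A", "B"]).index("LIK_AxB")
            if self_v[i] >= cross_v[i]:
                wins += 1
        assert wins >= 25  # same-population genotypes are more likely


class TestSummarize:
    def test_three_population_vector_has_24_entries(self, rng):
        mm = cs.MutationModel.fixed(5, 5e-4, 0.2)
        pv = cs.ParamVector(N1=500, N2=500, N3=500, Ne=500, Ns=500,
                            t1=100, t2=300, t3a=2000, t3b=1000)
        cfg = cs.SampleConfig(n_individuals=(4, 4, 4), ploidies=(2, 2, 2),
                              n_loci=5)
        ds = cs.simulate_dataset(5, pv, mm, cfg, rng=rng)
        v = ss.summarize(ds, ["P1", "P2", "P3"])
        assert len(v) == 24
        assert len(ss.stat_names(["P1", "P2", "P3"])) == 24

    def test_permuting_population_order_permutes_entries(self, rng):
        mm = cs.MutationModel.fixed(4, 1e-3, 0.2)
        pv = cs.ParamVector(N1=500, N2=800, N3=300, Ne=500, Ns=500,
                            t1=500, t2=1500, t3a=8000, t3b=4000)
        cfg = cs.SampleConfig(n_individuals=(4, 5, 6), ploidies=(2, 2, 2),
                              n_loci=4)
        ds = cs.simulate_dataset(5, pv, mm, cfg, rng=rng)
        v1 = dict(zip(ss.stat_names(["P1", "P2", "P3"]),
                      ss.summarize(ds, ["P1", "P2", "P3"])))
        v2 = dict(zip(ss.stat_names(["P3", "P1", "P2"]),
                      ss.summarize(ds, ["P3", "P1", "P2"])))
        assert v1["NAL_P3"] == v2["NAL_P3"]
        assert v1["M_P1"] == v2["M_P1"]
        # pairwise statistics are symmetric in their arguments
        assert v1["FST_P1xP3"] == pytest.approx(v2["FST_P3xP1"])
        assert v1["DAS_P2xP3"] == pytest.approx(v2["DAS_P3xP2"])
        assert v1["LIK_P1xP2"] == pytest.approx(v2["LIK_P1xP2"])

    def test_csv_roundtrip_preserves_vector(self, rng):
        mm = cs.MutationModel.fixed(4, 1e-3, 0.2)
        pv = cs.ParamVector(N1=500, N2=500, N3=500, Ne=500, Ns=500,
                            t1=500, t2=1500, t3a=8000, t3b=4000)
        cfg = cs.SampleConfig(n_individuals=(4, 4, 4), ploidies=(2, 2, 2),
                              n_loci=4)
        ds = cs.simulate_dataset(5, pv, mm, cfg, rng=rng)
        buf = io.StringIO()
        genodata.write_csv_dataset(ds, buf)
        buf.seek(0)
        back = genodata.read_csv_dataset(buf)
        assert np.array_equal(
            ss.summarize(ds, ["P1", "P2", "P3"]),
            ss.summarize(back, ["P1", "P2", "P3"]),
        )

    def test_tetraploid_data_rejected(self, mixed_ploidy):
        with pytest.raises(ValueError, match="diploid"):
            ss.summarize(mixed_ploidy, ["TET", "DIP"])
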