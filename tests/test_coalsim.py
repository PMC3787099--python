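"""Coalescent engine and GSM mutation: closed forms, priors, determinism."""

import numpy as np
import pytest

from msatrelict import coalsim as cs
from msatrelict import sumstats as ss


def single_pop_config(n_individuals, n_loci=1):
    return cs.SampleConfig(
        n_individuals=(n_individuals, 0, 0), ploidies=(2, 2, 2), n_loci=n_loci
    )


def single_pop_params(n):
    # scenario 1 with t = 0 collapses to one panmictic deme of size Ns
    return cs.ParamVector(N1=n, N2=n, N3=n, Ns=n, t=0.0)


class TestPriors:
    @pytest.mark.parametrize("sid", [1, 5])
    def test_bounds_hold_on_ten_thousand_draws(self, sid, rng):
        params, mu, p, sni = cs.sample_priors_batch(sid, 10_000, 11, rng)
        scenario = cs.DemographicScenario.from_id(sid)
        cols = dict(zip(scenario.param_names, params.T))
        for nm in scenario.param_names:
            if nm.startswith("N"):
                assert cols[nm].min() >= 10 and cols[nm].max() <= 20_000
            else:
                assert cols[nm].min() >= 1 and cols[nm].max() <= 20_000
        assert mu.min() >= 1e-5 and mu.max() <= 1e-2
        assert p.min() >= 0.01 and p.max() <= 0.9
        assert np.all(sni == 0.0)  # flanking indels off by default

    def test_time_ordering_constraint(self, rng):
        params, *_ = cs.sample_priors_batch(4, 10_000, 11, rng)
        names = cs.DemographicScenario.from_id(4).param_names
        c = dict(zip(names, params.T))
        assert np.all(c["t1"] < c["t2"])
        assert np.all(c["t2"] < c["t3a"])
        assert np.all(c["t2"] < c["t3b"])

    def test_fixed_seed_reproduces_draws(self):
        a = cs.sample_priors_batch(5, 100, 11, np.random.default_rng(9))
        b = cs.sample_priors_batch(5, 100, 11, np.random.default_rng(9))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_single_draw_api(self, rng):
        pv, mm = cs.sample_priors(5, rng)
        assert np.isnan(pv.t)
        assert pv.t1 < pv.t2 < min(pv.t3a, pv.t3b)
        assert len(mm.mu) == 11


class TestScenarioTable:
    def test_seven_scenarios_enumerate_roles_once(self):
        seen = set()
        for sid in cs.SCENARIO_IDS:
            sc = cs.DemographicScenario.from_id(sid)
            if sid == 1:
                assert sc.is_trichotomy
                continue
            seen.add((sc.outgroup, sc.order))
        # 3 outgroup choices x 2 orderings, each exactly once
        assert len(seen) == 6
        assert {o for o, _ in seen} == {0, 1, 2}

    def test_best_supported_scenario_roles(self):
        # the Moroccan pool (index 0) is the outgroup; the Tunisian pool
        # (index 1) diverged most recently; its order-swap is scenario 4
        s5 = cs.DemographicScenario.from_id(5)
        assert s5.outgroup == 0 and s5.order == (2, 1)
        s4 = cs.DemographicScenario.from_id(4)
        assert s4.outgroup == 0 and s4.order == (1, 2)


class TestCoalescentClosedForms:
    def test_pairwise_tmrca_is_2n(self, rng):
        n_diploid = 1000
        reps = 10_000
        pv = single_pop_params(n_diploid)
        cfg = single_pop_config(1)
        tmrca = np.array([
            cs.simulate_genealogy(1, pv, cfg, rng)[0][-1] for _ in range(reps)
        ])
        se = tmrca.std(ddof=1) / np.sqrt(reps)
        assert abs(tmrca.mean() - 2 * n_diploid) < 3 * se

    def test_tmrca_of_n_copies(self, rng):
        # E[TMRCA] = 4N (1 - 1/n) generations for n gene copies
        n_diploid, n_copies, reps = 500, 10, 10_000
        pv = single_pop_params(n_diploid)
        cfg = single_pop_config(n_copies // 2)
        tmrca = np.array([
            cs.simulate_genealogy(1, pv, cfg, rng)[0][-1] for _ in range(reps)
        ])
        expected = 4 * n_diploid * (1 - 1 / n_copies)
        se = tmrca.std(ddof=1) / np.sqrt(reps)
        assert abs(tmrca.mean() - expected) < 3 * se

    def test_outgroup_isolated_before_deep_split(self, rng):
        # with t3a far beyond every other event, outgroup lineages cannot
        # coalesce with the rest before t3a
        pv = cs.ParamVector(
            N1=100, N2=100, N3=100, Ne=100, Ns=100,
            t1=10, t2=20, t3a=50_000, t3b=30,
        )
        cfg = cs.SampleConfig(n_individuals=(2, 2, 2), ploidies=(2, 2, 2), n_loci=1)
        for _ in range(50):
            times, parent = cs.simulate_genealogy(5, pv, cfg, rng)
            # outgroup tips of scenario 5 are population 0 (rows 0..3)
            n = 12
            for tip in range(4):
                node = tip
                while parent[node] != -1 and times[parent[node]] < 50_000:
                    node = parent[node]
                # every ancestor younger than t3a subtends only outgroup tips
                desc = _tips_below(parent, n, node)
                assert desc <= {0, 1, 2, 3}


def _tips_below(parent, n_tips, node):
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parent):
        children.setdefault(p, []).append(i)
    stack, tips = [node], set()
    while stack:
        x = stack.pop()
        if x < n_tips:
            tips.add(x)
        stack.extend(children.get(x, []))
    return tips


class TestMutation:
    def test_zero_rate_yields_monomorphic_tips(self):
        pv = single_pop_params(500)
        mm = cs.MutationModel.fixed(3, 0.0, 0.2)
        cfg = single_pop_config(10, n_loci=3)
        m = cs.simulate_allele_matrix(1, pv, mm, cfg, rng=5)
        assert np.all(m == cfg.origin_bp)

    def test_geometric_step_mean(self, rng):
        # P(s) = (1-p) p^(s-1) has mean 1/(1-p) = 1.25 at p = 0.2; the
        # engine draws steps via numpy's geometric with success prob 1-p
        draws = rng.geometric(1 - 0.2, size=100_000)
        assert draws.mean() == pytest.approx(1.25, abs=0.01)

    def test_variance_monotone_in_mutation_rate(self):
        # mean within-population allele-size variance grows with mu
        mus = [1e-5, 1e-4, 5e-4, 2e-3]
        pv = single_pop_params(1000)
        cfg = single_pop_config(20, n_loci=10)
        mean_vars = []
        for i, mu in enumerate(mus):
            mm = cs.MutationModel.fixed(10, mu, 0.2)
            m = cs.simulate_allele_matrix(1, pv, mm, cfg, rng=100 + i)
            v = np.var(m / 2.0, axis=0, ddof=1).mean()
            mean_vars.append(v)
        assert all(a < b for a, b in zip(mean_vars, mean_vars[1:]))

    def test_determinism_under_fixed_seed(self):
        pv = cs.ParamVector(
            N1=800, N2=900, N3=1000, Ne=500, Ns=700,
            t1=50, t2=400, t3a=5000, t3b=2000,
        )
        mm = cs.MutationModel.fixed(11, 5e-4, 0.2)
        a = cs.simulate_allele_matrix(5, pv, mm, cs.SampleConfig(), rng=77)
        b = cs.simulate_allele_matrix(5, pv, mm, cs.SampleConfig(), rng=77)
        assert np.array_equal(a, b)


class TestSimulateDataset:
    def test_panmixia_limit_fst_near_zero(self, rng):
        # equal sizes, all splits at one generation: the three populations
        # are one panmictic pool, so theta centres on zero
        pv = cs.ParamVector(
            N1=1000, N2=1000, N3=1000, Ne=1000, Ns=1000,
            t1=1, t2=1.01, t3a=1.03, t3b=1.02,
        )
        mm = cs.MutationModel.fixed(8, 5e-4, 0.2)
        cfg = cs.SampleConfig(n_individuals=(15, 15, 15), ploidies=(2, 2, 2),
                              n_loci=8)
        thetas = []
        for k in range(60):
            m = cs.simulate_allele_matrix(5, pv, mm, cfg, rng=rng)
            v = ss.summarize_matrix(m, [0, 30, 60, 90], np.full(8, 2))
            thetas.append(v[12])  # FST of the first pair
        thetas = np.asarray(thetas)
        se = thetas.std(ddof=1) / np.sqrt(len(thetas))
        assert abs(thetas.mean()) < 3 * se + 1e-3

    def test_dataset_assembly_and_tetraploid_mode(self, rng):
        pv = cs.ParamVector(
            N1=500, N2=500, N3=500, Ne=500, Ns=500,
            t1=100, t2=200, t3a=3000, t3b=2500,
        )
        mm = cs.MutationModel.fixed(4, 1e-3, 0.2)
        cfg = cs.SampleConfig(n_individuals=(5, 6, 7), ploidies=(4, 2, 2),
                              n_loci=4)
        ds = cs.simulate_dataset(5, pv, mm, cfg, rng=rng)
        assert len(ds.individuals) == 18
        p1 = ds.population_individuals("P1")
        assert all(i.ploidy == 4 for i in p1)
        # dosage-ambiguous scoring: between 1 and 4 distinct alleles
        for i in p1:
            for g in i.genotypes.values():
                assert 1 <= g.observed_distinct <= 4
                assert len(g.allele_sizes) == g.observed_distinct


def test_matches_msprime_single_population_tmrca(rng):
    """Independent oracle: msprime's coalescent for one population."""
    msprime = pytest.importorskip("msprime")
    n_diploid, reps = 700, 3000
    pv = single_pop_params(n_diploid)
    cfg = single_pop_config(4)  # 8 gene copies
    mine = np.array([
        cs.simulate_genealogy(1, pv, cfg, rng)[0][-1] for _ in range(reps)
    ])
    theirs = np.array([
        ts.max_root_time
        for ts in msprime.sim_ancestry(
            samples=4, population_size=n_diploid, ploidy=2,
            num_replicates=reps, random_seed=1234,
        )
    ])
    se = np.sqrt(mine.var(ddof=1) / reps + theirs.var(ddof=1) / reps)
    assert abs(mine.mean() - theirs.mean()) < 3 * se
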