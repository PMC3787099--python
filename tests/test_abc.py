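"""ABC machinery: rejection, scenario choice, estimation, assessments."""

import warnings

import numpy as np
import pytest

from msatrelict import abc as abcm
from msatrelict.coalsim import SampleConfig

SMALL_CFG = SampleConfig(n_individuals=(8, 8, 8), ploidies=(2, 2, 2), n_loci=6)


@pytest.fixture(scope="module")
def small_table():
    """1000-row two-scenario table at reduced sample sizes (fast)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return abcm.build_reference_table(
            [4, 5], 500, SMALL_CFG, np.random.default_rng(42)
        )


class TestRejection:
    def test_matches_brute_force_scan(self, small_table):
        obs = small_table.stats[123]
        idx, d = abcm.rejection_select(small_table, obs, 50)
        zn = np.where(
            np.isfinite(small_table.normalize(small_table.stats)),
            small_table.normalize(small_table.stats), 0.0,
        )
        zo = small_table.normalize(obs)
        brute = np.sqrt(((zn - zo) ** 2).sum(axis=1))
        expect = np.argsort(brute, kind="stable")[:50]
        assert np.array_equal(idx, expect)
        assert np.allclose(d, brute[expect])

    def test_observed_table_row_ranks_first_at_zero(self, small_table):
        idx, d = abcm.rejection_select(small_table, small_table.stats[7], 3)
        assert idx[0] == 7
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_full_tolerance_returns_whole_table(self, small_table):
        idx, _ = abcm.rejection_select(
            small_table, small_table.stats[0], small_table.n_rows
        )
        assert sorted(idx) == list(range(small_table.n_rows))

    def test_oversized_keep_rejected(self, small_table):
        with pytest.raises(ValueError, match="exceeds table size"):
            abcm.rejection_select(small_table, small_table.stats[0], 10**9)


class TestScenarioChoice:
    def test_probabilities_sum_to_one(self, small_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = abcm.model_choice(small_table, small_table.stats[3], n_closest=200)
        assert sum(res.probabilities.values()) == pytest.approx(1.0)
        for lo, hi in res.ci.values():
            assert 0.0 <= lo <= hi <= 1.0
        assert res.chosen in res.scenario_ids

    def test_identical_simulators_give_half_half(self, rng):
        # same generative process labelled as two classes: P must centre
        # on 0.5 regardless of the query point
        X = rng.normal(size=(2000, 5))
        y = np.repeat([0, 1], 1000)
        est = abcm.ABCScenarioChoice(n_closest=400).fit(X, y)
        probs = est.predict_proba(rng.normal(size=(40, 5)) * 0.3)
        mean_p = probs[:, 0].mean()
        se = probs[:, 0].std(ddof=1) / np.sqrt(len(probs))
        assert abs(mean_p - 0.5) < max(3 * se, 0.05)

    def test_regression_agrees_with_rejection_vote_when_separated(self, rng):
        # two well-separated Gaussian clouds: the weighted vote fraction and
        # the regression probability must agree closely
        X = np.vstack([
            rng.normal(0, 1, size=(800, 4)),
            rng.normal(6, 1, size=(800, 4)),
        ])
        y = np.repeat([0, 1], 800)
        est = abcm.ABCScenarioChoice(n_closest=300).fit(X, y)
        for query in (np.zeros(4), np.full(4, 6.0), np.full(4, 2.5)):
            xn = (query - est.center_) / est.scale_
            d = np.sqrt(((est.Xn_ - xn) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[:300]
            w = 1 - (d[order] / d[order].max()) ** 2
            vote = np.average(est.y_[order] == 0, weights=w)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = est.predict_proba(query[None, :])[0, 0]
            assert abs(p - vote) < 0.1

    def test_absent_scenario_gets_zero_probability(self, rng):
        X = np.vstack([
            rng.normal(0, 0.5, size=(300, 3)),
            rng.normal(10, 0.5, size=(300, 3)),
            rng.normal(20, 0.5, size=(300, 3)),
        ])
        y = np.repeat([1, 2, 3], 300)
        est = abcm.ABCScenarioChoice(n_closest=100).fit(X, y)
        with pytest.warns(UserWarning, match="absent|only one"):
            res = est.posterior(np.zeros(3))
        assert res.probabilities[3] == 0.0
        assert res.probabilities[1] > 0.9


class TestParameterEstimation:
    def test_quantile_ordering_and_positivity(self, small_table):
        s = abcm.estimate_parameters(
            small_table, 5, small_table.stats[11], n_keep=0.4
        )
        for nm in s.param_names:
            assert s.q05[nm] <= s.q95[nm]
            assert s.mode[nm] > 0

    def test_no_adjustment_reproduces_rejection_sample(self, small_table):
        obs = small_table.stats[2]
        est = abcm.ABCParameterEstimator.from_table(
            small_table, 5, n_keep=50, adjust=False, transform="none"
        )
        sample, w = est.posterior_sample(obs)
        sub = small_table.for_scenario(5)
        idx, _ = abcm.rejection_select(sub, obs, 50)
        y, names = small_table.param_matrix(5)
        assert np.array_equal(sample, y[idx])

    def test_toy_model_recovery_beats_prior(self, rng):
        # one-parameter toy: stat = log(theta) + small noise; the adjusted
        # posterior must concentrate near the generating value
        theta = rng.uniform(10, 1000, size=4000)
        X = (np.log(theta) + rng.normal(0, 0.05, size=4000))[:, None]
        est = abcm.ABCParameterEstimator(n_keep=300, transform="log").fit(
            X, theta[:, None], param_names=["theta"]
        )
        errors = []
        for true in (50.0, 200.0, 600.0):
            mode = est.posterior_summary([np.log(true)]).mode["theta"]
            errors.append(abs(mode - true) / true)
        assert np.mean(errors) < 0.1

    def test_predict_returns_mode_matrix(self, small_table):
        est = abcm.ABCParameterEstimator.from_table(small_table, 4, n_keep=0.3)
        out = est.predict(small_table.stats[:3])
        assert out.shape == (3, 9)
        assert np.all(out > 0)


class TestAssessments:
    def test_confusion_rows_sum_to_pseudo_count(self, small_table):
        conf = abcm.assess_confidence(
            small_table, SMALL_CFG, np.random.default_rng(5),
            n_pseudo=12, n_closest=100,
        )
        assert conf.matrix.shape == (2, 2)
        assert np.all(conf.matrix.sum(axis=1) == 12)
        t1 = conf.type_one()
        t2 = conf.type_two()
        for sid in conf.scenario_ids:
            assert 0 <= t1[sid] <= 1
            assert 0 <= t2[sid] <= 1

    def test_truth_oracle_stub_has_zero_bias(self, small_table, rng):
        # supply known truths and an estimator that returns them: the
        # quality metrics must be exactly ideal
        truths = np.column_stack([
            rng.uniform(100, 1000, 6),   # N1
            rng.uniform(100, 1000, 6),   # N2
            rng.uniform(100, 1000, 6),   # N3
            rng.uniform(100, 1000, 6),   # Ne
            rng.uniform(100, 1000, 6),   # Ns
            np.sort(rng.uniform(10, 5000, (6, 4)), axis=1),  # t1<t2<t3a,t3b
        ])
        calls = iter(range(len(truths)))
        q = abcm.assess_estimation(
            small_table, 5, SMALL_CFG, np.random.default_rng(8),
            n_pseudo=6, truth_params=truths,
            point_estimator=lambda s, it=calls: truths[next(it)],
        )
        for nm in q.param_names:
            assert q.relative_bias[nm] == 0.0
            assert q.relative_rmse[nm] == 0.0
            assert q.factor2[nm] == 1.0

    def test_assigned_composition_sums_to_one(self, small_table):
        conf = abcm.assess_confidence(
            small_table, SMALL_CFG, np.random.default_rng(6),
            n_pseudo=10, n_closest=100,
        )
        for sid in conf.scenario_ids:
            comp = conf.assigned_composition(sid)
            total = sum(v for v in comp.values() if np.isfinite(v))
            if total:
                assert total == pytest.approx(1.0)


class TestReferenceTable:
    def test_equal_per_scenario_counts_and_determinism(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = abcm.build_reference_table(
                [1, 5], 100, SMALL_CFG, np.random.default_rng(77)
            )
            b = abcm.build_reference_table(
                [1, 5], 100, SMALL_CFG, np.random.default_rng(77)
            )
        assert a.scenario_counts() == {1: 100, 5: 100}
        assert np.array_equal(a.stats, b.stats)
        assert np.array_equal(a.params, b.params, equal_nan=True)

    def test_save_load_roundtrip(self, small_table, tmp_path):
        path = tmp_path / "table.npz"
        small_table.save(path)
        back = abcm.ReferenceTable.load(path)
        assert np.array_equal(back.stats, small_table.stats)
        assert np.array_equal(back.scenario_ids, small_table.scenario_ids)
        assert back.stat_names == small_table.stat_names

    def test_trichotomy_rows_use_reduced_parameter_set(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = abcm.build_reference_table(
                [1], 50, SMALL_CFG, np.random.default_rng(3)
            )
        y, names = t.param_matrix(1)
        assert names == ["N1", "N2", "N3", "Ns", "t"]
        assert np.all(np.isfinite(y))
        # columns outside scenario 1's parameters stay nan
        assert np.all(np.isnan(t.params[:, abcm.PARAM_COLS.index("t1")]))
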