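"""Simulation harness: banks, examinees, responses, MAP scoring, ANOVA."""

import numpy as np
import pytest
from scipy import stats

from cdta import (
    ExperimentConfig,
    class_probability_table,
    empirical_prior,
    enumerate_latent_classes,
    evaluate,
    expected_pcr_independent,
    generate_examinees,
    generate_item_bank,
    map_classify,
    one_way_anova,
    outperform_proportions,
    run_experiment,
    simulate_responses,
    summarize,
)
from cdta.cdm_core import ItemParameters, QMatrix
from cdta.sim_eval import PopulationRole, ResponseMatrix


class TestGenerateItemBank:
    def test_no_empty_q_rows(self):
        q, _ = generate_item_bank(500, 4, "DINA", np.random.default_rng(0))
        assert (q.entries.sum(axis=1) >= 1).all()

    def test_slip_mean_matches_uniform(self):
        _, params = generate_item_bank(10_000, 4, "DINA", np.random.default_rng(1))
        se = (0.4 - 0.05) / np.sqrt(12 * 10_000)
        assert abs(params.slip.mean() - 0.225) < 3 * se
        assert abs(params.guess.mean() - 0.225) < 3 * se

    def test_single_attribute_fraction(self):
        q, _ = generate_item_bank(30_000, 4, "DINA", np.random.default_rng(2))
        frac = (q.attributes_per_item() == 1).mean()
        p = 4 / 15
        se = np.sqrt(p * (1 - p) / 30_000)
        assert abs(frac - p) < 3 * se

    def test_rrum_ranges(self):
        q, params = generate_item_bank(2000, 3, "RRUM", np.random.default_rng(3))
        assert params.baseline.min() >= 0.75 and params.baseline.max() <= 0.95
        measured = ~np.isnan(params.penalty)
        assert np.array_equal(measured, q.entries == 1)
        vals = params.penalty[measured]
        assert vals.min() >= 0.2 and vals.max() <= 0.95


class TestGenerateExaminees:
    def test_marginal_mastery_half_when_independent(self):
        pop = generate_examinees(100_000, 4, 0.0, np.random.default_rng(0))
        se = 0.5 / np.sqrt(100_000)
        assert np.abs(pop.alphas.mean(axis=0) - 0.5).max() < 3 * se

    def test_independent_patterns_uniform(self):
        pop = generate_examinees(64_000, 4, 0.0, np.random.default_rng(1))
        space = enumerate_latent_classes(4)
        counts = np.bincount(space.pattern_index(pop.alphas), minlength=16)
        chi2 = ((counts - 4000) ** 2 / 4000).sum()
        assert stats.chi2.sf(chi2, 15) > 0.01

    def test_correlated_orthant_probability(self):
        """P(both mastered) under rho=0.5 is 1/4 + arcsin(0.5)/(2 pi) = 1/3."""
        pop = generate_examinees(200_000, 2, 0.5, np.random.default_rng(2))
        both = (pop.alphas.sum(axis=1) == 2).mean()
        expected = 1 / 4 + np.arcsin(0.5) / (2 * np.pi)
        se = np.sqrt(expected * (1 - expected) / 200_000)
        assert abs(both - expected) < 4 * se

    def test_rho_bounds(self):
        with pytest.raises(ValueError, match="rho"):
            generate_examinees(10, 2, 1.0, np.random.default_rng(0))


class TestSimulateResponses:
    @pytest.fixture
    def setup(self, space_k2, dina_bank_k2):
        q, params = dina_bank_k2
        table = class_probability_table(q, params, space_k2)
        pop = generate_examinees(100_000, 2, 0.0, np.random.default_rng(0))
        return table, pop, space_k2

    def test_masters_correct_rate(self, setup):
        table, pop, space = setup
        rng = np.random.default_rng(1)
        resp = simulate_responses(np.array([0]), table, pop, space, rng)
        masters = pop.alphas[:, 0] == 1  # item 0 measures attribute 1 only
        rate = resp.X[masters, 0].mean()
        n = masters.sum()
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(rate - 0.9) < 3 * se
        rate_non = resp.X[~masters, 0].mean()
        assert abs(rate_non - 0.2) < 3 * np.sqrt(0.2 * 0.8 / (len(masters) - n))

    def test_same_seed_identical(self, setup):
        table, pop, space = setup
        r1 = simulate_responses(np.array([0, 2]), table, pop, space, np.random.default_rng(9))
        r2 = simulate_responses(np.array([0, 2]), table, pop, space, np.random.default_rng(9))
        assert np.array_equal(r1.X, r2.X)


class TestEmpiricalPrior:
    def test_point_mass(self, space_k2):
        from cdta.sim_eval import Population

        pop = Population(alphas=np.tile([1, 0], (50, 1)), rho=0.0,
                         role=PopulationRole.PRIOR_GROUP)
        prior = empirical_prior(pop, space_k2)
        assert prior.tolist() == [0, 0, 1, 0]

    def test_counting_oracle(self, space_k3):
        pop = generate_examinees(5000, 3, 0.0, np.random.default_rng(4))
        prior = empirical_prior(pop, space_k3)
        assert prior.sum() == pytest.approx(1.0)
        for c, pattern in enumerate(space_k3.patterns):
            tally = (pop.alphas == pattern).all(axis=1).mean()
            assert prior[c] == pytest.approx(tally, abs=1e-12)


class TestMapClassify:
    def test_single_item_two_class_posterior(self):
        space = enumerate_latent_classes(1)
        q = QMatrix([[1]])
        params = ItemParameters(model="DINA", slip=[0.1], guess=[0.2])
        table = class_probability_table(q, params, space)
        prior = np.array([0.5, 0.5])
        resp = ResponseMatrix(X=np.array([[1], [0]]), item_ids=np.array([0]))
        alphas = map_classify(resp, table, prior, space)
        # X=1: P(1|master)=0.9 > P(1|non)=0.2 -> classified as master
        assert alphas.tolist() == [[1], [0]]

    def test_near_noiseless_recovery(self, space_k3):
        q = QMatrix(np.eye(3, dtype=int))
        params = ItemParameters(model="DINA", slip=[0.001] * 3, guess=[0.001] * 3)
        table = class_probability_table(q, params, space_k3)
        pop = generate_examinees(200, 3, 0.0, np.random.default_rng(5))
        # error-free responses: respond by ideal response
        classes = space_k3.pattern_index(pop.alphas)
        X = table.ideal[classes, :]
        resp = ResponseMatrix(X=X, item_ids=np.arange(3))
        prior = np.full(8, 1 / 8)
        alphas = map_classify(resp, table, prior, space_k3)
        assert np.array_equal(alphas, pop.alphas)

    def test_tie_breaks_to_first_class(self, space_k2):
        q = QMatrix([[1, 1]])
        params = ItemParameters(model="DINA", slip=[0.5], guess=[0.5])
        table = class_probability_table(q, params, space_k2)
        resp = ResponseMatrix(X=np.array([[1]]), item_ids=np.array([0]))
        alphas = map_classify(resp, table, np.full(4, 0.25), space_k2)
        assert alphas.tolist() == [[0, 0]]

    def test_zero_prior_classes_excluded(self, space_k2, dina_bank_k2):
        q, params = dina_bank_k2
        table = class_probability_table(q, params, space_k2)
        prior = np.array([0.5, 0.0, 0.0, 0.5])  # only extreme classes allowed
        pop = generate_examinees(100, 2, 0.0, np.random.default_rng(6))
        resp = simulate_responses(np.arange(3), table, pop, space_k2, np.random.default_rng(7))
        alphas = map_classify(resp, table, prior, space_k2)
        assert set(space_k2.pattern_index(alphas).tolist()) <= {0, 3}

    def test_all_zero_prior_rejected(self, space_k2, table_k2):
        resp = ResponseMatrix(X=np.zeros((1, 3), dtype=int), item_ids=np.arange(3))
        with pytest.raises(ValueError, match="prior"):
            map_classify(resp, table_k2, np.zeros(4), space_k2)


class TestEvaluate:
    def test_perfect(self):
        a = np.array([[1, 0], [0, 1]])
        res = evaluate(a, a)
        assert res.ACR == 1.0 and res.PCR == 1.0

    def test_hand_count(self):
        truth = np.array([[1, 0], [0, 1]])
        est = np.array([[1, 0], [1, 1]])
        res = evaluate(est, truth)
        assert res.ACR == pytest.approx(0.75)
        assert res.PCR == pytest.approx(0.5)

    def test_pcr_never_exceeds_acr(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            truth = rng.integers(0, 2, (50, 4))
            est = rng.integers(0, 2, (50, 4))
            res = evaluate(est, truth)
            assert res.PCR <= res.ACR

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            evaluate(np.zeros((2, 2)), np.zeros((3, 2)))


class TestExpectedPcrIndependent:
    @pytest.mark.parametrize(
        "rates, expected",
        [((0.1, 0.9), 0.09), ((0.4, 0.4), 0.16), ((1, 1, 1), 1.0)],
    )
    def test_product_rule(self, rates, expected):
        assert expected_pcr_independent(rates) == pytest.approx(expected)


class TestOneWayAnova:
    def test_identical_groups(self):
        y = np.array([0.9, 0.91, 0.92])
        res = one_way_anova(y, y)
        assert res.S_A == pytest.approx(0.0)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_hand_values(self):
        res = one_way_anova([1, 2, 3], [3, 4, 5])
        assert res.S_A == pytest.approx(6.0)
        assert res.S_E == pytest.approx(4.0)
        assert res.F == pytest.approx(6.0)
        assert res.n == 3
        assert res.p == pytest.approx(stats.f.sf(6.0, 1, 4))

    def test_equals_squared_pooled_t(self):
        rng = np.random.default_rng(10)
        y1, y2 = rng.normal(0, 1, 30), rng.normal(0.3, 1, 30)
        res = one_way_anova(y1, y2)
        t = stats.ttest_ind(y1, y2, equal_var=True)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_null_p_values_uniform(self):
        """Under identical generating distributions p-values are U(0,1)."""
        rng = np.random.default_rng(11)
        pvals = [
            one_way_anova(rng.normal(0, 1, 10), rng.normal(0, 1, 10)).p
            for _ in range(1000)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_sample_size_error(self):
        with pytest.raises(ValueError, match="two observations"):
            one_way_anova([1.0], [2.0])


@pytest.fixture(scope="module")
def small_run():
    cfg = ExperimentConfig(model="DINA", K=2, M=40, N=300, J=6,
                           replications=4, seed=123,
                           methods=("mmd", "random"), milp_time_limit=2.0)
    return cfg, run_experiment(cfg)


class TestRunExperiment:
    def test_long_table_shape(self, small_run):
        cfg, table = small_run
        assert len(table) == 4 * 2
        assert set(table.columns) == {"rep", "method", "constraint", "acr", "pcr"}

    def test_summary_equals_column_means(self, small_run):
        _, table = small_run
        summary = summarize(table)
        for _, row in summary.iterrows():
            sub = table[table.method == row.method]
            assert row.acr == pytest.approx(sub.acr.mean())
            assert row.pcr == pytest.approx(sub.pcr.mean())

    def test_pcr_le_acr_each_replication(self, small_run):
        _, table = small_run
        assert (table.pcr <= table.acr + 1e-12).all()

    def test_reproducible_under_seed(self, small_run):
        cfg, table = small_run
        again = run_experiment(cfg)
        assert table.equals(again)

    def test_outperform_proportions_bounds(self, small_run):
        _, table = small_run
        props = outperform_proportions(table, "pcr")
        assert ((props.proportion >= 0) & (props.proportion <= 1)).all()

    def test_map_beats_prior_mode_guessing(self):
        """MAP with item information should beat always-guessing the modal class."""
        cfg = ExperimentConfig(model="DINA", K=2, M=40, N=500, J=8,
                               replications=2, seed=77, methods=("random",))
        space = enumerate_latent_classes(2)
        master = np.random.SeedSequence(cfg.seed)
        from cdta.sim_eval import run_replication

        for rep, seq in enumerate(master.spawn(cfg.replications)):
            rows = run_replication(cfg, rep, seq)
            # modal-class guessing accuracy is at most max prior ~ 0.25 + noise
            assert rows[0]["pcr"] > 0.35

    def test_simplified_vs_full_no_significant_difference(self):
        """Reduced run of the simplification check: distance-matrix pruning
        should not significantly change accuracy (DINA, no constraints)."""
        cfg = ExperimentConfig(model="DINA", K=3, M=80, N=500, J=10,
                               replications=12, seed=2024,
                               methods=("mmd", "mmd_full"), milp_time_limit=2.0)
        table = run_experiment(cfg)
        wide = table.pivot(index="rep", columns="method", values="acr")
        res = one_way_anova(wide["mmd"].to_numpy(), wide["mmd_full"].to_numpy())
        assert res.p > 0.05
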