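"""Type 2 noise and signal-loss models: simulation, exact rates, optimization."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import metacrit as mc
from metacrit import (
    DegenerateModelError,
    ProcessModelParams,
    RewardMatrix2,
    SDTParams,
    Type2Criteria,
)
from metacrit.process_models import _mass_lower, _mass_upper

from conftest import binomial_se

COARSE = np.arange(0.0, 3.0 + 1e-9, 2e-3)  # "S2"-side grid for optimization


class TestProcessModelParams:
    def test_standard_reduction_labels(self):
        assert ProcessModelParams.noise(0.0).model == "standard"
        assert ProcessModelParams.loss(0.0, 0.0).model == "standard"
        assert ProcessModelParams("noise", 0.0, 0.0).model == "standard"

    def test_noise_fixes_k(self):
        with pytest.raises(ValueError):
            ProcessModelParams("noise", 0.5, 0.2)

    def test_degenerate_combination_rejected(self):
        with pytest.raises(DegenerateModelError):
            ProcessModelParams("loss", 0.0, 1.0)

    def test_bounds(self):
        with pytest.raises(ValueError):
            ProcessModelParams("loss", 0.1, 1.5)
        with pytest.raises(ValueError):
            ProcessModelParams("noise", -0.1, 0.0)


class TestSimulateTrials:
    def test_standard_model_copies_evidence(self, unbiased_d2, unit_criteria):
        t = mc.simulate_trials(
            ProcessModelParams.standard(), unbiased_d2, unit_criteria, 5000, 1
        )
        assert np.array_equal(t.x1.values, t.x2.values)

    def test_reproducible_from_seed(self, unbiased_d2, unit_criteria):
        pm = ProcessModelParams.noise(0.5)
        a = mc.simulate_trials(pm, unbiased_d2, unit_criteria, 2000, 99)
        b = mc.simulate_trials(pm, unbiased_d2, unit_criteria, 2000, 99)
        assert a.equals(b)

    def test_decision_and_confidence_rules(self, unbiased_d2):
        crit = Type2Criteria(-0.7, 0.4)
        t = mc.simulate_trials(
            ProcessModelParams.noise(0.8), unbiased_d2, crit, 20000, 3
        )
        resp_s2 = t.response.eq("S2")
        assert (resp_s2 == (t.x1 > 0.0)).all()
        assert (t.correct == (t.response == t.stimulus)).all()
        high = t.confidence.eq("high")
        expect_high = np.where(resp_s2, t.x2 > crit.c2_S2, t.x2 < crit.c2_S1)
        assert (high == expect_high).all()

    def test_stimulus_frequency_matches_prior(self):
        params = SDTParams(1.0, 0.0, 0.3)
        t = mc.simulate_trials(
            ProcessModelParams.standard(), params, Type2Criteria(-1, 1), 10**5, 5
        )
        p_emp = t.stimulus.eq("S2").mean()
        assert abs(p_emp - 0.3) < 4 * binomial_se(0.3, 10**5)

    def test_pure_noise_confidence_uninformative(self, unbiased_d2):
        # k = 1: x2 carries no information about x1, so high confidence is
        # equally frequent on correct and incorrect trials
        pm = ProcessModelParams.loss(1.0, 0.5)
        t = mc.simulate_trials(pm, unbiased_d2, Type2Criteria(-0.5, 0.5), 2 * 10**5, 11)
        assert abs(np.corrcoef(t.x1, t.x2)[0, 1]) < 0.01
        high = t.confidence.eq("high")
        hr2 = high[t.correct].mean()
        far2 = high[~t.correct].mean()
        se_diff = np.hypot(
            binomial_se(hr2, t.correct.sum()),
            binomial_se(far2, (~t.correct).sum()),
        )
        assert abs(hr2 - far2) < 4 * se_diff

    def test_average_confidence_example(self, unbiased_d2, unit_criteria):
        t = mc.simulate_trials(
            ProcessModelParams.standard(), unbiased_d2, unit_criteria, 10**6, 17
        )
        # the analytic value is 0.5228; the printed figure is 0.52
        assert t.confidence.eq("high").mean() == pytest.approx(0.52, abs=5e-3)


class TestExactJointRates:
    def test_reduction_to_standard(self, unbiased_d2, unit_criteria):
        exact = mc.joint_type2_rates_exact(
            ProcessModelParams.standard(), unbiased_d2, unit_criteria
        )
        closed = mc.type2_summary(unbiased_d2, unit_criteria)
        for field in (
            "HR2_S2", "FAR2_S2", "HR2_S1", "FAR2_S1", "HR2", "FAR2",
            "p_correct2", "p_high", "D2",
        ):
            assert getattr(exact, field) == pytest.approx(
                getattr(closed, field), abs=1e-9
            )

    def test_degenerate_rejected(self, unbiased_d2, unit_criteria):
        with pytest.raises(DegenerateModelError):
            mc.joint_type2_rates_exact(
                ProcessModelParams("loss", 0.0, 1.0), unbiased_d2, unit_criteria
            )

    def test_independence_limit(self, unbiased_d2):
        pm = ProcessModelParams.loss(1.0, 0.4)
        s = mc.joint_type2_rates_exact(pm, unbiased_d2, Type2Criteria(-0.5, 0.5))
        assert s.HR2_S2 == pytest.approx(s.FAR2_S2, abs=1e-9)
        assert s.HR2_S1 == pytest.approx(s.FAR2_S1, abs=1e-9)

    def test_orthant_masses_match_scipy_mvn(self, rng):
        # independent cross-check of the quadrature against the bivariate
        # normal distribution function
        for _ in range(6):
            k = rng.uniform(0.0, 0.9)
            s2 = rng.uniform(0.05, 1.2)
            mu = rng.uniform(-1.5, 1.5)
            a = rng.uniform(-1.0, 1.0)
            b = rng.uniform(-1.0, 2.0)
            cov = [[1.0, 1.0 - k], [1.0 - k, (1.0 - k) ** 2 + s2**2]]
            dist = multivariate_normal(mean=[mu, (1.0 - k) * mu], cov=cov)
            upper = (
                1.0
                - dist.cdf([a, np.inf])
                - dist.cdf([np.inf, b])
                + dist.cdf([a, b])
            )
            assert float(_mass_upper(mu, a, b, k, s2)) == pytest.approx(
                upper, abs=1e-8
            )
            assert float(_mass_lower(mu, a, b, k, s2)) == pytest.approx(
                dist.cdf([a, b]), abs=1e-8
            )

    def test_matches_monte_carlo(self, unbiased_d2):
        pm = ProcessModelParams.noise(0.8)
        crit = Type2Criteria(-0.84, 0.84)
        s = mc.joint_type2_rates_exact(pm, unbiased_d2, crit)
        n = 10**6
        t = mc.simulate_trials(pm, unbiased_d2, crit, n, 23)
        high = t.confidence.eq("high")
        n_corr = t.correct.sum()
        assert abs(high[t.correct].mean() - s.HR2) < 4 * binomial_se(s.HR2, n_corr)
        assert abs(high[~t.correct].mean() - s.FAR2) < 4 * binomial_se(
            s.FAR2, n - n_corr
        )
        assert abs(high.mean() - s.p_high) < 4 * binomial_se(s.p_high, n)


class TestModelOutcomeCurves:
    def test_standard_curves_match_oracle(self, unbiased_d2):
        rm = RewardMatrix2.from_quotient(3.0)
        for context, extras in [("reward", rm), ("hf", None), ("accuracy", None)]:
            oracle = mc.outcome_curve(context, unbiased_d2, extras, "S2", COARSE)
            model = mc.model_outcome_curve(
                context, ProcessModelParams.standard(), unbiased_d2, extras,
                "S2", COARSE,
            )
            assert np.allclose(oracle.values, model.values, atol=1e-9)

    def test_mc_engine_matches_exact(self, unbiased_d2):
        pm = ProcessModelParams.noise(0.8)
        rm = RewardMatrix2.from_quotient(3.0)
        grid = np.linspace(0.0, 2.0, 21)
        exact = mc.model_outcome_curve("reward", pm, unbiased_d2, rm, "S2", grid)
        mc_curve = mc.model_outcome_curve(
            "reward", pm, unbiased_d2, rm, "S2", grid, engine="mc",
            n=4 * 10**5, seed=31,
        )
        assert np.allclose(exact.values, mc_curve.values, atol=0.02)

    def test_mc_curves_reproducible(self, unbiased_d2):
        pm = ProcessModelParams.noise(0.5)
        grid = np.linspace(0.0, 2.0, 11)
        a = mc.model_outcome_curve(
            "hf", pm, unbiased_d2, None, "S2", grid, engine="mc", n=10**5, seed=7
        )
        b = mc.model_outcome_curve(
            "hf", pm, unbiased_d2, None, "S2", grid, engine="mc", n=10**5, seed=7
        )
        assert np.array_equal(a.values, b.values)

    def test_mc_requires_seed(self, unbiased_d2):
        with pytest.raises(ValueError):
            mc.model_outcome_curve(
                "hf", ProcessModelParams.noise(0.5), unbiased_d2, None, "S2",
                COARSE, engine="mc", n=1000,
            )


class TestOptimizeUnderModel:
    def test_reduction_recovers_closed_forms(self, unbiased_d2):
        rm = RewardMatrix2.from_quotient(3.0)
        opt, _ = mc.optimize_c2_under_model(
            "reward", ProcessModelParams.standard(), unbiased_d2, rm, grid=COARSE
        )
        assert opt.c2_S2_star == pytest.approx(math.log(3) / 2, abs=2e-3)
        assert opt.c2_S1_star == pytest.approx(-math.log(3) / 2, abs=2e-3)
        opt_hf, _ = mc.optimize_c2_under_model(
            "hf", ProcessModelParams.standard(), unbiased_d2, grid=COARSE
        )
        assert opt_hf.c2_S2_star == pytest.approx(0.8341, abs=2e-3)

    def test_type2_noise_makes_reward_optima_liberal(self, unbiased_d2):
        rm = RewardMatrix2.from_quotient(3.0)
        opt, _ = mc.optimize_c2_under_model(
            "reward", ProcessModelParams.noise(0.8), unbiased_d2, rm, grid=COARSE
        )
        assert opt.c2_S2_star < math.log(3) / 2 - 2e-3
        assert opt.c2_S1_star > -math.log(3) / 2 + 2e-3

    def test_type2_noise_makes_hf_optima_conservative(self, unbiased_d2):
        opt, _ = mc.optimize_c2_under_model(
            "hf", ProcessModelParams.noise(0.8), unbiased_d2, grid=COARSE
        )
        base = mc.c2_opt_hf(unbiased_d2)
        assert opt.c2_S2_star > base.c2_S2_star + 2e-3
        assert opt.c2_S1_star < base.c2_S1_star - 2e-3

    def test_signal_loss_makes_both_liberal(self, unbiased_d2):
        rm = RewardMatrix2.from_quotient(3.0)
        pm = ProcessModelParams.loss(0.5, 0.1)
        opt_r, _ = mc.optimize_c2_under_model(
            "reward", pm, unbiased_d2, rm, grid=COARSE
        )
        assert opt_r.c2_S2_star < math.log(3) / 2 - 2e-3
        opt_h, _ = mc.optimize_c2_under_model("hf", pm, unbiased_d2, grid=COARSE)
        assert opt_h.c2_S2_star < mc.c2_opt_hf(unbiased_d2).c2_S2_star - 2e-3


class TestCostOfIgnoring:
    def test_zero_under_standard_model(self, unbiased_d2):
        rm = RewardMatrix2.from_quotient(3.0)
        cost = mc.cost_of_ignoring_suboptimality(
            "reward", ProcessModelParams.standard(), unbiased_d2, rm, grid=COARSE
        )
        assert cost["overall"] == pytest.approx(0.0, abs=1e-9)

    def test_small_positive_for_reward_under_noise(self, unbiased_d2):
        rm = RewardMatrix2.from_quotient(3.0)
        cost = mc.cost_of_ignoring_suboptimality(
            "reward", ProcessModelParams.noise(0.8), unbiased_d2, rm, grid=COARSE
        )
        assert 0.0 < cost["overall"] < 0.05

    def test_signal_loss_hf_cost_exceeds_matched_noise_cost(self, unbiased_d2):
        # signal loss at k = 0.5 (sigma2 = 0.1) vs type 2 noise at the
        # sigma2 giving the same M_ratio: ignoring the loss model costs more
        pm_loss = ProcessModelParams.loss(0.5, 0.1)
        crit = Type2Criteria(-1.0, 1.0)
        target = mc.fit_metad(
            mc.expected_counts(pm_loss, unbiased_d2, crit, 1e5)
        ).m_ratio

        from scipy.optimize import brentq

        def mratio_gap(s2):
            counts = mc.expected_counts(
                ProcessModelParams.noise(s2), unbiased_d2, crit, 1e5
            )
            return mc.fit_metad(counts).m_ratio - target

        s2_matched = brentq(mratio_gap, 0.05, 1.0, xtol=1e-3)
        cost_loss = mc.cost_of_ignoring_suboptimality(
            "hf", pm_loss, unbiased_d2, grid=COARSE
        )
        cost_noise = mc.cost_of_ignoring_suboptimality(
            "hf", ProcessModelParams.noise(s2_matched), unbiased_d2, grid=COARSE
        )
        assert cost_loss["overall"] > 0.0
        assert cost_loss["overall"] > cost_noise["overall"]


class TestSweep:
    def test_sweep_parameter_table(self, unbiased_d2):
        grid = np.arange(0.0, 2.0 + 1e-9, 5e-3)
        table = mc.sweep_parameter(
            [0.0, 0.8], "sigma2", unbiased_d2, contexts=("reward",),
            q2=3.0, n_fit=1e5, grid=grid,
        )
        assert list(table["value"]) == [0.0, 0.8]
        assert table.loc[0, "m_ratio"] == pytest.approx(1.0, abs=1e-3)
        assert table.loc[1, "m_ratio"] < table.loc[0, "m_ratio"]
        # model-aware reward optimum more liberal under noise
        assert table.loc[1, "c2_S2_star_reward"] < table.loc[0, "c2_S2_star_reward"]

    def test_invalid_parameter_name(self, unbiased_d2):
        with pytest.raises(ValueError):
            mc.sweep_parameter([0.1], "tau", unbiased_d2)
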