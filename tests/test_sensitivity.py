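"""Scenario runs, tornado analysis, threshold-price search, and PSA."""

import numpy as np
import pandas as pd
import pytest

from adtcea.economics import evaluate
from adtcea.sensitivity import (ParamPerturbation, PsaDistribution,
                                ceac_curve, default_one_way_perturbations,
                                default_psa_distributions, one_way, psa,
                                scenario_run, threshold_price)


class TestOneWay:
    def test_unread_parameter_has_zero_range(self, fast_params):
        # the enzalutamide price is carried in the cost set but not read by
        # the default state-cost map
        base_icer = evaluate(fast_params).icer
        table = one_way(fast_params, [
            ParamPerturbation("drug_costs.enzalutamide_daily",
                              100.0, 300.0, "cost")])
        row = table.iloc[0]
        assert row["icer_low"] == pytest.approx(base_icer)
        assert row["icer_high"] == pytest.approx(base_icer)
        assert row["range"] == pytest.approx(0.0)

    def test_degarelix_price_direction(self, fast_params):
        base_icer = evaluate(fast_params).icer
        price = fast_params.drug_costs.degarelix_maintenance
        table = one_way(fast_params, [
            ParamPerturbation("drug_costs.degarelix_maintenance",
                              0.8 * price, 1.2 * price, "cost")])
        row = table.iloc[0]
        assert row["icer_low"] < base_icer < row["icer_high"]

    def test_duplicate_parameter_gives_identical_rows(self, fast_params):
        pert = ParamPerturbation("utilities.first_line", 0.81, 0.99, "utility")
        table = one_way(fast_params, [pert, pert])
        assert len(table) == 2
        pd.testing.assert_series_equal(table.iloc[0], table.iloc[1],
                                       check_names=False)

    def test_sorted_by_descending_range_stably(self, fast_params):
        perts = [
            ParamPerturbation("drug_costs.enzalutamide_daily", 100.0, 300.0,
                              "cost"),
            ParamPerturbation("drug_costs.degarelix_maintenance",
                              2560.0, 3840.0, "cost"),
            ParamPerturbation("utilities.first_line", 0.81, 0.99, "utility"),
        ]
        t1 = one_way(fast_params, perts)
        assert list(t1["range"]) == sorted(t1["range"], reverse=True)
        # input order does not change content, only the documented sort
        t2 = one_way(fast_params, list(reversed(perts)))
        pd.testing.assert_frame_equal(
            t1.sort_values("parameter").reset_index(drop=True),
            t2.sort_values("parameter").reset_index(drop=True))

    def test_unknown_path_raises(self, fast_params):
        with pytest.raises(KeyError):
            one_way(fast_params,
                    [ParamPerturbation("drug_costs.nope", 0.0, 1.0, "cost")])

    def test_default_battery_is_valid(self, fixture_params):
        perts = default_one_way_perturbations(fixture_params)
        for p in perts:
            assert p.low <= fixture_params.get(p.path) <= p.high


class TestScenarioRun:
    def test_no_edits_equals_base(self, fast_params):
        base = evaluate(fast_params)
        res = scenario_run(fast_params, {})
        assert res.icer == pytest.approx(base.icer, rel=1e-12)

    def test_base_is_never_mutated(self, fast_params):
        before = fast_params.sha256()
        scenario_run(fast_params, {"drug_costs.leuprorelin_per_cycle": 1.0})
        assert fast_params.sha256() == before

    def test_comparator_price_isolation(self, fast_params):
        base = evaluate(fast_params)
        res = scenario_run(fast_params, {
            "drug_costs.leuprorelin_per_cycle":
                2.0 * fast_params.drug_costs.leuprorelin_per_cycle})
        assert res.comparator.cost > base.comparator.cost
        assert res.intervention.cost == pytest.approx(base.intervention.cost,
                                                      rel=1e-12)

    def test_shorter_horizon_truncates_both_arms(self, fixture_params):
        base = evaluate(fixture_params.with_edits(
            {"settings.horizon_years": 10.0}))
        full = evaluate(fixture_params)
        assert base.intervention.cost < full.intervention.cost
        assert base.comparator.cost < full.comparator.cost
        assert base.intervention.qalys < full.intervention.qalys
        assert base.comparator.qalys < full.comparator.qalys


class TestThresholdPrice:
    def test_target_equal_to_base_icer_returns_base_price(self, fast_params):
        base = evaluate(fast_params)
        thr = threshold_price(fast_params,
                              "drug_costs.degarelix_maintenance",
                              target_icer=base.icer)
        assert thr.price == pytest.approx(
            fast_params.drug_costs.degarelix_maintenance, abs=0.5)
        assert thr.pct_change == pytest.approx(0.0, abs=0.1)

    def test_bisection_matches_algebraic_solution(self, fast_params):
        # delta-cost is affine in the maintenance price and delta-QALYs does
        # not depend on it, so the ICER is affine in price: solve exactly
        # from two evaluations and compare against the bisection answer
        path = "drug_costs.degarelix_maintenance"
        target = fast_params.willingness.gdp_per_capita
        p0, p1 = 1000.0, 3000.0
        i0 = scenario_run(fast_params, {path: p0}).icer
        i1 = scenario_run(fast_params, {path: p1}).icer
        slope = (i1 - i0) / (p1 - p0)
        algebraic = p0 + (target - i0) / slope
        thr = threshold_price(fast_params, path, target_icer=target,
                              icer_tol=1e-9, price_tol=0.005)
        assert thr.price == pytest.approx(algebraic, abs=0.01)

    def test_unbracketed_target_raises(self, fast_params):
        with pytest.raises(ValueError):
            threshold_price(fast_params, "drug_costs.degarelix_maintenance",
                            target_icer=-1e9, bracket=(3000.0, 3500.0))


class TestPsa:
    def test_degenerate_distributions_reproduce_base_exactly(self, fast_params):
        base = evaluate(fast_params)
        dists = [PsaDistribution(d.path, d.family, rse=0.0)
                 for d in default_psa_distributions(fast_params)]
        res = psa(fast_params, dists, n_iter=8, seed=1)
        assert np.all(res.samples["delta_cost"] == base.delta_cost)
        assert np.all(res.samples["delta_qaly"] == base.delta_qalys)
        # CEAC is then a step function jumping 0 -> 1 at the base ICER
        ceac = res.ceac
        below = ceac[ceac["wtp"] < base.icer]["probability"]
        above = ceac[ceac["wtp"] > base.icer]["probability"]
        assert np.all(below == 0.0)
        assert np.all(above == 1.0)

    def test_ceac_at_zero_wtp_counts_cost_savings(self, fast_params):
        dists = default_psa_distributions(fast_params)
        res = psa(fast_params, dists, n_iter=60, seed=2)
        frac_saving = float((res.samples["delta_cost"] < 0).mean())
        assert res.prob_cost_effective(0.0) == pytest.approx(frac_saving)
        assert res.ceac.iloc[0]["probability"] == pytest.approx(frac_saving)

    def test_ceac_limit_counts_qaly_gains(self, fast_params):
        dists = default_psa_distributions(fast_params)
        res = psa(fast_params, dists, n_iter=60, seed=3)
        frac_gain = float((res.samples["delta_qaly"] > 0).mean())
        assert res.prob_cost_effective(1e12) == pytest.approx(frac_gain)

    def test_quadrant_counts_sum_to_iterations(self, fast_params):
        res = psa(fast_params, default_psa_distributions(fast_params),
                  n_iter=40, seed=4)
        assert sum(res.quadrant_counts().values()) == 40

    def test_reproducible_and_seed_sensitive(self, fast_params):
        dists = default_psa_distributions(fast_params)
        a = psa(fast_params, dists, n_iter=10, seed=5)
        b = psa(fast_params, dists, n_iter=10, seed=5)
        c = psa(fast_params, dists, n_iter=10, seed=6)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert not a.samples.equals(c.samples)

    def test_adding_a_parameter_leaves_other_draws_unchanged(self, fast_params):
        dists = default_psa_distributions(fast_params)
        shorter = dists[:5]
        longer = dists[:5] + [PsaDistribution("utilities.palliative_care",
                                              "beta", 0.2)]
        a = psa(fast_params, shorter, n_iter=6, seed=7)
        b = psa(fast_params, longer, n_iter=6, seed=7)
        shared = [d.path for d in shorter]
        pd.testing.assert_frame_equal(a.draws[shared], b.draws[shared])

    def test_probabilities_lie_in_unit_interval(self, fast_params):
        res = psa(fast_params, default_psa_distributions(fast_params),
                  n_iter=30, seed=8)
        assert res.ceac["probability"].between(0.0, 1.0).all()

    def test_invalid_iteration_count(self, fast_params):
        with pytest.raises(ValueError):
            psa(fast_params, [], n_iter=0, seed=0)

    def test_draw_domains(self):
        rng = np.random.default_rng(0)
        g = PsaDistribution("x", "gamma", 0.2)
        assert all(g.draw(100.0, rng) >= 0 for _ in range(50))
        b = PsaDistribution("x", "beta", 0.2)
        assert all(0 <= b.draw(0.9, rng) <= 1 for _ in range(50))
        ln = PsaDistribution("x", "lognormal", 0.2)
        assert all(ln.draw(2.39, rng) > 0 for _ in range(50))
        with pytest.raises(ValueError):
            PsaDistribution("x", "beta", 0.2).draw(1.5, rng)
        with pytest.raises(ValueError):
            PsaDistribution("x", "cauchy", 0.2).draw(1.0, rng)

    def test_moment_matching_centres_draws(self):
        # sample means track the base value at 20% relative standard error
        rng = np.random.default_rng(9)
        for fam, base in (("gamma", 3200.0), ("beta", 0.9),
                          ("lognormal", 2.39)):
            d = PsaDistribution("x", fam, 0.2)
            draws = np.array([d.draw(base, rng) for _ in range(4000)])
            assert draws.mean() == pytest.approx(base, rel=0.02)
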