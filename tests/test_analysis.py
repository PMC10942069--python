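"""ICER, NMB, CEAC, EVPI, tornado, threshold search and scenario runs."""

import numpy as np
import pandas as pd
import pytest

from trastcea.markov import ArmResult
from trastcea.analysis import (
    ceac,
    evpi,
    icer,
    nmb,
    run_deterministic,
    run_psa_model,
    scenario_run,
    threshold_price,
    tornado,
)
from trastcea.params import ConfigError, ParameterSet, PSASpec


def _arm(cost, ly, qaly, name="x", cohort=5052):
    return ArmResult(arm=name, cost=cost, ly=ly, qaly=qaly, cost_undisc=cost,
                     ly_undisc=ly, qaly_undisc=qaly, cohort_size=cohort)


class TestICER:
    def test_simple_ratio(self):
        res = icer(_arm(100, 4, 2), _arm(0, 2, 0))
        assert res.icer_per_qaly_vnd == pytest.approx(50)
        assert res.icer_per_ly_vnd == pytest.approx(50)
        assert res.dominance == "trade-off"

    def test_dominant_has_no_ratio(self):
        res = icer(_arm(-10, 1, 0.5), _arm(0, 0, 0))
        assert res.dominance == "dominant"
        assert res.icer_per_qaly_vnd is None

    def test_dominated(self):
        res = icer(_arm(10, 0, -0.5), _arm(0, 0, 0))
        assert res.dominance == "dominated"

    def test_zero_effect_flagged_not_crashed(self):
        res = icer(_arm(10, 0, 0), _arm(0, 0, 0))
        assert res.dominance == "undefined"
        assert res.icer_per_qaly_vnd is None

    def test_published_increment_arithmetic(self):
        # division cross-check against the printed incremental pair
        res = icer(_arm(888_453_971, 3.0914, 1.7098), _arm(0, 0, 0))
        assert res.icer_per_ly_vnd == pytest.approx(287_390_000, rel=2e-4)

    def test_invariant_to_cohort_scaling(self):
        k = 5052
        a = icer(_arm(100, 4, 2), _arm(40, 2, 1))
        b = icer(_arm(100 * k, 4 * k, 2 * k), _arm(40 * k, 2 * k, 1 * k))
        assert a.icer_per_qaly_vnd == pytest.approx(b.icer_per_qaly_vnd)


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(2.0, 100.0, 0.0) == -100.0

    def test_break_even(self):
        assert nmb(2.0, 100.0, 50.0) == 0.0

    def test_sign_matches_icer_threshold_comparison(self):
        rng = np.random.default_rng(0)
        dq = rng.uniform(0.1, 3, 200)
        dc = rng.uniform(-1e9, 2e9, 200)
        lam = 519e6
        inmb = nmb(dq, dc, lam)
        np.testing.assert_array_equal(inmb > 0, (dc / dq) < lam)


class TestCEAC:
    def _draws(self, pairs):
        return pd.DataFrame({"d_cost": [c for c, _ in pairs],
                             "d_qaly": [q for _, q in pairs]})

    def test_costlier_arm_never_wins_at_zero_wtp(self, psa_draws):
        pts = ceac(psa_draws, [0.0])
        assert pts[0].p_trastuzumab == 0.0
        assert pts[0].p_chemo == 1.0

    def test_limit_all_positive_qaly(self, psa_draws):
        pts = ceac(psa_draws, [1e15])
        assert pts[0].p_trastuzumab == 1.0

    def test_two_draw_enumeration(self):
        draws = self._draws([(100.0, 1.0), (300.0, 1.0)])  # ICERs 100 and 300
        pts = ceac(draws, [200.0])
        assert pts[0].p_trastuzumab == 0.5

    def test_tie_goes_to_comparator(self):
        draws = self._draws([(200.0, 1.0)])
        assert ceac(draws, [200.0])[0].p_trastuzumab == 0.0

    def test_probabilities_sum_to_one_and_monotone(self, psa_draws):
        pts = ceac(psa_draws)
        p = np.array([x.p_trastuzumab for x in pts])
        q = np.array([x.p_chemo for x in pts])
        np.testing.assert_allclose(p + q, 1.0)
        assert np.all(np.diff(p) >= 0)  # all draws in the trade-off quadrant

    def test_empty_inputs_rejected(self, psa_draws):
        with pytest.raises(ValueError):
            ceac(psa_draws.iloc[:0])
        with pytest.raises(ValueError):
            ceac(psa_draws, [])


class TestEVPI:
    def _draws(self, pairs):
        return pd.DataFrame({"d_cost": [c for c, _ in pairs],
                             "d_qaly": [q for _, q in pairs]})

    def test_unanimous_choice_has_no_value(self):
        draws = self._draws([(100.0, 1.0)] * 4)
        assert evpi(draws, 50.0)["evpi_per_person_vnd"] == 0.0
        assert evpi(draws, 1000.0)["evpi_per_person_vnd"] == 0.0

    def test_two_draw_enumeration(self):
        # iNMB +10 and -10 with equal probability -> EVPI 5
        draws = self._draws([(90.0, 1.0), (110.0, 1.0)])
        out = evpi(draws, 100.0, population=5052)
        assert out["evpi_per_person_vnd"] == pytest.approx(5.0)
        assert out["evpi_population_vnd"] == pytest.approx(5.0 * 5052)

    def test_nonnegative_on_random_draws(self):
        rng = np.random.default_rng(3)
        draws = pd.DataFrame({"d_cost": rng.normal(0, 1e8, 500),
                              "d_qaly": rng.normal(0.5, 0.5, 500)})
        for lam in (0.0, 83e6, 249e6, 1e9):
            assert evpi(draws, lam)["evpi_per_person_vnd"] >= 0.0


class TestPSAModel:
    def test_degenerate_distributions_reproduce_deterministic(self, params, lifetable):
        p = ParameterSet(params.clinical, params.utilities, params.costs,
                         params.settings, PSASpec(default_rel_range=0.0))
        draws = run_psa_model(p, lifetable, 5, seed=9)
        _, _, det = run_deterministic(params, lifetable)
        np.testing.assert_allclose(draws["d_cost"], det.d_cost_vnd, rtol=1e-12)
        np.testing.assert_allclose(draws["d_qaly"], det.d_qaly, rtol=1e-12)

    def test_reproducible_under_seed(self, params, lifetable):
        a = run_psa_model(params, lifetable, 50, seed=4)
        b = run_psa_model(params, lifetable, 50, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_two_seeds_agree_within_monte_carlo_error(self, params, lifetable):
        a = run_psa_model(params, lifetable, 2_000, seed=1)
        b = run_psa_model(params, lifetable, 2_000, seed=2)
        for col in ("d_cost", "d_qaly"):
            se = np.hypot(a[col].std() / np.sqrt(len(a)), b[col].std() / np.sqrt(len(b)))
            assert abs(a[col].mean() - b[col].mean()) < 3 * se


class TestTornado:
    def test_sorted_by_span_with_zero_width_last(self, params, lifetable):
        ranges = {
            "hr_met": (0.39, 0.59),
            "u_dfs": (0.832 * 0.9, min(0.832 * 1.1, 1.0)),
            "c_met": (131_065_482.0, 131_065_482.0),  # zero width
        }
        entries = tornado(params, lifetable, ranges)
        assert [e.span for e in entries] == sorted([e.span for e in entries], reverse=True)
        assert entries[-1].name == "c_met" and entries[-1].span == 0.0

    def test_hr_ci_outranks_utility_band(self, params, lifetable):
        ranges = {"hr_met": (0.39, 0.59),
                  "u_dfs": (0.832 * 0.9, min(0.832 * 1.1, 1.0))}
        entries = tornado(params, lifetable, ranges)
        assert entries[0].name == "hr_met"

    def test_vial_price_raises_icer_monotonically(self, params, lifetable):
        entries = {e.name: e for e in tornado(params, lifetable,
                                              {"p_440": (0.9 * 45_596_775, 1.1 * 45_596_775)})}
        e = entries["p_440"]
        assert e.icer_low < e.icer_high

    def test_invalid_parameter_value_flagged_not_fatal(self, params, lifetable):
        entries = tornado(params, lifetable, {"p_dfs_after_lrr": (0.1, 0.95),
                                              "u_met": (0.7, 0.8)})
        flagged = {e.name: e for e in entries}
        assert not flagged["p_dfs_after_lrr"].valid
        assert flagged["u_met"].valid


class TestThresholdPrice:
    def test_fixed_point_when_icer_equals_lambda(self, params, lifetable):
        _, _, det = run_deterministic(params, lifetable)
        th = threshold_price(det.icer_per_qaly_vnd, params, lifetable)
        assert th.scale == pytest.approx(1.0)

    def test_bisection_matches_linear_closed_form(self, params, lifetable):
        # d_cost is exactly linear in the price scale and d_qaly constant,
        # so s* = (lambda * e - a) / b has a closed form
        lam = 249e6
        drug = params.costs.trast_drug
        _, _, at0 = run_deterministic(params.with_values({"trast_drug": 0.0}), lifetable)
        _, _, at1 = run_deterministic(params, lifetable)
        a = at0.d_cost_vnd
        b = at1.d_cost_vnd - at0.d_cost_vnd
        e = at1.d_qaly
        s_closed = (lam * e - a) / b
        th = threshold_price(lam, params, lifetable, rel_tol=1e-10)
        assert th.scale == pytest.approx(s_closed, rel=1e-6)

    def test_scale_decreases_with_lambda(self, params, lifetable):
        th_hi = threshold_price(249e6, params, lifetable)
        th_lo = threshold_price(83e6, params, lifetable)
        assert th_lo.scale < th_hi.scale

    def test_tolerance_contract(self, params, lifetable):
        for lam in (83e6, 249e6):
            th = threshold_price(lam, params, lifetable)
            assert abs(th.achieved_icer_vnd - lam) <= 1e-4 * lam

    def test_unreachable_target_flagged(self, params, lifetable):
        th = threshold_price(1e6, params, lifetable)
        assert not th.reachable
        assert th.scale is None
        assert th.achieved_icer_vnd > 1e6  # reported ICER floor at zero drug cost


class TestScenario:
    def test_empty_overrides_match_base_case(self, params, lifetable):
        rep = scenario_run({}, params, lifetable, run_psa=False, run_thresholds=False)
        _, _, det = run_deterministic(params, lifetable)
        assert rep.icer.icer_per_qaly_vnd == det.icer_per_qaly_vnd

    def test_unknown_override_rejected(self, params, lifetable):
        with pytest.raises(ConfigError, match="no_such"):
            scenario_run({"no_such": 1.0}, params, lifetable,
                         run_psa=False, run_thresholds=False)

    def test_cost_only_override_leaves_effects_bit_identical(self, params, lifetable):
        rep = scenario_run({"trast_drug": 570_022_437.0}, params, lifetable,
                           run_psa=False, run_thresholds=False)
        _, _, det = run_deterministic(params, lifetable)
        assert rep.icer.d_qaly == det.d_qaly
        assert rep.icer.d_ly == det.d_ly
        assert rep.icer.d_cost_vnd < det.d_cost_vnd

    def test_sharing_report_shape(self, params, lifetable):
        rep = scenario_run({"trast_drug": 570_022_437.0}, params, lifetable,
                           n_psa=500, seed=3)
        df = rep.to_frame()
        assert rep.therapy_cost_total_vnd == 603_473_703
        assert {"quantity", "vnd", "usd"} <= set(df.columns)
        # sharing lowers the ICER below the base case
        _, _, det = run_deterministic(params, lifetable)
        assert rep.icer.icer_per_qaly_vnd < det.icer_per_qaly_vnd
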