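from dataclasses import replace

import numpy as np
import pytest

from relapsehta import (Accrual, Arm, accumulate, discount_factor, evaluate,
                        net_monetary_benefit, population_nmb,
                        random_parameter_set, run_arm, with_price_and_effect)


def no_mortality(params):
    return replace(params, baseline_annual_mortality_male=0.0,
                   baseline_annual_mortality_female=0.0)


class TestDiscounting:
    @pytest.mark.parametrize("cycle,rate,expected", [
        (1, 0.035, 1.0),
        (5, 0.035, 1 / 1.035),
        (5, 0.0, 1.0),
        (9, 0.035, 1 / 1.035 ** 2),
    ])
    def test_quarterly_compounding(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            discount_factor(0, 0.035)
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestAccumulate:
    def test_perfect_health_year_is_one_qaly(self, aud_inputs):
        """Utilities 1, no discounting, no mortality: 4 cycles = 1 QALY."""
        space, p, _ = aud_inputs
        p = no_mortality(replace(
            p, utility_full_year={s: 1.0 for s in space.transient},
            discount_rate_outcomes=0.0))
        trace = run_arm("aud", p, Arm.SOC, 1)
        qalys, _, _ = accumulate(trace, p, Arm.SOC)
        assert qalys == pytest.approx(1.0, abs=1e-12)

    def test_soc_arm_never_charged_for_app(self, aud_inputs):
        space, p, _ = aud_inputs
        pricey = replace(p, app_cost_per_cycle=1e6)
        trace = run_arm("aud", pricey, Arm.SOC, 1)
        _, costs, _ = accumulate(trace, pricey, Arm.SOC)
        trace_base = run_arm("aud", p, Arm.SOC, 1)
        _, costs_base, _ = accumulate(trace_base, p, Arm.SOC)
        assert costs == costs_base

    def test_app_charge_covers_alive_mass_for_active_cycles(self, aud_inputs):
        """Charging the whole surviving cohort: cost gap equals the
        discounted alive-mass x price over the provisioned cycles."""
        space, p, _ = aud_inputs
        neutral = replace(p, app_effect_multiplier=1.0)
        free = replace(neutral, app_cost_per_cycle=0.0)
        trace = run_arm("aud", neutral, Arm.SOC_PLUS_APP, 2)
        _, costs_paid, _ = accumulate(trace, neutral, Arm.SOC_PLUS_APP)
        _, costs_free, _ = accumulate(trace, free, Arm.SOC_PLUS_APP)
        alive = 1.0 - trace.occupancy[:4, space.index("death")]
        df = (1.035) ** (-(np.arange(4)) / 4)
        assert costs_paid - costs_free == pytest.approx(25 * (alive * df).sum(),
                                                        rel=1e-12)


class TestEvaluate:
    @pytest.mark.parametrize("model", ["aud", "oud"])
    def test_zero_effect_zero_incrementals_exactly(self, model_inputs, model):
        _, p, _ = model_inputs[model]
        p = replace(p, app_effect_multiplier=1.0, app_cost_per_cycle=0.0)
        res = evaluate(model, p, 5)
        assert res.d_qalys == 0.0
        assert res.d_costs == 0.0
        assert res.d_relapses == 0.0
        assert res.nmb == 0.0
        assert res.savings_per_relapse_avoided is None

    @pytest.mark.parametrize("model", ["aud", "oud"])
    @pytest.mark.parametrize("horizon", [1, 5])
    def test_nmb_identity(self, model_inputs, model, horizon):
        _, p, _ = model_inputs[model]
        res = evaluate(model, p, horizon)
        assert res.nmb == pytest.approx(
            20000 * res.d_qalys - res.d_costs, abs=1e-9)
        assert res.app.costs >= 0 and res.soc.costs >= 0
        assert res.app.qalys <= horizon and res.soc.qalys <= horizon

    @pytest.mark.parametrize("seed", range(6))
    def test_nmb_affine_decreasing_in_price(self, seed):
        """NMB falls linearly with annual price; the slope magnitude is the
        discounted alive person-cycle mass charged (per GBP of annual price)."""
        model = "aud" if seed % 2 else "oud"
        params = random_parameter_set(model, seed)
        params = replace(params, app_active_cycles=4)
        prices = [0.0, 100.0, 400.0]
        nmbs = [evaluate(model, with_price_and_effect(params, pr, 0.15),
                         1).nmb for pr in prices]
        slope01 = (nmbs[1] - nmbs[0]) / 100.0
        slope12 = (nmbs[2] - nmbs[1]) / 300.0
        assert slope01 == pytest.approx(slope12, rel=1e-9)
        assert slope01 < 0
        trace = run_arm(model, with_price_and_effect(params, 100, 0.15),
                        Arm.SOC_PLUS_APP, 1)
        space = trace.space
        alive = 1.0 - trace.occupancy[:4, space.index("death")]
        df = (1 + params.discount_rate_costs) ** (-(np.arange(4)) / 4)
        assert -slope01 == pytest.approx((alive * df).sum() / 4.0, rel=1e-9)

    @pytest.mark.parametrize("model", ["aud", "oud"])
    @pytest.mark.parametrize("horizon", [1, 5, 20])
    def test_effect_improves_qalys_on_base_cases(self, model_inputs, model,
                                                 horizon):
        """With abstinence the best-rated state and a protective effect,
        the intervention arm never loses QALYs on the base cases."""
        _, p, _ = model_inputs[model]
        assert evaluate(model, p, horizon).d_qalys >= 0

    def test_population_scaling(self, aud_inputs):
        _, p, _ = aud_inputs
        res = evaluate("aud", p, 1)
        assert population_nmb(res, 0) == 0.0
        assert population_nmb(res, 1000) == pytest.approx(1000 * res.nmb)
        with pytest.raises(ValueError):
            population_nmb(res, -1)

    def test_nmb_helper_matches_printed_identity(self):
        assert net_monetary_benefit(0.001, 10.0) == pytest.approx(10.0)


class TestHandComputedOracle:
    """Independent 3-cycle arithmetic for the alcohol pathway (no mortality).

    Every number below is derived by hand from the pathway definition:
    relapse 0.13 (year-1 band), seeking 0.8, continuation 0.58, recovery 1,
    spontaneous recovery 0.002.  This validates the pathway translation, not
    just the engine algebra.
    """

    def hand_trace(self):
        a, b, c, e = 0.13, 0.8, 0.58, 0.002
        occ = [(1.0, 0.0, 0.0, 0.0)]  # (abst, relapse, t_start, t_cont)
        entries = []
        for _ in range(3):
            A, R, TS, TC = occ[-1]
            new_A = A * (1 - a) + R * e + TC * 1.0
            inflow = A * a + TS * (1 - c) + TC * 0.0
            new_R = inflow + R * (1 - b - e)
            new_TS = R * b
            new_TC = TS * c
            occ.append((new_A, new_R, new_TS, new_TC))
            entries.append(inflow)
        return occ, entries

    def test_occupancy_matches_engine(self, aud_inputs):
        _, p, _ = aud_inputs
        trace = run_arm("aud", no_mortality(p), Arm.SOC, 1)
        occ, entries = self.hand_trace()
        for cyc in range(4):
            assert trace.occupancy[cyc, :4] == pytest.approx(occ[cyc],
                                                             abs=1e-12)
        assert trace.relapse_entries[:3] == pytest.approx(entries, abs=1e-12)

    def test_economics_matches_hand_sums(self, aud_inputs):
        _, p, _ = aud_inputs
        p = no_mortality(p)
        trace = run_arm("aud", p, Arm.SOC, 1)
        qalys, costs, relapses = accumulate(trace, p, Arm.SOC)
        occ, _ = self.hand_trace()
        # one extra hand cycle for the 4-cycle horizon
        a, b, c, e = 0.13, 0.8, 0.58, 0.002
        A, R, TS, TC = occ[-1]
        occ.append((A * (1 - a) + R * e + TC,
                    A * a + TS * (1 - c) + R * (1 - b - e),
                    R * b, TS * c))
        df = [1.035 ** (-k / 4) for k in range(4)]
        hand_costs = sum(
            df[k] * (occ[k + 1][1] * 1223 + (occ[k + 1][2] + occ[k + 1][3]) * 2086)
            for k in range(4))
        hand_qalys = sum(
            df[k] * (occ[k][0] * 0.67 + occ[k][1] * 0.57
                     + (occ[k][2] + occ[k][3]) * 0.62) / 4
            for k in range(4))
        hand_relapses = sum(occ[k + 1][1] for k in range(4))
        assert costs == pytest.approx(hand_costs, abs=1e-9)
        assert qalys == pytest.approx(hand_qalys, abs=1e-12)
        assert relapses == pytest.approx(hand_relapses, abs=1e-12)


class TestAccrualToggles:
    def test_start_cost_accrual_is_available_and_differs(self, aud_inputs):
        _, p, _ = aud_inputs
        default = evaluate("aud", p, 1)
        toggled = evaluate("aud", p, 1, accrual=Accrual(costs="start"))
        assert toggled.soc.costs < default.soc.costs  # abstinent start cycle free
        assert toggled.soc.qalys == default.soc.qalys

    def test_invalid_accrual_point(self):
        with pytest.raises(ValueError):
            Accrual(costs="middle")
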