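"""Cohort engine: transition matrices, occupancy bookkeeping, discounting,
closed-form degenerate cases and agreement with the per-tooth oracle."""

from dataclasses import replace

import numpy as np
import pytest

from sealcua import (
    NO_SEAL,
    SEAL_ALL,
    ModelConfig,
    ToothState,
    build_transition_matrix,
    discount_factor,
    run_cohort,
)
from sealcua.parameters import EventRates, RateWithRange
from sealcua.synthetic import base_case_fixture, microsim_oracle, random_valid_fixture


def zero_rates(reseal=0.0, refill=0.0):
    return EventRates(
        reseal=RateWithRange(reseal, reseal, reseal),
        refill=RateWithRange(refill, refill, refill),
        extraction_caries=RateWithRange(0.0, 0.0, 0.0),
        extraction_other=RateWithRange(0.0, 0.0, 0.0),
    )


def with_rates(fx, rates):
    return replace(fx, params=replace(fx.params, rates=rates))


def with_flat_effectiveness(fx, value):
    sched = fx.params.effectiveness
    return replace(
        fx,
        params=replace(
            fx.params,
            effectiveness=sched.with_effectiveness([value] * len(sched.years)),
        ),
    )


class TestDiscounting:
    def test_no_time_elapsed(self):
        assert discount_factor(0.03, 0) == 1.0

    def test_two_years_at_three_percent(self):
        assert discount_factor(0.03, 2) == pytest.approx(1.03**-2)
        assert discount_factor(0.03, 2) == pytest.approx(0.94260, abs=5e-6)

    def test_zero_rate_never_discounts(self):
        assert discount_factor(0.0, 17.5) == 1.0


class TestTransitionMatrix:
    def test_rows_sum_to_one_across_random_parameterizations(self, base_fixture):
        count = 0
        for seed in range(112):
            fx = random_valid_fixture(seed)
            for strategy in (NO_SEAL, SEAL_ALL):
                for cycle in range(fx.config.n_cycles):
                    m = build_transition_matrix(
                        strategy, cycle, fx.params, fx.config
                    )
                    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
                    assert np.all((m >= 0) & (m <= 1))
                    count += 1
        assert count >= 600

    def test_zero_rates_and_flat_prevalence_give_identity(self, base_fixture):
        fx = with_rates(base_fixture, zero_rates())
        trend = replace(fx.params.untreated_trend, increment_per_cycle=0.0)
        fx = replace(fx, params=replace(fx.params, untreated_trend=trend))
        m = build_transition_matrix(NO_SEAL, 0, fx.params, fx.config)
        assert np.allclose(m, np.eye(5), atol=1e-15)

    def test_sound_to_filled_entry_is_conditional_incidence(self, base_fixture):
        fx = with_rates(base_fixture, zero_rates())
        m = build_transition_matrix(NO_SEAL, 1, fx.params, fx.config)
        expected = (0.456 - 0.353) / (1 - 0.353)
        assert m[ToothState.SOUND, ToothState.FILLED] == pytest.approx(
            expected, abs=1e-12
        )

    def test_extracted_states_are_absorbing(self, base_fixture):
        m = build_transition_matrix(SEAL_ALL, 0, base_fixture.params,
                                    base_fixture.config)
        assert m[ToothState.EXTRACTED_CARIES, ToothState.EXTRACTED_CARIES] == 1.0
        assert m[ToothState.EXTRACTED_OTHER, ToothState.EXTRACTED_OTHER] == 1.0


class TestCohortRun:
    def test_occupancy_conserved_every_cycle(self, base_fixture):
        for strategy in (NO_SEAL, SEAL_ALL):
            trace = run_cohort(strategy, base_fixture.params, base_fixture.costs,
                               base_fixture.config)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(trace.occupancy >= -1e-15)

    def test_ever_carious_matches_schedule_without_extractions(self, base_fixture):
        fx = with_rates(base_fixture, zero_rates(reseal=0.03, refill=0.01))
        for strategy, sched in (
            (NO_SEAL, [0.25, 0.353, 0.456, 0.559]),
            (SEAL_ALL, [0.0, 0.353 * 0.22, 0.456 * 0.40, 0.559 * 0.52]),
        ):
            trace = run_cohort(strategy, fx.params, fx.costs, fx.config)
            ever = trace.occupancy[:, ToothState.FILLED] + trace.occupancy[
                :, ToothState.EXTRACTED_CARIES
            ]
            assert ever == pytest.approx(sched, abs=1e-9)

    def test_untreated_qaty_closed_form(self, base_fixture):
        # 4 examinations - 0.19 x the cumulative prevalence at each one
        fx = with_rates(base_fixture, zero_rates())
        config = replace(fx.config, discount_effects=False)
        trace = run_cohort(NO_SEAL, fx.params, fx.costs, config)
        expected = 4 - 0.19 * (0.25 + 0.353 + 0.456 + 0.559)
        assert trace.total_qaty == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.69, abs=5e-3)

    def test_all_weights_one_conserves_tooth_years(self, base_fixture):
        fx = with_rates(base_fixture, zero_rates())
        weights = {s: 1.0 for s in ToothState}
        weights[ToothState.EXTRACTED_CARIES] = 1.0
        weights[ToothState.EXTRACTED_OTHER] = 1.0
        config = replace(fx.config, utility_weights=weights,
                         discount_effects=False)
        trace = run_cohort(NO_SEAL, fx.params, fx.costs, config)
        assert trace.total_qaty == pytest.approx(4.0, abs=1e-12)

    def test_discounted_never_exceeds_undiscounted(self, base_fixture):
        for strategy in (NO_SEAL, SEAL_ALL):
            trace = run_cohort(strategy, base_fixture.params, base_fixture.costs,
                               base_fixture.config)
            assert np.all(trace.cycle_cost_discounted <= trace.cycle_cost + 1e-15)
            assert np.all(trace.cycle_qaty_discounted <= trace.cycle_qaty + 1e-15)

    def test_useless_sealant_costs_exactly_the_sealing(self, base_fixture):
        # zero effectiveness, no resealing: identical epidemiology in both
        # arms, so the only cost difference is the baseline sealant outlay
        fx = with_flat_effectiveness(base_fixture, 0.0)
        fx = with_rates(fx, zero_rates(refill=0.01))
        ref = run_cohort(NO_SEAL, fx.params, fx.costs, fx.config)
        intv = run_cohort(SEAL_ALL, fx.params, fx.costs, fx.config)
        assert intv.total_qaty == pytest.approx(ref.total_qaty, abs=1e-12)
        assert intv.total_cost - ref.total_cost == pytest.approx(
            intv.cost_components["sealant"], abs=1e-12
        )

    def test_perfect_sealant_attains_maximum_qaty(self, base_fixture):
        fx = with_flat_effectiveness(base_fixture, 1.0)
        fx = with_rates(fx, zero_rates())
        config = replace(fx.config, discount_effects=False)
        trace = run_cohort(SEAL_ALL, fx.params, fx.costs, config)
        assert trace.total_qaty == pytest.approx(4.0, abs=1e-12)


class TestMicrosimAgreement:
    def test_base_case_within_three_standard_errors(self, base_fixture):
        for strategy in (NO_SEAL, SEAL_ALL):
            trace = run_cohort(strategy, base_fixture.params, base_fixture.costs,
                               base_fixture.config)
            mc, mq, se_c, se_q = microsim_oracle(
                base_fixture, strategy, n_teeth=100_000, seed=20_260
            )
            assert abs(trace.total_cost - mc) <= 3 * se_c
            assert abs(trace.total_qaty - mq) <= 3 * se_q

    @pytest.mark.parametrize("seed", range(20))
    def test_random_parameter_sets_within_sampling_error(self, seed):
        fx = random_valid_fixture(seed)
        for strategy in (NO_SEAL, SEAL_ALL):
            trace = run_cohort(strategy, fx.params, fx.costs, fx.config)
            mc, mq, se_c, se_q = microsim_oracle(
                fx, strategy, n_teeth=50_000, seed=1_000 + seed
            )
            assert abs(trace.total_cost - mc) <= 3 * se_c + 1e-9
            assert abs(trace.total_qaty - mq) <= 3 * se_q + 1e-9
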