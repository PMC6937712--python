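"""Prevalence trend, sealed-arm derivation, conditional incidence and the
PSA sampling distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sealcua.parameters import (
    DistributionSpec,
    EffectivenessSchedule,
    PrevalencePoint,
    PrevalenceTrend,
    build_distribution,
    fit_prevalence_trend,
    incidence_from_prevalence,
    prevalence_schedule,
    sealed_prevalence,
)


class TestPrevalenceTrend:
    def test_two_point_line_through_published_prevalences(self):
        trend = fit_prevalence_trend(
            [PrevalencePoint(6, 0.25), PrevalencePoint(12, 0.559)], cycle_length=2
        )
        assert trend.increment_per_cycle == pytest.approx(0.103, abs=1e-12)
        assert trend.baseline_prevalence == pytest.approx(0.25, abs=1e-12)

    def test_constant_prevalence_gives_zero_increment(self):
        trend = fit_prevalence_trend(
            [PrevalencePoint(6, 0.25), PrevalencePoint(12, 0.25)]
        )
        assert trend.increment_per_cycle == pytest.approx(0.0, abs=1e-15)

    def test_identical_ages_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fit_prevalence_trend([PrevalencePoint(6, 0.2), PrevalencePoint(6, 0.3)])

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PrevalencePoint(6, 1.2)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_normal_equations_oracle(self, seed):
        # independent closed-form least squares: solve the 2x2 normal equations
        rng = np.random.default_rng(seed)
        x = rng.uniform(5, 13, size=5)
        y = rng.uniform(0.05, 0.95, size=5)
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        trend = fit_prevalence_trend(
            [PrevalencePoint(a, p) for a, p in zip(x, y)], cycle_length=2
        )
        assert trend.increment_per_cycle == pytest.approx(2 * slope, abs=1e-12)

    def test_schedule_reproduces_published_values(self):
        trend = PrevalenceTrend(0.25, 0.103, baseline_age=6, cycle_length=2)
        sched = prevalence_schedule(trend, [6, 8, 10, 12])
        assert sched == pytest.approx([0.25, 0.353, 0.456, 0.559], abs=1e-12)

    def test_schedule_baseline_only(self):
        trend = PrevalenceTrend(0.25, 0.103)
        assert prevalence_schedule(trend, [6]) == pytest.approx([0.25])

    def test_schedule_clips_at_one(self):
        trend = PrevalenceTrend(0.95, 0.103)
        assert prevalence_schedule(trend, [6, 8]) == pytest.approx([0.95, 1.0])


class TestSealedPrevalence:
    @pytest.mark.parametrize(
        "untreated, eff, expected_pct",
        [(0.559, 0.48, 29), (0.353, 0.78, 8), (0.456, 0.60, 18)],
    )
    def test_published_sealed_arm_values(self, untreated, eff, expected_pct):
        value = sealed_prevalence(untreated, eff)
        assert round(100 * value) == expected_pct

    def test_perfect_effectiveness_prevents_everything(self):
        assert sealed_prevalence(0.7, 1.0) == 0.0

    @given(
        p=st.floats(0, 1), e1=st.floats(0, 1), e2=st.floats(0, 1)
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_effectiveness_and_bounded(self, p, e1, e2):
        lo, hi = sorted([e1, e2])
        assert sealed_prevalence(p, hi) <= sealed_prevalence(p, lo) <= p


class TestConditionalIncidence:
    def test_reproduces_next_prevalence(self):
        i = incidence_from_prevalence(0.353, 0.456)
        assert i == pytest.approx(0.1592, abs=5e-5)
        assert 0.353 + i * (1 - 0.353) == pytest.approx(0.456, abs=1e-15)

    def test_no_new_cases(self):
        assert incidence_from_prevalence(0.2, 0.2) == 0.0

    def test_conditional_equals_marginal_at_zero_prevalence(self):
        assert incidence_from_prevalence(0.0, 0.37) == pytest.approx(0.37)

    def test_saturated_prevalence_returns_zero(self):
        assert incidence_from_prevalence(1.0, 1.0) == 0.0

    def test_decreasing_prevalence_rejected(self):
        with pytest.raises(ValueError, match="decrease"):
            incidence_from_prevalence(0.5, 0.4)

    @given(
        st.lists(st.floats(0, 0.999), min_size=2, max_size=8)
    )
    @settings(derandomize=True, max_examples=100)
    def test_roundtrip_with_cumulative_schedule(self, values):
        # any non-decreasing cumulative schedule is recovered exactly from
        # its conditional incidences
        sched = np.sort(np.asarray(values))
        p = sched[0]
        for p_now, p_next in zip(sched, sched[1:]):
            p = p + incidence_from_prevalence(p_now, p_next) * (1 - p)
            assert p == pytest.approx(p_next, abs=1e-12)


class TestDistributions:
    def test_normal_sampler_mean_and_coverage(self):
        spec = DistributionSpec("normal", mean=0.353, half_width=0.02)
        draws = build_distribution(spec)(np.random.default_rng(0), size=100_000)
        assert draws.mean() == pytest.approx(0.353, abs=2e-4)
        inside = np.mean((draws >= 0.333) & (draws <= 0.373))
        assert inside >= 0.945

    def test_beta_sampler_support_mean_and_coverage(self):
        spec = DistributionSpec("beta", mean=0.03, low=0.0, high=0.13)
        draws = build_distribution(spec)(np.random.default_rng(1), size=100_000)
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() == pytest.approx(0.03, abs=2e-3)
        assert np.mean(draws <= 0.13) >= 0.95

    def test_degenerate_specs_are_point_masses(self):
        rng = np.random.default_rng(2)
        normal = DistributionSpec("normal", mean=0.4, half_width=0.0)
        beta = DistributionSpec("beta", mean=0.01)
        assert np.all(build_distribution(normal)(rng, size=100) == 0.4)
        assert np.all(build_distribution(beta)(rng, size=100) == 0.01)

    def test_beta_mean_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("beta", mean=1.5)

    def test_table_sampler_preserves_monotone_decay(self):
        sched = EffectivenessSchedule(
            years=(0.0, 2.0, 4.0, 6.0),
            effectiveness=(1.0, 0.78, 0.60, 0.48),
            ci_low=(1.0, 0.66, 0.49, 0.37),
            ci_high=(1.0, 0.85, 0.69, 0.57),
        )
        spec = DistributionSpec("table", schedule=sched)
        draws = build_distribution(spec)(np.random.default_rng(3), size=2_000)
        assert draws.shape == (2_000, 4)
        assert np.all(np.diff(draws, axis=1) <= 1e-12)
        assert np.all(draws[:, 0] == 1.0)
        assert draws[:, 1].mean() == pytest.approx(0.78, abs=5e-3)

    def test_effectiveness_must_decay(self):
        with pytest.raises(ValueError, match="non-increasing"):
            EffectivenessSchedule(
                years=(2.0, 4.0),
                effectiveness=(0.5, 0.7),
                ci_low=(0.4, 0.6),
                ci_high=(0.6, 0.8),
            )
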