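"""Parameter fixtures and an independent microsimulation oracle.

``base_case_fixture`` encodes the published base case: the prevalence trend,
sealant-effectiveness schedule, expert-survey event rates, micro-costed
procedure costs, and the sampling distributions for the probabilistic
sensitivity analysis.  ``random_valid_fixture`` draws randomized but
internally consistent parameter sets for property testing.

``microsim_oracle`` is a per-tooth event-sampling simulator used as an
independent cross-check of the cohort engine: it samples each molar's state
path tooth by tooth with the same per-cycle probabilities and prices, and
returns Monte-Carlo means with standard errors.  It deliberately shares no
cohort-propagation code with the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .costing import CostItem, CostSet, CostValue, CurrencyContext, procedure_total
from .engine import ModelConfig, StrategySpec, discount_factor
from .parameters import (
    DistributionSpec,
    EffectivenessSchedule,
    EpidemiologyParams,
    EventRates,
    PrevalenceTrend,
    RateWithRange,
)

__all__ = [
    "FixtureSet",
    "base_case_fixture",
    "random_valid_fixture",
    "microsim_oracle",
    "base_case_procedures",
]


@dataclass(frozen=True)
class FixtureSet:
    """A complete, self-consistent model parameterization."""

    label: str
    params: EpidemiologyParams
    costs: CostSet
    config: ModelConfig
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)
    known_truth: dict[str, float] = field(default_factory=dict)


def base_case_procedures() -> dict[str, "object"]:
    """Itemised Table-of-costs procedures (USD per molar intervened).

    The oral-exam total excludes its supplies line: the published total
    (4.603 = dentist + assistant + equipment) and the per-molar figure
    derived from it (4.603 / 24 = 0.192) are treated as authoritative.
    """
    sealant = procedure_total(
        [
            CostItem("dentist", 3.546, 3.039, 4.142, minutes=15, per_minute_rate=0.236),
            CostItem("assistant", 0.991, 0.846, 1.269, minutes=15, per_minute_rate=0.066),
            CostItem("supplies", 0.473, 0.433, 0.532),
            CostItem("clinical_site_preparation", 0.33, 0.305, 0.374, minutes=5,
                     per_minute_rate=0.066),
            CostItem("equipment_and_instruments", 0.066, 0.059, 0.079, minutes=15,
                     per_minute_rate=0.004),
        ],
        procedure="sealant",
    )
    filling = procedure_total(
        [
            CostItem("dentist", 7.092, 6.089, 8.274, minutes=30, per_minute_rate=0.236),
            CostItem("assistant", 1.982, 1.691, 2.539, minutes=30, per_minute_rate=0.066),
            CostItem("supplies", 1.593, 1.436, 1.752),
            CostItem("clinical_site_preparation", 0.33, 0.305, 0.374, minutes=5,
                     per_minute_rate=0.066),
            CostItem("equipment_and_instruments", 0.132, 0.117, 0.147, minutes=30,
                     per_minute_rate=0.004),
        ],
        procedure="filling",
    )
    extraction = procedure_total(
        [
            CostItem("dentist", 2.364, 2.364, 2.754, minutes=10, per_minute_rate=0.236),
            CostItem("assistant", 0.661, 0.561, 0.846, minutes=10, per_minute_rate=0.066),
            CostItem("supplies", 0.59, 0.532, 0.639),
            CostItem("clinical_site_preparation", 0.33, 0.305, 0.374, minutes=5,
                     per_minute_rate=0.066),
            CostItem("equipment_and_instruments", 0.044, 0.04, 0.048, minutes=10,
                     per_minute_rate=0.004),
        ],
        procedure="extraction",
    )
    oral_exam = procedure_total(
        [
            CostItem("dentist", 3.546, 3.039, 4.142, minutes=15, per_minute_rate=0.236),
            CostItem("assistant", 0.991, 0.846, 1.269, minutes=15, per_minute_rate=0.066),
            CostItem("equipment_and_instruments", 0.066, 0.059, 0.079, minutes=15,
                     per_minute_rate=0.004),
        ],
        procedure="oral_exam",
    )
    return {
        "sealant": sealant,
        "filling": filling,
        "extraction": extraction,
        "oral_exam": oral_exam,
    }


def _base_effectiveness() -> EffectivenessSchedule:
    # 0-year entry: a sealant placed on a sound molar leaves it caries-free.
    return EffectivenessSchedule(
        years=(0.0, 2.0, 4.0, 6.0),
        effectiveness=(1.0, 0.78, 0.60, 0.48),
        ci_low=(1.0, 0.66, 0.49, 0.37),
        ci_high=(1.0, 0.85, 0.69, 0.57),
    )


def base_case_fixture() -> FixtureSet:
    """The published base case: every printed parameter, range and
    distribution family."""
    trend = PrevalenceTrend(
        baseline_prevalence=0.25,
        increment_per_cycle=0.103,
        baseline_age=6.0,
        cycle_length=2.0,
    )
    effectiveness = _base_effectiveness()
    rates = EventRates(
        reseal=RateWithRange(0.03, 0.0, 0.13),
        refill=RateWithRange(0.01, 0.0, 0.14),
        extraction_caries=RateWithRange.pct20(0.001),
        extraction_other=RateWithRange.pct20(0.0001),
    )
    params = EpidemiologyParams(
        untreated_trend=trend, effectiveness=effectiveness, rates=rates
    )

    procs = base_case_procedures()
    exam_per_molar = procs["oral_exam"].total / 24.0
    costs = CostSet(
        sealant=CostValue.from_procedure(procs["sealant"]),
        filling=CostValue.from_procedure(procs["filling"]),
        extraction=CostValue.from_procedure(procs["extraction"]),
        molar_exam=CostValue(
            exam_per_molar,
            procs["oral_exam"].total_low / 24.0,
            procs["oral_exam"].total_high / 24.0,
        ),
        currency=CurrencyContext(clp_per_usd=681.09, reference_date="2019-05-07"),
    )
    config = ModelConfig()  # 3 x 2-year cycles, 3%/year, WTP 29.36 USD/QATY

    distributions = {
        "prevalence_increment": DistributionSpec(
            "normal", mean=0.103, half_width=0.02, support=(0.0, 1.0)
        ),
        "effectiveness": DistributionSpec(
            "table", schedule=effectiveness
        ),
        "reseal_rate": DistributionSpec("beta", mean=0.03, low=0.0, high=0.13),
        "refill_rate": DistributionSpec("beta", mean=0.01, low=0.0, high=0.14),
        "extraction_caries_rate": DistributionSpec(
            "beta", mean=0.001, low=0.0008, high=0.0012
        ),
        "extraction_other_rate": DistributionSpec(
            "beta", mean=0.0001, low=0.00008, high=0.00012
        ),
    }
    return FixtureSet(
        label="base_case",
        params=params,
        costs=costs,
        config=config,
        distributions=distributions,
    )


def random_valid_fixture(seed: int, zero_effectiveness: bool = False) -> FixtureSet:
    """A randomized, internally consistent parameter set.

    Prevalence schedules stay within [0, 1] over the horizon, effectiveness
    decays monotonically, all rates are valid probabilities and all costs are
    positive.  The same seed always yields the same fixture.  With
    ``zero_effectiveness`` the sealant does nothing, for which the
    incremental utility is exactly zero (recorded in ``known_truth``).
    """
    rng = np.random.default_rng(seed)
    baseline = float(rng.uniform(0.0, 0.6))
    n_cycles = 3
    increment = float(rng.uniform(0.0, (1.0 - baseline) / n_cycles))
    trend = PrevalenceTrend(baseline, increment, baseline_age=6.0, cycle_length=2.0)

    if zero_effectiveness:
        eff = np.zeros(4)
    else:
        top = rng.uniform(0.4, 0.95)
        decay = rng.uniform(0.0, 0.15, size=3)
        eff = np.concatenate([[1.0], top - np.cumsum(np.concatenate([[0], decay[:2]]))])
        eff = np.clip(eff, 0.0, 1.0)
        eff = np.minimum.accumulate(eff)
    hw = rng.uniform(0.01, 0.1, size=4)
    schedule = EffectivenessSchedule(
        years=(0.0, 2.0, 4.0, 6.0),
        effectiveness=tuple(float(e) for e in eff),
        ci_low=tuple(float(max(e - w, 0.0)) for e, w in zip(eff, hw)),
        ci_high=tuple(float(min(e + w, 1.0)) for e, w in zip(eff, hw)),
    )

    def _rate(hi: float) -> RateWithRange:
        b = float(rng.uniform(0.0, hi))
        return RateWithRange(b, 0.0, min(2 * hi, 1.0))

    rates = EventRates(
        reseal=_rate(0.15),
        refill=_rate(0.15),
        extraction_caries=_rate(0.01),
        extraction_other=_rate(0.001),
    )
    params = EpidemiologyParams(
        untreated_trend=trend, effectiveness=schedule, rates=rates
    )

    def _cost() -> CostValue:
        b = float(rng.uniform(0.5, 20.0))
        return CostValue(b, 0.8 * b, 1.25 * b)

    costs = CostSet(
        sealant=_cost(), filling=_cost(), extraction=_cost(),
        molar_exam=CostValue(*(lambda b: (b, 0.8 * b, 1.25 * b))(
            float(rng.uniform(0.05, 1.0)))),
    )
    config = ModelConfig(discount_rate=float(rng.uniform(0.0, 0.05)))
    truth = {"delta_qaty": 0.0} if zero_effectiveness else {}
    return FixtureSet(
        label=f"random_{seed}" + ("_zero_eff" if zero_effectiveness else ""),
        params=params,
        costs=costs,
        config=config,
        known_truth=truth,
    )


def microsim_oracle(
    fixture: FixtureSet,
    strategy: StrategySpec,
    n_teeth: int = 100_000,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """Per-tooth Monte-Carlo simulation of one strategy arm.

    Returns ``(mean_cost, mean_qaty, se_cost, se_qaty)`` per molar, applying
    the same event structure as the cohort engine by sampling each tooth's
    path: baseline sealing/filling, per-cycle caries onset among sound,
    sealed and filled molars, extraction risks, resealing, scheduled
    refilling and the per-examination molar exam.
    """
    if n_teeth < 1:
        raise ValueError("need at least one tooth")
    rng = np.random.default_rng(seed)
    params, costs, config = fixture.params, fixture.costs, fixture.config
    ages = config.evaluation_ages
    if strategy.seals_at_baseline:
        sched = params.sealed_schedule(ages, sealing_age=ages[0])
    else:
        sched = params.untreated_schedule(ages)
    weights = config.weight_vector()
    e_car = params.rates.extraction_caries.base
    e_oth = params.rates.extraction_other.base
    rho = params.rates.reseal.base if strategy.reseal_enabled else 0.0
    phi = params.rates.refill.base

    SOUND, SEALED, FILLED, XCAR, XOTH = 0, 1, 2, 3, 4
    state = np.full(n_teeth, SOUND, dtype=np.int8)
    cost = np.zeros(n_teeth)
    qaty = np.zeros(n_teeth)

    # baseline: prevalent caries filled, remainder sealed (seal-all) or sound
    carious = rng.uniform(size=n_teeth) < sched[0]
    state[carious] = FILLED
    cost += np.where(carious, costs.filling.base, 0.0)
    if strategy.seals_at_baseline:
        state[~carious] = SEALED
        cost += np.where(~carious, costs.sealant.base, 0.0)
    cost += costs.molar_exam.base  # all teeth present at baseline
    qaty += weights[state]

    for k in range(1, config.n_cycles + 1):
        p0, p1 = sched[k - 1], sched[k]
        inc = 0.0 if p0 >= 1.0 else (p1 - p0) / (1.0 - p0)
        df = discount_factor(config.discount_rate, ages[k] - config.baseline_age)
        cycle_cost = np.zeros(n_teeth)

        lost_other = rng.uniform(size=n_teeth) < e_oth
        u_caries = rng.uniform(size=n_teeth)
        u_ext = rng.uniform(size=n_teeth)

        at_risk = (state == SOUND) | (state == SEALED)
        new_caries = at_risk & ~lost_other & (u_caries < inc)
        filled_now = state == FILLED
        lost_caries = filled_now & ~lost_other & (u_ext < e_car)
        new_lesion = filled_now & ~lost_other & ~lost_caries & (u_caries < inc)

        alive = state < XCAR
        state[alive & lost_other] = XOTH
        state[new_caries] = FILLED
        state[lost_caries] = XCAR
        cycle_cost += np.where(new_caries, costs.filling.base, 0.0)
        cycle_cost += np.where(new_lesion, costs.filling.base, 0.0)
        cycle_cost += np.where(lost_caries, costs.extraction.base, 0.0)

        resealed = (state == SEALED) & (rng.uniform(size=n_teeth) < rho)
        refilled = (state == FILLED) & (rng.uniform(size=n_teeth) < phi)
        cycle_cost += np.where(resealed, costs.reseal.base, 0.0)
        cycle_cost += np.where(refilled, costs.refill.base, 0.0)
        cycle_cost += np.where(state < XCAR, costs.molar_exam.base, 0.0)

        cost += cycle_cost * df
        qaty += weights[state] * (df if config.discount_effects else 1.0)

    se = 1.0 / np.sqrt(n_teeth)
    return (
        float(cost.mean()),
        float(qaty.mean()),
        float(cost.std(ddof=1) * se) if n_teeth > 1 else 0.0,
        float(qaty.std(ddof=1) * se) if n_teeth > 1 else 0.0,
    )
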