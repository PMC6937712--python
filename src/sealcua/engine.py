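"""Markov cohort engine for the two sealant strategies.

A cohort of first permanent molars is propagated through five health states
(sound, sealed, filled, extracted-for-caries, extracted-other-causes) in
two-year cycles from age 6 to age 12.  Direct costs and quality-adjusted
tooth years (QATY) are accrued per molar and discounted at an annual rate.

Structural conventions
----------------------
* Transitions occur at cycle boundaries; there is no half-cycle correction.
  Treatment events during a cycle are costed at the examination age that
  closes the cycle; baseline events (sealant placement, prevalent-caries
  fillings, the first examination) are costed at age 6 undiscounted.
* Prevalent caries at baseline (25% of untreated 6-year-olds) is treated as
  an immediate sound→filled conversion with a filling cost; in the sealed
  arm the corresponding fraction comes from the arm's own schedule (zero in
  the base case, since a freshly sealed sound molar is caries-free).
* A filled molar stays at risk of new carious lesions at the arm's own
  per-cycle conditional incidence; each new lesion is treated with another
  restoration (a cost event; the molar remains in the filled state).
* Molars are lost to caries only from the filled state (1/1000 per cycle,
  with an extraction cost) and to other causes from any live state
  (1/10000 per cycle, no program-attributable cost).
* Outcomes are valued at the four examination ages (6, 8, 10, 12):
  QATY weight 1 for sound or sealed, 0.81 for filled, 0 for extracted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import CostSet, CurrencyContext
from .parameters import EpidemiologyParams, incidence_from_prevalence

__all__ = [
    "ToothState",
    "StrategySpec",
    "SEAL_ALL",
    "NO_SEAL",
    "ModelConfig",
    "CohortTrace",
    "discount_factor",
    "build_transition_matrix",
    "run_cohort",
]


class ToothState(enum.IntEnum):
    SOUND = 0
    SEALED = 1
    FILLED = 2
    EXTRACTED_CARIES = 3
    EXTRACTED_OTHER = 4


N_STATES = len(ToothState)
LIVE_STATES = (ToothState.SOUND, ToothState.SEALED, ToothState.FILLED)


@dataclass(frozen=True)
class StrategySpec:
    name: str
    seals_at_baseline: bool
    reseal_enabled: bool

    def __post_init__(self) -> None:
        if self.name == "seal_all" and not self.seals_at_baseline:
            raise ValueError("seal_all must seal at baseline")


SEAL_ALL = StrategySpec("seal_all", seals_at_baseline=True, reseal_enabled=True)
NO_SEAL = StrategySpec("no_seal", seals_at_baseline=False, reseal_enabled=False)


def _default_weights() -> dict[ToothState, float]:
    return {
        ToothState.SOUND: 1.0,
        ToothState.SEALED: 1.0,
        ToothState.FILLED: 0.81,
        ToothState.EXTRACTED_CARIES: 0.0,
        ToothState.EXTRACTED_OTHER: 0.0,
    }


@dataclass(frozen=True)
class ModelConfig:
    """Run-level settings: horizon, discounting, valuation."""

    baseline_age: float = 6.0
    cycle_length: float = 2.0
    n_cycles: int = 3
    discount_rate: float = 0.03
    utility_weights: dict[ToothState, float] = field(default_factory=_default_weights)
    wtp_threshold: float = 29.36  # USD per QATY (public-system filling tariff)
    discount_effects: bool = True
    currency: CurrencyContext = field(default_factory=CurrencyContext)

    def __post_init__(self) -> None:
        if self.cycle_length <= 0 or self.n_cycles < 1:
            raise ValueError("need positive cycle length and at least one cycle")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        for state, w in self.utility_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"utility weight for {state.name} outside [0, 1]")

    @property
    def horizon_years(self) -> float:
        return self.n_cycles * self.cycle_length

    @property
    def evaluation_ages(self) -> np.ndarray:
        return self.baseline_age + self.cycle_length * np.arange(self.n_cycles + 1)

    def weight_vector(self) -> np.ndarray:
        return np.array([self.utility_weights[s] for s in ToothState], dtype=float)


def discount_factor(rate: float, elapsed_years: float) -> float:
    """Present-value factor (1 + rate)^(-elapsed)."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return float((1.0 + rate) ** (-elapsed_years))


def _arm_schedule(
    strategy: StrategySpec, params: EpidemiologyParams, ages: np.ndarray
) -> np.ndarray:
    if strategy.seals_at_baseline:
        return params.sealed_schedule(ages, sealing_age=ages[0])
    return params.untreated_schedule(ages)


def build_transition_matrix(
    strategy: StrategySpec,
    cycle_index: int,
    params: EpidemiologyParams,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Per-cycle stochastic matrix for the given strategy and cycle.

    Rows/columns follow :class:`ToothState`.  Caries onset uses the
    conditional incidence derived from the arm's cumulative prevalence
    schedule, so cohort occupancy reproduces the printed prevalences.
    """
    config = config or ModelConfig()
    if not 0 <= cycle_index < config.n_cycles:
        raise ValueError(f"cycle_index {cycle_index} outside horizon")
    ages = config.evaluation_ages
    sched = _arm_schedule(strategy, params, ages)
    inc = incidence_from_prevalence(sched[cycle_index], sched[cycle_index + 1])
    e_car = params.rates.extraction_caries.base
    e_oth = params.rates.extraction_other.base
    for label, p in (("incidence", inc), ("extraction_caries", e_car),
                     ("extraction_other", e_oth)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"derived probability {label}={p} outside [0, 1]")

    m = np.zeros((N_STATES, N_STATES))
    s, sl, f, xc, xo = ToothState
    keep = 1.0 - e_oth
    m[s, xo] = e_oth
    m[s, f] = keep * inc
    m[s, s] = keep * (1.0 - inc)
    m[sl, xo] = e_oth
    m[sl, f] = keep * inc  # sealant failed and the lesion is filled
    m[sl, sl] = keep * (1.0 - inc)
    m[f, xo] = e_oth
    m[f, xc] = keep * e_car
    m[f, f] = keep * (1.0 - e_car)
    m[xc, xc] = 1.0
    m[xo, xo] = 1.0
    return m


@dataclass
class CohortTrace:
    """Per-cycle bookkeeping for one strategy arm (all quantities per molar)."""

    strategy: str
    ages: np.ndarray
    occupancy: np.ndarray  # (n_points, n_states)
    cycle_cost: np.ndarray  # undiscounted, accrued at each evaluation age
    cycle_cost_discounted: np.ndarray
    cycle_qaty: np.ndarray
    cycle_qaty_discounted: np.ndarray
    cost_components: dict[str, float]  # discounted totals by event type
    discount_effects: bool

    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost_discounted.sum())

    @property
    def total_qaty(self) -> float:
        if self.discount_effects:
            return float(self.cycle_qaty_discounted.sum())
        return float(self.cycle_qaty.sum())

    @property
    def total_qaty_undiscounted(self) -> float:
        return float(self.cycle_qaty.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy, columns=[s.name.lower() for s in ToothState]
        )
        df.insert(0, "age", self.ages)
        df["cycle_cost"] = self.cycle_cost
        df["cycle_cost_discounted"] = self.cycle_cost_discounted
        df["cycle_qaty"] = self.cycle_qaty
        df["cycle_qaty_discounted"] = self.cycle_qaty_discounted
        df["cum_cost_discounted"] = np.cumsum(self.cycle_cost_discounted)
        key = (
            "cycle_qaty_discounted" if self.discount_effects else "cycle_qaty"
        )
        df["cum_qaty"] = np.cumsum(df[key].to_numpy())
        return df


def run_cohort(
    strategy: StrategySpec,
    params: EpidemiologyParams,
    costs: CostSet,
    config: ModelConfig | None = None,
) -> CohortTrace:
    """Propagate the cohort and accrue discounted costs and QATYs."""
    config = config or ModelConfig()
    ages = config.evaluation_ages
    sched = _arm_schedule(strategy, params, ages)
    if len(sched) != config.n_cycles + 1:
        raise ValueError("schedule length inconsistent with horizon")
    weights = config.weight_vector()
    rate = config.discount_rate
    e_car = params.rates.extraction_caries.base
    e_oth = params.rates.extraction_other.base
    rho = params.rates.reseal.base if strategy.reseal_enabled else 0.0
    phi = params.rates.refill.base

    n_pts = config.n_cycles + 1
    occ = np.zeros((n_pts, N_STATES))
    cost = np.zeros(n_pts)
    cost_disc = np.zeros(n_pts)
    qaty = np.zeros(n_pts)
    qaty_disc = np.zeros(n_pts)
    comp: dict[str, float] = {
        k: 0.0
        for k in ("sealant", "filling", "new_lesion_refill", "scheduled_refill",
                  "reseal", "extraction", "exam")
    }
    s, sl, f, xc, xo = ToothState

    # --- baseline (age 6): prevalent caries filled; sound molars sealed in
    # the seal-all arm; first examination in both arms.
    v = np.zeros(N_STATES)
    p0 = sched[0]
    v[f] = p0
    c0 = p0 * costs.filling.base
    comp["filling"] += p0 * costs.filling.base
    if strategy.seals_at_baseline:
        v[sl] = 1.0 - p0
        c0 += v[sl] * costs.sealant.base
        comp["sealant"] += v[sl] * costs.sealant.base
    else:
        v[s] = 1.0 - p0
    c0 += costs.molar_exam.base
    comp["exam"] += costs.molar_exam.base
    occ[0] = v
    cost[0] = cost_disc[0] = c0
    qaty[0] = qaty_disc[0] = float(v @ weights)

    # --- cycles
    for k in range(1, n_pts):
        inc = incidence_from_prevalence(sched[k - 1], sched[k])
        m = build_transition_matrix(strategy, k - 1, params, config)
        prev = occ[k - 1]
        cur = prev @ m
        if not np.isclose(cur.sum(), 1.0, atol=1e-12):
            raise AssertionError("occupancy no longer sums to one")
        occ[k] = cur

        df_ = discount_factor(rate, ages[k] - config.baseline_age)
        keep = 1.0 - e_oth
        new_fills = (prev[s] + prev[sl]) * keep * inc
        new_lesions = prev[f] * keep * (1.0 - e_car) * inc
        extracted = prev[f] * keep * e_car
        resealed = rho * cur[sl]
        refilled = phi * cur[f]
        alive = cur[[s, sl, f]].sum()

        ck = (
            new_fills * costs.filling.base
            + new_lesions * costs.filling.base
            + extracted * costs.extraction.base
            + resealed * costs.reseal.base
            + refilled * costs.refill.base
            + alive * costs.molar_exam.base
        )
        comp["filling"] += new_fills * costs.filling.base * df_
        comp["new_lesion_refill"] += new_lesions * costs.filling.base * df_
        comp["extraction"] += extracted * costs.extraction.base * df_
        comp["reseal"] += resealed * costs.reseal.base * df_
        comp["scheduled_refill"] += refilled * costs.refill.base * df_
        comp["exam"] += alive * costs.molar_exam.base * df_
        cost[k] = ck
        cost_disc[k] = ck * df_
        uq = float(cur @ weights)
        qaty[k] = uq
        qaty_disc[k] = uq * df_

    return CohortTrace(
        strategy=strategy.name,
        ages=ages,
        occupancy=occ,
        cycle_cost=cost,
        cycle_cost_discounted=cost_disc,
        cycle_qaty=qaty,
        cycle_qaty_discounted=qaty_disc,
        cost_components=comp,
        discount_effects=config.discount_effects,
    )
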