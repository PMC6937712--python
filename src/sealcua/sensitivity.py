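"""Deterministic (tornado) and probabilistic (Monte Carlo) sensitivity
analysis around the base case.

The one-way analysis re-runs the full deterministic pipeline at each
parameter's low and high value holding everything else at base, and sorts
parameters by the induced ICUR span.  The probabilistic analysis jointly
samples the distributed epidemiological parameters, records one
cost-effectiveness-plane point per iteration, and classifies each iteration
against the willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .costing import CostValue
from .cua import DOMINANT, CUAResult, compare_strategies
from .parameters import EffectivenessSchedule, RateWithRange, build_distribution
from .synthetic import FixtureSet

__all__ = [
    "TornadoBar",
    "PSAOutcome",
    "one_way_dsa",
    "run_psa",
    "dsa_parameter_names",
    "tornado_frame",
]


# --- fixture editing -------------------------------------------------------

def _set_increment(fx: FixtureSet, v: float) -> FixtureSet:
    trend = replace(fx.params.untreated_trend, increment_per_cycle=float(v))
    return replace(fx, params=replace(fx.params, untreated_trend=trend))


def _set_effectiveness(fx: FixtureSet, sched: EffectivenessSchedule) -> FixtureSet:
    return replace(fx, params=replace(fx.params, effectiveness=sched))


def _set_rate(name: str):
    def setter(fx: FixtureSet, v: float) -> FixtureSet:
        old: RateWithRange = getattr(fx.params.rates, name)
        new = RateWithRange(float(v), min(old.low, float(v)), max(old.high, float(v)))
        return replace(fx, params=replace(fx.params, rates=replace(fx.params.rates, **{name: new})))
    return setter


def _set_cost(name: str):
    def setter(fx: FixtureSet, v: float) -> FixtureSet:
        old: CostValue = getattr(fx.costs, name)
        new = CostValue(float(v), min(old.low, float(v)), max(old.high, float(v)))
        return replace(fx, costs=replace(fx.costs, **{name: new}))
    return setter


_RATE_PARAMS = {
    "reseal_rate": "reseal",
    "refill_rate": "refill",
    "extraction_caries_rate": "extraction_caries",
    "extraction_other_rate": "extraction_other",
}
_COST_PARAMS = {
    "sealant_cost": "sealant",
    "filling_cost": "filling",
    "extraction_cost": "extraction",
    "molar_exam_cost": "molar_exam",
}


def dsa_parameter_names(fixture: FixtureSet) -> list[str]:
    """Parameters the one-way analysis varies by default: the distributed
    epidemiological quantities, one scalar at a time (each effectiveness
    time point over its own confidence interval).  Unit costs can be varied
    over their printed ranges by passing e.g. ``"sealant_cost"`` explicitly.
    """
    eff_names = [
        f"effectiveness_{int(y)}y"
        for y in fixture.params.effectiveness.years
        if y > 0
    ]
    return ["prevalence_increment"] + eff_names + list(_RATE_PARAMS)


def _set_effectiveness_point(years: float):
    def setter(fx: FixtureSet, v: float) -> FixtureSet:
        sched = fx.params.effectiveness
        idx = sched.years.index(years)
        values = list(sched.effectiveness)
        values[idx] = float(v)
        return _set_effectiveness(fx, sched.with_effectiveness(values))
    return setter


def _dsa_entry(fixture: FixtureSet, name: str):
    """(low value, high value, setter) for a named parameter."""
    if name == "prevalence_increment":
        inc = fixture.params.untreated_trend.increment_per_cycle
        spec = fixture.distributions.get("prevalence_increment")
        hw = spec.half_width if spec is not None else 0.2 * inc
        return max(inc - hw, 0.0), min(inc + hw, 1.0), _set_increment
    if name == "effectiveness":
        sched = fixture.params.effectiveness
        low = sched.with_effectiveness(sched.ci_low)
        high = sched.with_effectiveness(sched.ci_high)
        return low, high, _set_effectiveness
    if name.startswith("effectiveness_") and name.endswith("y"):
        years = float(name.removeprefix("effectiveness_").removesuffix("y"))
        sched = fixture.params.effectiveness
        idx = sched.years.index(years)
        return sched.ci_low[idx], sched.ci_high[idx], _set_effectiveness_point(years)
    if name in _RATE_PARAMS:
        rate: RateWithRange = getattr(fixture.params.rates, _RATE_PARAMS[name])
        return rate.low, rate.high, _set_rate(_RATE_PARAMS[name])
    if name in _COST_PARAMS:
        cost: CostValue = getattr(fixture.costs, _COST_PARAMS[name])
        return cost.low, cost.high, _set_cost(_COST_PARAMS[name])
    raise KeyError(f"unknown sensitivity parameter {name!r}")


# --- one-way deterministic analysis ---------------------------------------

@dataclass(frozen=True)
class TornadoBar:
    """ICUR excursion induced by one parameter's sensitivity range.

    ``icur_at_low``/``icur_at_high`` are the raw incremental cost / utility
    ratios (signed; negative when the intervention dominates) so a span is
    always defined; dominance is reported textually via the labels.
    """

    parameter: str
    low_value: object
    high_value: object
    icur_at_low: float
    icur_at_high: float
    dominant_at_low: bool
    dominant_at_high: bool

    @property
    def span(self) -> float:
        return abs(self.icur_at_high - self.icur_at_low)

    def label(self, at: str) -> str:
        dom = self.dominant_at_low if at == "low" else self.dominant_at_high
        val = self.icur_at_low if at == "low" else self.icur_at_high
        return "dominant" if dom else f"{val:.2f}"


def _raw_ratio(result: CUAResult) -> float:
    if result.incremental_utility == 0.0:
        return 0.0 if result.incremental_cost == 0.0 else np.inf
    return result.incremental_cost / result.incremental_utility


def one_way_dsa(
    fixture: FixtureSet, parameters: list[str] | None = None
) -> list[TornadoBar]:
    """Re-run the pipeline at each parameter's low/high; sort bars by span."""
    names = parameters if parameters is not None else dsa_parameter_names(fixture)
    bars = []
    for name in names:
        low, high, setter = _dsa_entry(fixture, name)
        if isinstance(low, float) and isinstance(high, float) and low > high:
            raise ValueError(f"{name}: low > high in sensitivity range")
        fx_lo = setter(fixture, low)
        fx_hi = setter(fixture, high)
        res_lo, _, _ = compare_strategies(fx_lo.params, fx_lo.costs, fx_lo.config)
        res_hi, _, _ = compare_strategies(fx_hi.params, fx_hi.costs, fx_hi.config)
        bars.append(
            TornadoBar(
                parameter=name,
                low_value=low,
                high_value=high,
                icur_at_low=_raw_ratio(res_lo),
                icur_at_high=_raw_ratio(res_hi),
                dominant_at_low=res_lo.dominance == DOMINANT,
                dominant_at_high=res_hi.dominance == DOMINANT,
            )
        )
    bars.sort(key=lambda b: b.span, reverse=True)
    return bars


def tornado_frame(bars: list[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [b.parameter for b in bars],
            "icur_at_low": [b.icur_at_low for b in bars],
            "icur_at_high": [b.icur_at_high for b in bars],
            "label_at_low": [b.label("low") for b in bars],
            "label_at_high": [b.label("high") for b in bars],
            "span": [b.span for b in bars],
        }
    )


# --- probabilistic sensitivity analysis ------------------------------------

@dataclass
class PSAOutcome:
    """Monte-Carlo simulation output over the distributed parameters."""

    iterations: int
    seed: int
    records: pd.DataFrame  # iteration, delta_cost, delta_qaty, icur, classification
    fraction_dominant: float
    fraction_not_cost_effective: float
    fraction_tradeoff: float

    @property
    def mean_delta_cost(self) -> float:
        return float(self.records["delta_cost"].mean())

    @property
    def mean_delta_qaty(self) -> float:
        return float(self.records["delta_qaty"].mean())

    @property
    def mean_icur_tradeoff(self) -> float:
        """Mean ICUR over trade-off iterations (ratio undefined when
        dominant, so those iterations are excluded)."""
        mask = self.records["classification"] == "tradeoff"
        return float(self.records.loc[mask, "icur"].mean())


def _sampled_fixture(fixture: FixtureSet, draw: dict[str, object]) -> FixtureSet:
    fx = fixture
    if "prevalence_increment" in draw:
        fx = _set_increment(fx, draw["prevalence_increment"])
    if "effectiveness" in draw:
        sched = fx.params.effectiveness.with_effectiveness(draw["effectiveness"])
        fx = _set_effectiveness(fx, sched)
    for name, attr in _RATE_PARAMS.items():
        if name in draw:
            fx = _set_rate(attr)(fx, draw[name])
    return fx


def run_psa(
    fixture: FixtureSet, n_iterations: int = 1000, seed: int = 0
) -> PSAOutcome:
    """Joint Monte-Carlo sampling of the distributed parameters.

    Each iteration draws one value per distribution, re-runs the
    deterministic pipeline, and records the cost-effectiveness-plane point
    and its classification against the willingness-to-pay threshold.
    Reproducible: the same seed yields identical records.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    samplers = {
        name: build_distribution(spec)
        for name, spec in fixture.distributions.items()
    }
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        draw = {name: sampler(rng) for name, sampler in samplers.items()}
        fx = _sampled_fixture(fixture, draw)
        result, _, _ = compare_strategies(fx.params, fx.costs, fx.config)
        if result.dominance == DOMINANT:
            cls = "dominant"
        elif result.cost_effective_at_wtp:
            cls = "tradeoff"
        else:
            cls = "not_cost_effective"
        rows.append(
            (
                it,
                result.incremental_cost,
                result.incremental_utility,
                result.icur if result.icur is not None else np.nan,
                cls,
            )
        )
    records = pd.DataFrame(
        rows, columns=["iteration", "delta_cost", "delta_qaty", "icur", "classification"]
    )
    n = float(n_iterations)
    counts = records["classification"].value_counts()
    return PSAOutcome(
        iterations=n_iterations,
        seed=seed,
        records=records,
        fraction_dominant=counts.get("dominant", 0) / n,
        fraction_not_cost_effective=counts.get("not_cost_effective", 0) / n,
        fraction_tradeoff=counts.get("tradeoff", 0) / n,
    )
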