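"""Incremental cost-utility analysis.

Given per-strategy discounted cost and QATY totals, compute incremental
quantities, the incremental cost-utility ratio (ICUR), a dominance label,
and the cost-effectiveness-plane coordinates, and judge cost-effectiveness
against the willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .costing import CostSet
from .engine import NO_SEAL, SEAL_ALL, CohortTrace, ModelConfig, run_cohort
from .parameters import EpidemiologyParams

__all__ = ["CUAResult", "icur", "ce_plane_point", "compare_strategies"]

DOMINANT = "intervention_dominant"
DOMINATED = "intervention_dominated"
TRADEOFF = "tradeoff"


@dataclass(frozen=True)
class CUAResult:
    reference_name: str
    intervention_name: str
    reference_cost: float
    reference_utility: float
    intervention_cost: float
    intervention_utility: float
    incremental_cost: float
    incremental_utility: float
    icur: float | None  # undefined when incremental utility is zero or dominant
    dominance: str
    cost_effective_at_wtp: bool
    wtp_threshold: float

    @property
    def ce_plane_point(self) -> tuple[float, float]:
        return (self.incremental_utility, self.incremental_cost)


def icur(
    reference: tuple[float, float],
    intervention: tuple[float, float],
    wtp: float = 29.36,
    reference_name: str = "no_seal",
    intervention_name: str = "seal_all",
) -> CUAResult:
    """Incremental cost-utility ratio with dominance classification.

    ``reference``/``intervention`` are (discounted cost, discounted utility)
    pairs.  The ratio is reported only for genuine trade-offs; a strategy
    that is cheaper and more effective is labelled dominant and no ratio is
    reported, following cost-effectiveness-plane convention.
    """
    (c_ref, u_ref), (c_int, u_int) = reference, intervention
    d_cost = c_int - c_ref
    d_util = u_int - u_ref

    if d_util > 0 and d_cost <= 0:
        dominance, ratio = DOMINANT, None
    elif d_util < 0 and d_cost >= 0:
        dominance, ratio = DOMINATED, None
    elif d_util == 0:
        # equal utilities: ratio undefined, decide on cost alone
        ratio = None
        if d_cost < 0:
            dominance = DOMINANT
        elif d_cost > 0:
            dominance = DOMINATED
        else:
            dominance = TRADEOFF
    else:
        dominance = TRADEOFF
        ratio = d_cost / d_util

    if dominance == DOMINANT:
        cost_effective = True
    elif dominance == DOMINATED:
        cost_effective = False
    elif ratio is None:
        cost_effective = d_cost <= 0
    elif d_util > 0:
        cost_effective = ratio <= wtp
    else:
        # less effective but cheaper: not acceptable at any positive WTP here
        cost_effective = False

    return CUAResult(
        reference_name=reference_name,
        intervention_name=intervention_name,
        reference_cost=c_ref,
        reference_utility=u_ref,
        intervention_cost=c_int,
        intervention_utility=u_int,
        incremental_cost=d_cost,
        incremental_utility=d_util,
        icur=ratio,
        dominance=dominance,
        cost_effective_at_wtp=cost_effective,
        wtp_threshold=wtp,
    )


def ce_plane_point(
    reference: tuple[float, float], intervention: tuple[float, float]
) -> tuple[float, float]:
    """Cost-effectiveness-plane coordinates (ΔQATY on x, Δcost on y)."""
    (c_ref, u_ref), (c_int, u_int) = reference, intervention
    return (u_int - u_ref, c_int - c_ref)


def compare_strategies(
    params: EpidemiologyParams,
    costs: CostSet,
    config: ModelConfig | None = None,
) -> tuple[CUAResult, CohortTrace, CohortTrace]:
    """Run both arms of the base-case model and compare them.

    Returns the CUA result plus the no-seal and seal-all cohort traces.
    """
    config = config or ModelConfig()
    ref = run_cohort(NO_SEAL, params, costs, config)
    intv = run_cohort(SEAL_ALL, params, costs, config)
    result = icur(
        (ref.total_cost, ref.total_qaty),
        (intv.total_cost, intv.total_qaty),
        wtp=config.wtp_threshold,
    )
    return result, ref, intv
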