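"""Micro-costing of dental procedures.

Each procedure's direct cost per molar is built bottom-up: staff minutes
times a per-minute wage, supplies, clinical-site preparation, and amortized
equipment.  Component costs carry a (low, high) range from the supplier
quotes, aggregated component-wise.  Values are carried at full precision in
USD and converted to Chilean pesos only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CostItem",
    "ProcedureCost",
    "CostValue",
    "CostSet",
    "CurrencyContext",
    "staff_cost",
    "amortized_equipment_rate",
    "procedure_total",
    "per_molar_exam_cost",
    "convert_currency",
]


def staff_cost(minutes: float, per_minute_rate: float) -> float:
    """Cost of staff time: minutes x per-minute wage, no rounding."""
    if minutes < 0 or per_minute_rate < 0:
        raise ValueError("minutes and per-minute rate must be non-negative")
    return minutes * per_minute_rate


def amortized_equipment_rate(
    equipment_capital: float,
    lifetime_years: float,
    usable_minutes_per_year: float,
) -> float:
    """Per-minute equipment cost under straight-line obsolescence."""
    if lifetime_years <= 0 or usable_minutes_per_year <= 0:
        raise ValueError("lifetime and usable minutes must be positive")
    if equipment_capital < 0:
        raise ValueError("equipment capital must be non-negative")
    return equipment_capital / (lifetime_years * usable_minutes_per_year)


@dataclass(frozen=True)
class CostItem:
    """One cost component of a procedure (USD per molar intervened)."""

    label: str
    base: float
    low: float
    high: float
    minutes: float | None = None
    per_minute_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.label}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.minutes is not None and self.minutes < 0:
            raise ValueError(f"{self.label}: minutes must be non-negative")


@dataclass(frozen=True)
class ProcedureCost:
    """A procedure's itemised direct cost with component-wise totals."""

    procedure: str
    items: tuple[CostItem, ...]

    @property
    def total(self) -> float:
        return sum(i.base for i in self.items)

    @property
    def total_low(self) -> float:
        return sum(i.low for i in self.items)

    @property
    def total_high(self) -> float:
        return sum(i.high for i in self.items)


def procedure_total(items: list[CostItem], procedure: str = "") -> ProcedureCost:
    """Aggregate cost components into a procedure total (base/low/high)."""
    if not items:
        raise ValueError("procedure needs at least one cost item")
    return ProcedureCost(procedure=procedure, items=tuple(items))


def per_molar_exam_cost(oral_exam_total: float, teeth: int = 24) -> float:
    """Oral-exam cost attributed to a single molar (exam cost / teeth present)."""
    if teeth <= 0:
        raise ValueError("teeth count must be positive")
    return oral_exam_total / teeth


@dataclass(frozen=True)
class CurrencyContext:
    """CLP/USD conversion at the Central Bank reference rate."""

    clp_per_usd: float = 681.09
    reference_date: str = "2019-05-07"

    def __post_init__(self) -> None:
        if self.clp_per_usd <= 0:
            raise ValueError("exchange rate must be positive")


def convert_currency(
    amount: float, ctx: CurrencyContext, direction: str = "usd_to_clp"
) -> float:
    """Convert between USD and CLP; rounding is the caller's concern."""
    if direction == "usd_to_clp":
        return amount * ctx.clp_per_usd
    if direction == "clp_to_usd":
        return amount / ctx.clp_per_usd
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class CostValue:
    """A scalar cost with its sensitivity range (USD)."""

    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"need low <= base <= high, got ({self.low}, {self.base}, {self.high})"
            )

    @classmethod
    def from_procedure(cls, proc: ProcedureCost) -> "CostValue":
        return cls(proc.total, proc.total_low, proc.total_high)


@dataclass(frozen=True)
class CostSet:
    """Per-procedure unit costs consumed by the cohort engine (USD/molar).

    Resealing is priced as a new sealant application and refilling as a new
    restoration: the program performs the same procedure again.
    """

    sealant: CostValue
    filling: CostValue
    extraction: CostValue
    molar_exam: CostValue
    currency: CurrencyContext = field(default_factory=CurrencyContext)

    @property
    def reseal(self) -> CostValue:
        return self.sealant

    @property
    def refill(self) -> CostValue:
        return self.filling
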