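"""Structured-text (YAML) configuration mirroring the model's input tables.

A configuration file has four sections — ``model``, ``epidemiology``,
``costs`` and ``distributions`` — holding every scientific input: horizon
and discounting, the prevalence trend, the sealant-effectiveness schedule,
per-cycle event rates, per-procedure direct costs with their sensitivity
ranges, and the sampling distributions for the probabilistic analysis.
Fixtures serialize to this format and read back bit-exactly.
"""

from __future__ import annotations

import pathlib

import yaml

from .costing import CostSet, CostValue, CurrencyContext
from .engine import ModelConfig, ToothState
from .parameters import (
    DistributionSpec,
    EffectivenessSchedule,
    EpidemiologyParams,
    EventRates,
    PrevalenceTrend,
    RateWithRange,
)
from .synthetic import FixtureSet

__all__ = ["fixture_to_dict", "fixture_from_dict", "load_fixture", "save_fixture",
           "ConfigError"]


class ConfigError(ValueError):
    """Configuration does not match the expected schema."""


def _require(mapping: dict, keys: list[str], where: str) -> None:
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise ConfigError(f"section '{where}' is missing keys: {missing}")


def fixture_to_dict(fx: FixtureSet) -> dict:
    params, costs, config = fx.params, fx.costs, fx.config
    eff = params.effectiveness
    dists = {}
    for name, spec in fx.distributions.items():
        d: dict = {"family": spec.family}
        if spec.family == "normal":
            d.update(mean=spec.mean, half_width=spec.half_width)
        elif spec.family == "beta":
            d.update(mean=spec.mean, low=spec.low, high=spec.high)
        # table family re-uses the epidemiology effectiveness schedule
        dists[name] = d
    return {
        "label": fx.label,
        "model": {
            "baseline_age": config.baseline_age,
            "cycle_length": config.cycle_length,
            "n_cycles": config.n_cycles,
            "discount_rate": config.discount_rate,
            "discount_effects": config.discount_effects,
            "wtp_threshold": config.wtp_threshold,
            "utility_weights": {
                s.name.lower(): config.utility_weights[s] for s in ToothState
            },
            "currency": {
                "clp_per_usd": config.currency.clp_per_usd,
                "reference_date": config.currency.reference_date,
            },
        },
        "epidemiology": {
            "prevalence_trend": {
                "baseline_prevalence": params.untreated_trend.baseline_prevalence,
                "increment_per_cycle": params.untreated_trend.increment_per_cycle,
                "baseline_age": params.untreated_trend.baseline_age,
                "cycle_length": params.untreated_trend.cycle_length,
            },
            "effectiveness": [
                {"years": y, "effectiveness": e, "ci_low": lo, "ci_high": hi}
                for y, e, lo, hi in zip(
                    eff.years, eff.effectiveness, eff.ci_low, eff.ci_high
                )
            ],
            "rates": {
                name: {"base": r.base, "low": r.low, "high": r.high}
                for name, r in (
                    ("reseal", params.rates.reseal),
                    ("refill", params.rates.refill),
                    ("extraction_caries", params.rates.extraction_caries),
                    ("extraction_other", params.rates.extraction_other),
                )
            },
        },
        "costs": {
            name: {"base": c.base, "low": c.low, "high": c.high}
            for name, c in (
                ("sealant", costs.sealant),
                ("filling", costs.filling),
                ("extraction", costs.extraction),
                ("molar_exam", costs.molar_exam),
            )
        },
        "distributions": dists,
    }


def fixture_from_dict(data: dict) -> FixtureSet:
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    _require(data, ["model", "epidemiology", "costs"], "root")

    m = data["model"]
    _require(
        m,
        ["baseline_age", "cycle_length", "n_cycles", "discount_rate",
         "wtp_threshold"],
        "model",
    )
    weights = m.get("utility_weights", {})
    try:
        uw = {
            s: float(weights.get(s.name.lower(), 1.0 if s.value < 2 else 0.0))
            for s in ToothState
        }
        cur = m.get("currency", {})
        config = ModelConfig(
            baseline_age=float(m["baseline_age"]),
            cycle_length=float(m["cycle_length"]),
            n_cycles=int(m["n_cycles"]),
            discount_rate=float(m["discount_rate"]),
            discount_effects=bool(m.get("discount_effects", True)),
            wtp_threshold=float(m["wtp_threshold"]),
            utility_weights=uw,
            currency=CurrencyContext(
                clp_per_usd=float(cur.get("clp_per_usd", 681.09)),
                reference_date=str(cur.get("reference_date", "2019-05-07")),
            ),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid 'model' section: {exc}") from exc

    e = data["epidemiology"]
    _require(e, ["prevalence_trend", "effectiveness", "rates"], "epidemiology")
    t = e["prevalence_trend"]
    _require(t, ["baseline_prevalence", "increment_per_cycle"], "prevalence_trend")
    try:
        trend = PrevalenceTrend(
            baseline_prevalence=float(t["baseline_prevalence"]),
            increment_per_cycle=float(t["increment_per_cycle"]),
            baseline_age=float(t.get("baseline_age", config.baseline_age)),
            cycle_length=float(t.get("cycle_length", config.cycle_length)),
        )
        rows = e["effectiveness"]
        eff = EffectivenessSchedule(
            years=tuple(float(r["years"]) for r in rows),
            effectiveness=tuple(float(r["effectiveness"]) for r in rows),
            ci_low=tuple(float(r["ci_low"]) for r in rows),
            ci_high=tuple(float(r["ci_high"]) for r in rows),
        )
        r = e["rates"]
        _require(r, ["reseal", "refill", "extraction_caries", "extraction_other"],
                 "rates")

        def _rate(name: str) -> RateWithRange:
            row = r[name]
            return RateWithRange(float(row["base"]), float(row["low"]),
                                 float(row["high"]))

        rates = EventRates(
            reseal=_rate("reseal"),
            refill=_rate("refill"),
            extraction_caries=_rate("extraction_caries"),
            extraction_other=_rate("extraction_other"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid 'epidemiology' section: {exc}") from exc
    params = EpidemiologyParams(untreated_trend=trend, effectiveness=eff, rates=rates)

    c = data["costs"]
    _require(c, ["sealant", "filling", "extraction", "molar_exam"], "costs")
    try:
        def _cost(name: str) -> CostValue:
            row = c[name]
            return CostValue(float(row["base"]), float(row["low"]),
                             float(row["high"]))

        costs = CostSet(
            sealant=_cost("sealant"),
            filling=_cost("filling"),
            extraction=_cost("extraction"),
            molar_exam=_cost("molar_exam"),
            currency=config.currency,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid 'costs' section: {exc}") from exc

    dists: dict[str, DistributionSpec] = {}
    for name, d in (data.get("distributions") or {}).items():
        try:
            family = d["family"]
            if family == "normal":
                dists[name] = DistributionSpec(
                    "normal", mean=float(d["mean"]),
                    half_width=float(d["half_width"]),
                )
            elif family == "beta":
                dists[name] = DistributionSpec(
                    "beta", mean=float(d["mean"]),
                    low=None if d.get("low") is None else float(d["low"]),
                    high=None if d.get("high") is None else float(d["high"]),
                )
            elif family == "table":
                dists[name] = DistributionSpec("table", schedule=eff)
            else:
                raise ConfigError(
                    f"distribution '{name}': unknown family {family!r}"
                )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"invalid distribution '{name}': {exc}") from exc

    return FixtureSet(
        label=str(data.get("label", "unnamed")),
        params=params,
        costs=costs,
        config=config,
        distributions=dists,
    )


def save_fixture(fx: FixtureSet, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    path.write_text(
        yaml.safe_dump(fixture_to_dict(fx), sort_keys=False), encoding="utf-8"
    )


def load_fixture(path: str | pathlib.Path) -> FixtureSet:
    path = pathlib.Path(path)
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return fixture_from_dict(data)
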