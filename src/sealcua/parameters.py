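"""Epidemiological inputs and their derivations.

Caries prevalence in first permanent molars (FPM) enters the model as a
cumulative probability ("ever carious") at ages 6, 8, 10 and 12.  This module
fits the linear prevalence trend for the untreated population, derives the
sealed-arm prevalence from sealant effectiveness, converts cumulative
prevalence into per-cycle conditional incidence among still-at-risk molars,
and builds the sampling distributions used by the probabilistic sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PrevalencePoint",
    "PrevalenceTrend",
    "EffectivenessSchedule",
    "RateWithRange",
    "EventRates",
    "EpidemiologyParams",
    "DistributionSpec",
    "fit_prevalence_trend",
    "prevalence_schedule",
    "sealed_prevalence",
    "incidence_from_prevalence",
    "build_distribution",
]


# ---------------------------------------------------------------------------
# prevalence trend


@dataclass(frozen=True)
class PrevalencePoint:
    """One (age, prevalence) observation from the literature."""

    age: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(
                f"prevalence must lie in [0, 1], got {self.prevalence}"
            )


@dataclass(frozen=True)
class PrevalenceTrend:
    """Linear cumulative-prevalence trend, expressed per model cycle.

    ``baseline_prevalence`` is the prevalence at ``baseline_age``;
    ``increment_per_cycle`` is the rise per cycle of ``cycle_length`` years.
    Evaluations are clipped to [0, 1].
    """

    baseline_prevalence: float
    increment_per_cycle: float
    baseline_age: float = 6.0
    cycle_length: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_prevalence <= 1.0:
            raise ValueError(
                "baseline_prevalence must lie in [0, 1], got "
                f"{self.baseline_prevalence}"
            )
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")

    def at_age(self, age: float) -> float:
        cycles = (age - self.baseline_age) / self.cycle_length
        value = self.baseline_prevalence + cycles * self.increment_per_cycle
        return float(np.clip(value, 0.0, 1.0))


def fit_prevalence_trend(
    points: list[PrevalencePoint],
    cycle_length: float = 2.0,
    baseline_age: float | None = None,
) -> PrevalenceTrend:
    """Ordinary least-squares line through (age, prevalence) observations.

    The slope is re-expressed per cycle.  With exactly two points the line
    interpolates them.  Raises if fewer than two distinct ages are given.
    """
    if len(points) < 2:
        raise ValueError("need at least two prevalence points")
    ages = np.array([p.age for p in points], dtype=float)
    prevs = np.array([p.prevalence for p in points], dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("all ages identical: slope undefined")
    slope_per_year, intercept = np.polyfit(ages, prevs, deg=1)
    if baseline_age is None:
        baseline_age = float(ages.min())
    baseline = float(intercept + slope_per_year * baseline_age)
    return PrevalenceTrend(
        baseline_prevalence=float(np.clip(baseline, 0.0, 1.0)),
        increment_per_cycle=float(slope_per_year * cycle_length),
        baseline_age=baseline_age,
        cycle_length=cycle_length,
    )


def prevalence_schedule(
    trend: PrevalenceTrend, ages: list[float] | np.ndarray
) -> np.ndarray:
    """Cumulative prevalence at each age, clipped to [0, 1]."""
    return np.array([trend.at_age(a) for a in ages], dtype=float)


def sealed_prevalence(untreated_prevalence: float, effectiveness: float) -> float:
    """Prevalence in the sealed arm: caries averted in proportion to
    effectiveness, subtracted from the untreated prevalence."""
    if not 0.0 <= untreated_prevalence <= 1.0:
        raise ValueError("untreated_prevalence outside [0, 1]")
    if not 0.0 <= effectiveness <= 1.0:
        raise ValueError("effectiveness outside [0, 1]")
    return untreated_prevalence * (1.0 - effectiveness)


def incidence_from_prevalence(p_now: float, p_next: float) -> float:
    """Per-cycle conditional caries probability for still-at-risk molars.

    The model is fed cumulative ("ever carious") prevalences; the cohort
    needs the probability that a molar which reached this cycle caries-free
    develops caries during the cycle.  Propagating these conditional
    probabilities reproduces the cumulative schedule exactly.
    """
    if not 0.0 <= p_now <= 1.0 or not 0.0 <= p_next <= 1.0:
        raise ValueError("prevalences must lie in [0, 1]")
    if p_next < p_now:
        raise ValueError(
            "cumulative prevalence cannot decrease "
            f"({p_now} -> {p_next})"
        )
    if p_now == 1.0:
        return 0.0
    return (p_next - p_now) / (1.0 - p_now)


# ---------------------------------------------------------------------------
# sealant effectiveness


@dataclass(frozen=True)
class EffectivenessSchedule:
    """Sealant effectiveness by years since application, with 95% CIs.

    The schedule carries an explicit point at 0 years (effectiveness 1.0 by
    default: a sealant placed on a sound molar leaves it caries-free at
    placement), so that the sealed-arm prevalence at every examination age is
    ``untreated x (1 - effectiveness)``.
    """

    years: tuple[float, ...]
    effectiveness: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.effectiveness) == len(self.ci_low) == len(self.ci_high) == n):
            raise ValueError("schedule columns must have equal length")
        if list(self.years) != sorted(self.years):
            raise ValueError("years must be sorted ascending")
        for y, e, lo, hi in zip(
            self.years, self.effectiveness, self.ci_low, self.ci_high
        ):
            if not 0.0 <= lo <= e <= hi <= 1.0:
                raise ValueError(
                    f"need 0 <= ci_low <= effectiveness <= ci_high <= 1 at {y} y"
                )
        eff = np.asarray(self.effectiveness)
        if np.any(np.diff(eff) > 1e-12):
            raise ValueError("effectiveness must be non-increasing over time")

    def at(self, years_since_application: float) -> float:
        try:
            idx = self.years.index(years_since_application)
        except ValueError:
            raise KeyError(
                f"no effectiveness entry at {years_since_application} years"
            ) from None
        return self.effectiveness[idx]

    def with_effectiveness(self, values: "np.ndarray | list[float]") -> "EffectivenessSchedule":
        values = tuple(float(np.clip(v, 0.0, 1.0)) for v in values)
        lo = tuple(min(l, v) for l, v in zip(self.ci_low, values))
        hi = tuple(max(h, v) for h, v in zip(self.ci_high, values))
        return replace(self, effectiveness=values, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# event rates


@dataclass(frozen=True)
class RateWithRange:
    """Per-cycle probability with its deterministic sensitivity range."""

    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.base <= self.high <= 1.0:
            raise ValueError(
                f"need 0 <= low <= base <= high <= 1, got "
                f"({self.low}, {self.base}, {self.high})"
            )

    @classmethod
    def pct20(cls, base: float) -> "RateWithRange":
        """Default +-20% sensitivity range around the base value."""
        return cls(base, base * 0.8, min(base * 1.2, 1.0))


@dataclass(frozen=True)
class EventRates:
    reseal: RateWithRange
    refill: RateWithRange
    extraction_caries: RateWithRange
    extraction_other: RateWithRange


@dataclass(frozen=True)
class EpidemiologyParams:
    """All epidemiological inputs for one model run."""

    untreated_trend: PrevalenceTrend
    effectiveness: EffectivenessSchedule
    rates: EventRates

    def untreated_schedule(self, ages: list[float] | np.ndarray) -> np.ndarray:
        return prevalence_schedule(self.untreated_trend, ages)

    def sealed_schedule(
        self, ages: list[float] | np.ndarray, sealing_age: float | None = None
    ) -> np.ndarray:
        """Sealed-arm cumulative prevalence at each age.

        Effectiveness is applied to the untreated prevalence at the matching
        age (the derivation that reproduces 8/18/29% from 35.3/45.6/55.9%).
        """
        if sealing_age is None:
            sealing_age = self.untreated_trend.baseline_age
        out = []
        for age in ages:
            eff = self.effectiveness.at(age - sealing_age)
            out.append(sealed_prevalence(self.untreated_trend.at_age(age), eff))
        return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# sampling distributions for the PSA


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling recipe for one uncertain parameter.

    family
        ``"normal"``  — mean plus a 95% half-width (the printed "+-" range).
        ``"beta"``    — mean in (0, 1) plus a stated (low, high) range read
                        as a 95% interval; dispersion falls back to a 20%
                        coefficient-of-interval when no range is given.
        ``"table"``   — an effectiveness schedule sampled by a single common
                        quantile through normal approximations of each
                        time-point's 95% CI, preserving monotone decay.
    """

    family: str
    mean: float = 0.0
    half_width: float = 0.0  # normal: 95% half-width
    low: float | None = None  # beta: stated range
    high: float | None = None
    schedule: EffectivenessSchedule | None = None  # table family
    support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.family not in ("normal", "beta", "table"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValueError("beta mean must lie strictly in (0, 1)")
        if self.family == "normal" and self.half_width < 0:
            raise ValueError("normal half-width must be non-negative")
        if self.family == "table" and self.schedule is None:
            raise ValueError("table family requires an effectiveness schedule")


_Z95 = float(stats.norm.ppf(0.975))  # 1.959964...


def _beta_moments(mean: float, sd: float) -> float:
    """Alpha shape from mean and standard deviation (variance capped below
    the Bernoulli bound)."""
    var = sd * sd
    max_var = mean * (1.0 - mean)
    if var >= max_var:
        var = 0.5 * max_var
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu


def _fit_beta(mean: float, low: float | None, high: float | None):
    """Beta shapes matching the stated mean with 95% of mass inside the
    stated range.

    For a one-sided range anchored at 0 the dispersion is chosen so that
    P(X <= high) = 0.975 when that equation has a solution; when every beta
    with the stated mean already keeps 97.5% of mass below ``high`` (very
    skewed rates), or when the range is two-sided, the range is read as a
    95% interval and method-of-moments is used.  Without any range a 20%
    coefficient of interval stands in (sd = 0.2 mean / 1.96).
    """
    if high is not None and high > mean and (low is None or low <= 1e-12):
        def miss(alpha: float) -> float:
            beta = alpha * (1.0 - mean) / mean
            return stats.beta.cdf(high, alpha, beta) - 0.975

        lo_a, hi_a = 1e-6, 1e6
        if miss(lo_a) * miss(hi_a) < 0:
            alpha = optimize.brentq(miss, lo_a, hi_a, xtol=1e-12)
        else:
            alpha = _beta_moments(mean, (high - (low or 0.0)) / (2.0 * _Z95))
    elif low is not None and high is not None and high > low:
        alpha = _beta_moments(mean, (high - low) / (2.0 * _Z95))
    else:
        alpha = _beta_moments(mean, 0.2 * mean / _Z95)
    beta = alpha * (1.0 - mean) / mean
    if alpha <= 0 or beta <= 0:
        raise ValueError("fitted beta shapes must be positive")
    return alpha, beta


class _Sampler:
    """Callable sampler drawing from one DistributionSpec."""

    def __init__(self, spec: DistributionSpec):
        self.spec = spec
        if spec.family == "beta":
            if spec.half_width == 0.0 and spec.low is None and spec.high is None:
                self._shapes = None  # degenerate: point mass at mean
            else:
                self._shapes = _fit_beta(spec.mean, spec.low, spec.high)
        elif spec.family == "normal":
            self._sd = spec.half_width / _Z95
        elif spec.family == "table":
            sched = spec.schedule
            self._means = np.asarray(sched.effectiveness, dtype=float)
            self._sds = (
                np.asarray(sched.ci_high) - np.asarray(sched.ci_low)
            ) / (2.0 * _Z95)

    def __call__(self, rng: np.random.Generator, size: int | None = None):
        spec = self.spec
        lo, hi = spec.support
        if spec.family == "normal":
            if self._sd == 0.0:
                draws = np.full(size if size else 1, spec.mean)
            else:
                draws = rng.normal(spec.mean, self._sd, size=size if size else 1)
            draws = np.clip(draws, lo, hi)
            return draws if size is not None else float(draws[0])
        if spec.family == "beta":
            if self._shapes is None:
                draws = np.full(size if size else 1, spec.mean)
            else:
                draws = rng.beta(*self._shapes, size=size if size else 1)
            draws = np.clip(draws, lo, hi)
            return draws if size is not None else float(draws[0])
        # table: one common quantile across time points keeps decay monotone
        n = size if size is not None else 1
        u = rng.uniform(size=n)
        z = stats.norm.ppf(u)
        draws = np.clip(self._means[None, :] + z[:, None] * self._sds[None, :], 0.0, 1.0)
        # enforce non-increasing effectiveness over time (clipping can break it)
        draws = np.minimum.accumulate(draws, axis=1)
        if size is None:
            return draws[0]
        return draws


def build_distribution(spec: DistributionSpec):
    """Return a seedable sampler: ``sampler(rng)`` → one draw,
    ``sampler(rng, size=n)`` → an array of draws (for the table family, an
    ``(n, k)`` array of effectiveness schedules)."""
    return _Sampler(spec)
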