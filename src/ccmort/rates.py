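"""Crude, proportionate and directly age-standardised mortality rates.

Rates are expressed per 100,000 person-years.  Direct standardisation
uses the child age bands of the Revised European Standard Population
(ESP-2013): weights 5000 (ages 0-4, i.e. 1000 for age 0 plus 4000 for
1-4), 5500 (5-9) and 5500 (10-14) per 100,000, normalised over the three
groups.  Standard errors are Poisson delta-method throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "PER_100K",
    "RESP_CHILD_WEIGHTS",
    "StandardPopulation",
    "RateEstimate",
    "AsmrResult",
    "crude_rate",
    "direct_asmr",
    "compare_rates",
    "proportionate_rate",
    "rate_ratio",
]

PER_100K = 100_000.0

#: ESP-2013 weights per 100,000 for the three child age bands.
RESP_CHILD_WEIGHTS: Mapping[str, float] = {"0-4": 5000.0, "5-9": 5500.0, "10-14": 5500.0}


@dataclass(frozen=True)
class StandardPopulation:
    """A standard population: positive weights per age group."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights or any(w <= 0 for w in self.weights.values()):
            raise ValueError("standard population weights must be positive")
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def normalised(self) -> dict[str, float]:
        total = sum(self.weights.values())
        return {a: w / total for a, w in self.weights.items()}

    @classmethod
    def resp_children(cls) -> "StandardPopulation":
        """The Revised European Standard Population, ages 0-14."""
        return cls(RESP_CHILD_WEIGHTS)


@dataclass(frozen=True)
class RateEstimate:
    """A rate per 100,000 with its Poisson standard error."""

    rate: float
    se: float
    deaths: float
    person_time: float


@dataclass(frozen=True)
class AsmrResult:
    """Directly age-standardised mortality rate with components.

    ``asmr = sum_a w_a * r_a`` with normalised weights ``w_a`` and
    age-specific crude rates ``r_a``;
    ``se = 100000 * sqrt(sum_a w_a^2 d_a / n_a^2)``.
    """

    asmr: float
    se: float
    age_rates: Mapping[str, float]
    deaths: Mapping[str, float]
    person_time: Mapping[str, float]
    label: str = ""

    @property
    def total_deaths(self) -> float:
        return float(sum(self.deaths.values()))

    def summary(self) -> str:
        lines = [
            f"Age-standardised mortality rate{f' ({self.label})' if self.label else ''}:"
            f" {self.asmr:.2f} per 100,000 person-years (SE {self.se:.2f})"
        ]
        for a in self.age_rates:
            lines.append(
                f"  {a:>6}: {self.deaths[a]:.0f} deaths / {self.person_time[a]:.0f} "
                f"person-years = {self.age_rates[a]:.2f}"
            )
        return "\n".join(lines)


def crude_rate(deaths: float, person_time: float) -> RateEstimate:
    """Crude rate per 100,000 person-years with Poisson SE."""
    if person_time <= 0:
        raise ValueError("person_time must be positive")
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    rate = PER_100K * deaths / person_time
    se = PER_100K * math.sqrt(deaths) / person_time
    return RateEstimate(rate=rate, se=se, deaths=deaths, person_time=person_time)


def direct_asmr(
    deaths: Mapping[str, float],
    person_time: Mapping[str, float],
    standard: StandardPopulation | None = None,
    label: str = "",
) -> AsmrResult:
    """Directly standardised rate over the standard's age groups.

    Every age group of the standard must be present in ``deaths`` and
    ``person_time`` with positive person-time.
    """
    standard = standard or StandardPopulation.resp_children()
    w = standard.normalised
    missing = [a for a in w if a not in deaths or a not in person_time]
    if missing:
        raise ValueError(f"missing age groups: {missing}")
    if any(person_time[a] <= 0 for a in w):
        raise ValueError("person_time must be positive in every age group")
    rates = {a: PER_100K * deaths[a] / person_time[a] for a in w}
    asmr = sum(w[a] * rates[a] for a in w)
    var = sum(w[a] ** 2 * deaths[a] / person_time[a] ** 2 for a in w)
    return AsmrResult(
        asmr=asmr,
        se=PER_100K * math.sqrt(var),
        age_rates=rates,
        deaths={a: float(deaths[a]) for a in w},
        person_time={a: float(person_time[a]) for a in w},
        label=label,
    )


def compare_rates(a: AsmrResult, b: AsmrResult) -> tuple[float, float]:
    """Two-sample z-test on the standardised scale.

    Returns ``(z, p)`` with ``z = (asmr_a - asmr_b) / sqrt(se_a^2 + se_b^2)``
    and a two-sided normal p-value.
    """
    if a.se <= 0 or b.se <= 0:
        raise ValueError("both standard errors must be positive")
    z = (a.asmr - b.asmr) / math.hypot(a.se, b.se)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def proportionate_rate(cause_deaths: float, all_deaths: float) -> tuple[float, float]:
    """Proportionate mortality: fraction of all deaths due to one cause.

    Returns ``(fraction, binomial SE)``.
    """
    if all_deaths <= 0:
        raise ValueError("all_deaths must be positive")
    if not 0 <= cause_deaths <= all_deaths:
        raise ValueError("need 0 <= cause_deaths <= all_deaths")
    p = cause_deaths / all_deaths
    return p, math.sqrt(p * (1.0 - p) / all_deaths)


def rate_ratio(
    deaths_1: float, person_time_1: float, deaths_2: float, person_time_2: float
) -> tuple[float, tuple[float, float] | None]:
    """Ratio of two crude rates with a 95% log-scale Wald CI.

    The CI uses ``exp(log ratio +/- 1.96 sqrt(1/d1 + 1/d2))``; it is
    returned as ``None`` (undefined) when either death count is zero.
    """
    if person_time_1 <= 0 or person_time_2 <= 0:
        raise ValueError("person-times must be positive")
    if deaths_2 <= 0:
        raise ValueError("denominator group has no deaths; ratio undefined")
    ratio = (deaths_1 / person_time_1) / (deaths_2 / person_time_2)
    if deaths_1 <= 0:
        return ratio, None
    half = 1.959963984540054 * math.sqrt(1.0 / deaths_1 + 1.0 / deaths_2)
    return ratio, (ratio * math.exp(-half), ratio * math.exp(half))
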