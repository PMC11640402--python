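"""Registry data model and I/O for stratified death-count extracts.

A national mortality registry extract is a long-format table of death
counts stratified by calendar time (year, optionally month), sex, age
group, NUTS2 region and cause group, together with population
denominators.  This module defines the record types used throughout the
package, CSV readers/writers for them, the packaged summary-table
fixtures, monthly aggregation over a study period, and the bookkeeping
estimator that turns annual population anchors plus monthly birth/death
flows into monthly person-time at risk.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "AGE_GROUPS",
    "REGIONS",
    "CAUSES",
    "MONTH_NAMES",
    "StratifiedRecord",
    "MonthlyCountSeries",
    "RegistryValidationError",
    "read_registry",
    "write_registry",
    "read_population",
    "write_population",
    "load_fixture",
    "aggregate_monthly",
    "mean_month_days",
    "estimate_monthly_population",
]

SEXES = ("male", "female", "all")
AGE_GROUPS = ("0-4", "5-9", "10-14", "0-14")
#: The eight Hungarian NUTS2 regions (2016 revision) plus the national total.
REGIONS = ("HU11", "HU12", "HU21", "HU22", "HU23", "HU31", "HU32", "HU33", "HU")
CAUSES = (
    "all_cancer",
    "all_cause",
    "cns",
    "lymphoid_leukaemia",
    "myeloid_leukaemia",
    "nhl",
    "other",
)
MONTH_NAMES = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

#: Mean length of a month in days (Julian year / 12); the reference month
#: length used when adjusting counts for unequal calendar months.
MEAN_MONTH_DAYS = 365.25 / 12


class RegistryValidationError(ValueError):
    """Raised when a registry file or record violates the schema."""


@dataclass(frozen=True)
class StratifiedRecord:
    """One registry cell: a death count for a single stratum.

    ``month`` is ``None`` for annual records.  ``sex``, ``age_group``,
    ``region`` use the marginal tokens ``"all"``, ``"0-14"``, ``"HU"``
    for totals.
    """

    year: int
    month: int | None
    sex: str
    age_group: str
    region: str
    cause: str
    deaths: int

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= int(self.month) <= 12:
            raise RegistryValidationError(f"month must be 1-12, got {self.month}")
        if self.sex not in SEXES:
            raise RegistryValidationError(f"unknown sex token {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise RegistryValidationError(f"unknown age_group token {self.age_group!r}")
        if self.region not in REGIONS:
            raise RegistryValidationError(f"unknown region token {self.region!r}")
        if self.cause not in CAUSES:
            raise RegistryValidationError(f"unknown cause token {self.cause!r}")
        if int(self.deaths) != self.deaths or self.deaths < 0:
            raise RegistryValidationError(
                f"deaths must be a non-negative integer, got {self.deaths!r}"
            )

    @property
    def key(self) -> tuple:
        """Stratum identifier (all fields except the count)."""
        return (self.year, self.month, self.sex, self.age_group, self.region, self.cause)


@dataclass(frozen=True)
class MonthlyCountSeries:
    """Twelve monthly death counts aggregated over a study period.

    Parameters
    ----------
    label
        Period identifier, e.g. ``"2001-2010"``.
    counts
        Counts ``n_1..n_12`` for January through December.
    at_risk
        Optional population at risk ``m_1..m_12`` (person-time per month,
        summed or averaged over the period -- only its monthly profile
        matters to the tests that use it).
    month_days
        Optional mean calendar days per month over the period.
    """

    label: str
    counts: tuple[int, ...]
    at_risk: tuple[float, ...] | None = None
    month_days: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != 12:
            raise RegistryValidationError("counts must have length 12")
        if any(c < 0 for c in counts):
            raise RegistryValidationError("counts must be non-negative")
        if sum(counts) == 0:
            raise RegistryValidationError("total count must be positive")
        object.__setattr__(self, "counts", counts)
        for name in ("at_risk", "month_days"):
            vals = getattr(self, name)
            if vals is not None:
                vals = tuple(float(v) for v in vals)
                if len(vals) != 12 or any(v <= 0 for v in vals):
                    raise RegistryValidationError(f"{name} must be 12 positive values")
                object.__setattr__(self, name, vals)

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def with_at_risk(self, at_risk: Sequence[float]) -> "MonthlyCountSeries":
        return replace(self, at_risk=tuple(float(v) for v in at_risk))


_REGISTRY_COLUMNS = ["year", "month", "sex", "age_group", "region", "cause", "deaths"]
_POPULATION_COLUMNS = ["year", "month", "sex", "age_group", "region", "persons"]


def read_registry(path, schema: str = "monthly") -> list[StratifiedRecord]:
    """Read a long-format registry CSV into validated records.

    ``schema`` is ``"monthly"`` (month column required per row) or
    ``"annual"`` (month column empty).  Duplicate stratum cells and
    negative counts are rejected with the offending row named.
    """
    if schema not in ("monthly", "annual"):
        raise ValueError(f"schema must be 'monthly' or 'annual', got {schema!r}")
    df = pd.read_csv(path, dtype={"sex": str, "age_group": str, "region": str, "cause": str})
    missing = set(_REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise RegistryValidationError(f"missing columns: {sorted(missing)}")
    records: list[StratifiedRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        month = getattr(row, "month")
        month = None if pd.isna(month) else int(month)
        if schema == "monthly" and month is None:
            raise RegistryValidationError(f"row {i}: monthly schema requires a month")
        if schema == "annual" and month is not None:
            raise RegistryValidationError(f"row {i}: annual schema forbids a month")
        try:
            rec = StratifiedRecord(
                year=int(row.year), month=month, sex=row.sex,
                age_group=row.age_group, region=row.region,
                cause=row.cause, deaths=int(row.deaths),
            )
        except (RegistryValidationError, ValueError) as exc:
            raise RegistryValidationError(f"row {i}: {exc}") from exc
        if rec.key in seen:
            raise RegistryValidationError(f"row {i}: duplicate cell {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_registry(records: Iterable[StratifiedRecord], path) -> None:
    """Write records to CSV in the documented long-format schema."""
    df = pd.DataFrame(
        [
            (r.year, "" if r.month is None else r.month, r.sex, r.age_group,
             r.region, r.cause, r.deaths)
            for r in records
        ],
        columns=_REGISTRY_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    """Read a population denominator CSV (persons per stratum and period)."""
    df = pd.read_csv(path)
    missing = set(_POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise RegistryValidationError(f"missing columns: {sorted(missing)}")
    if (df["persons"] <= 0).any():
        bad = df.index[df["persons"] <= 0][0] + 2
        raise RegistryValidationError(f"row {bad}: persons must be positive")
    return df


def write_population(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_POPULATION_COLUMNS)


def mean_month_days(years: Sequence[int]) -> tuple[float, ...]:
    """Mean calendar days of each month over the given years (leap-aware)."""
    years = list(years)
    return tuple(
        float(np.mean([calendar.monthrange(y, m)[1] for y in years]))
        for m in range(1, 13)
    )


def _fixture_frame(name: str) -> pd.DataFrame:
    with resources.files("ccmort.data").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh)


# period -> (fixture column, year range)
_TABLE2_PERIODS = {
    "2001-2010": ("cancer_2001_2010", range(2001, 2011)),
    "2011-2019": ("cancer_2011_2019", range(2011, 2020)),
    "2020-2021": ("cancer_2020_2021", range(2020, 2022)),
    "2001-2021": ("cancer_2001_2021", range(2001, 2022)),
    "all_cause": ("all_cause_2001_2021", range(2001, 2022)),
}
_TABLE2_TOTALS = {
    "2001-2010": 613,
    "2011-2019": 413,
    "2020-2021": 66,
    "2001-2021": 1092,
    "all_cause": 14931,
}


def load_fixture(name: str):
    """Load a packaged in-study summary table.

    ``"table2"`` returns a dict of :class:`MonthlyCountSeries` (monthly
    childhood-cancer deaths per sub-period plus the all-cause column),
    ``"table1"`` the subgroup death counts and crude rates, ``"causes"``
    the leading cause-of-death totals.  Totals are cross-checked on load.
    """
    if name == "table2":
        df = _fixture_frame("table2")
        out: dict[str, MonthlyCountSeries] = {}
        for label, (col, years) in _TABLE2_PERIODS.items():
            series = MonthlyCountSeries(
                label=label,
                counts=tuple(int(v) for v in df[col]),
                month_days=mean_month_days(years),
            )
            if series.total != _TABLE2_TOTALS[label]:
                raise RegistryValidationError(
                    f"fixture table2 column {label} sums to {series.total}, "
                    f"expected {_TABLE2_TOTALS[label]}"
                )
            out[label] = series
        return out
    if name == "table1":
        return _fixture_frame("table1")
    if name == "causes":
        return _fixture_frame("causes")
    raise KeyError(f"unknown fixture {name!r}; available: table1, table2, causes")


def aggregate_monthly(
    records: Iterable[StratifiedRecord],
    years: Sequence[int],
    cause: str = "all_cancer",
    sex: str = "all",
    age_group: str = "0-14",
    region: str = "HU",
    label: str | None = None,
) -> MonthlyCountSeries:
    """Aggregate monthly records over a period into a 12-month series.

    All selected records must carry a month; annual records raise.
    ``month_days`` is the leap-aware mean calendar length of each month
    over the period.
    """
    years = set(int(y) for y in years)
    counts = np.zeros(12, dtype=int)
    for r in records:
        if r.year not in years or (r.sex, r.age_group, r.region, r.cause) != (
            sex, age_group, region, cause,
        ):
            continue
        if r.month is None:
            raise RegistryValidationError(
                f"annual record for year {r.year} cannot be aggregated by month"
            )
        counts[r.month - 1] += r.deaths
    ys = sorted(years)
    return MonthlyCountSeries(
        label=label or f"{ys[0]}-{ys[-1]}",
        counts=tuple(int(c) for c in counts),
        month_days=mean_month_days(ys),
    )


def estimate_monthly_population(
    annual: Mapping[int, float],
    births: Mapping[tuple[int, int], float] | None = None,
    deaths: Mapping[tuple[int, int], float] | None = None,
) -> pd.DataFrame:
    """Estimate mid-month population from annual anchors and monthly flows.

    The annual figures anchor the population stock at the start of each
    January.  Within year ``y`` the month-end stock evolves as

        P_m = P_{m-1} + births_m - deaths_m - ageout,

    where the constant monthly age-out flow (children turning 15) is the
    residual that closes December's stock onto the next annual anchor:

        ageout = (P_0 + sum(births) - sum(deaths) - P_12_target) / 12.

    The mid-month population -- the person-time denominator -- is the mean
    of the two adjacent month-end stocks.  With zero flows this reduces to
    linear interpolation between consecutive anchors.

    Returns a DataFrame with columns ``year, month, persons`` covering every
    year that has a following anchor.
    """
    births = births or {}
    deaths = deaths or {}
    years = sorted(int(y) for y in annual)
    if len(years) < 2:
        raise ValueError("need annual anchors for at least two consecutive years")
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("annual anchors must cover consecutive years")
    rows = []
    for y in years[:-1]:
        p0 = float(annual[y])
        b = np.array([float(births.get((y, m), 0.0)) for m in range(1, 13)])
        d = np.array([float(deaths.get((y, m), 0.0)) for m in range(1, 13)])
        ageout = (p0 + b.sum() - d.sum() - float(annual[y + 1])) / 12.0
        stocks = p0 + np.cumsum(b - d - ageout)
        mid = (np.concatenate([[p0], stocks[:-1]]) + stocks) / 2.0
        if (mid <= 0).any():
            raise ValueError(f"non-positive estimated population in year {y}")
        for m in range(1, 13):
            rows.append((y, m, mid[m - 1]))
    return pd.DataFrame(rows, columns=["year", "month", "persons"])
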