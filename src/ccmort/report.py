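"""Study orchestration: run the full analysis pipeline and render tables.

``run_study`` takes a monthly registry extract (and optionally monthly
population denominators), splits it into study periods, and produces a
:class:`StudyReport` holding subgroup counts, per-period seasonality
tests (orders 1 and 2 plus the joint test, chi-square and Monte-Carlo
p-values), the annual Poisson trend with its joinpoint sensitivity scan,
and age-standardised rate comparisons where age-stratified denominators
are available.  ``render_report`` writes the report as JSON, CSV or
markdown with the display conventions of epidemiological summary tables
(rates to 2 decimals, p-values to 2-3 decimals with "<0.001" below a
thousandth).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import rates as rates_mod
from .registry import (
    MONTH_NAMES,
    MonthlyCountSeries,
    StratifiedRecord,
    aggregate_monthly,
)
from .seasonality import (
    SeasonalityResult,
    edwards_test,
    joint_harmonic_test,
    monte_carlo_p,
    walter_elwood_test,
)
from .trend import fit_poisson_trend, joinpoint_scan

__all__ = ["StudyReport", "run_study", "render_report", "format_p"]

DEFAULT_PERIODS = ((2001, 2010), (2011, 2019), (2020, 2021), (2001, 2021))


def format_p(p: float) -> str:
    """Format a p-value for display: '<0.001' below a thousandth, else
    three decimals with a trailing zero trimmed (0.18 not 0.180)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.001:
        return "<0.001"
    s = f"{p:.3f}"
    if s.endswith("0"):
        s = s[:-1]
    return s


def _seasonality_dict(r: SeasonalityResult) -> dict:
    return {
        "method": r.method,
        "order": r.order,
        "statistic": float(r.statistic),
        "df": int(r.df),
        "p_chi2": float(r.p_chi2),
        "p_mc": None if r.p_mc is None else float(r.p_mc),
        "p_display": format_p(r.p),
        "amplitude": float(r.amplitude),
        "peak_months": [int(m) for m in r.peak_months],
        "peak_labels": list(r.peak_month_names),
        "significant": bool(r.p < 0.05),
        "sparse": bool(r.sparse),
    }


@dataclass
class StudyReport:
    """Full study output as plain JSON-serialisable structures."""

    manifest: dict
    subgroups: list = field(default_factory=list)
    monthly: dict = field(default_factory=dict)
    trend: dict | None = None
    joinpoint: dict | None = None
    asmr: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls(**json.loads(text))

    def peak_summary(self) -> dict[str, str]:
        """Per-period peak labels, 'NS' where nothing is significant."""
        out = {}
        for period, block in self.monthly.items():
            tests = block["tests"]
            sig = [t for t in tests.values() if t["significant"] and t["df"] == 2]
            if not sig:
                out[period] = "NS"
            else:
                best = min(sig, key=lambda t: t["p_chi2"])
                out[period] = ", ".join(best["peak_labels"])
        return out


def _period_person_time(population: pd.DataFrame | None, years: set[int]):
    """Monthly person-time profile summed over the period, or None."""
    if population is None:
        return None
    df = population[population["year"].isin(years)]
    if df.empty or "month" not in df.columns:
        return None
    prof = df.groupby("month")["persons"].sum()
    if set(prof.index) != set(range(1, 13)):
        return None
    return tuple(float(prof[m]) for m in range(1, 13))


def _season_tests(
    series: MonthlyCountSeries, mc_reps: int, rng: np.random.Generator
) -> dict:
    use_we = series.at_risk is not None
    base = walter_elwood_test if use_we else edwards_test
    tests = {}
    for order in (1, 2):
        res = base(series, order=order)
        if mc_reps:
            res = res.with_mc(
                monte_carlo_p(
                    series,
                    lambda s, k=order: base(s, order=k).statistic,
                    n_reps=mc_reps,
                    seed=rng,
                )
            )
        tests[f"order{order}"] = _seasonality_dict(res)
    tests["joint"] = _seasonality_dict(joint_harmonic_test(series))
    return tests


def run_study(
    records: Sequence[StratifiedRecord],
    population: pd.DataFrame | None = None,
    periods: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
    cause: str = "all_cancer",
    mc_reps: int = 999,
    seed: int = 0,
) -> StudyReport:
    """Run the full pipeline on a monthly registry extract.

    ``population``, when given, is a monthly denominator table with
    columns ``year, month, persons`` (national); it feeds the
    population-at-risk seasonality tests and the annual trend.  The
    report is deterministic for a fixed seed.
    """
    records = list(records)
    all_years = sorted({r.year for r in records})
    for lo, hi in periods:
        if lo > hi or lo < all_years[0] or hi > all_years[-1]:
            raise ValueError(f"period {lo}-{hi} outside the data range")
    rng = np.random.default_rng(seed)
    report = StudyReport(
        manifest={
            "periods": [list(p) for p in periods],
            "cause": cause,
            "mc_reps": int(mc_reps),
            "seed": int(seed),
            "years": [all_years[0], all_years[-1]],
        }
    )

    # ---- subgroup counts (marginal records only) -------------------------
    for r in records:
        if r.cause != cause:
            continue
        marginal = [r.sex != "all", r.age_group != "0-14", r.region != "HU"]
        if sum(marginal) == 1:
            report.subgroups.append(
                {
                    "year": r.year,
                    "month": r.month,
                    "sex": r.sex,
                    "age_group": r.age_group,
                    "region": r.region,
                    "deaths": int(r.deaths),
                }
            )

    # ---- per-period seasonality -----------------------------------------
    for lo, hi in periods:
        years = set(range(lo, hi + 1))
        label = f"{lo}-{hi}"
        matched = [
            r for r in records
            if r.year in years
            and (r.sex, r.age_group, r.region, r.cause) == ("all", "0-14", "HU", cause)
        ]
        if sum(r.deaths for r in matched) == 0:
            # empty stratum: report a row of zeros, no tests (NS)
            report.monthly[label] = {"counts": [0] * 12, "total": 0, "tests": {}}
            continue
        series = aggregate_monthly(records, sorted(years), cause=cause)
        at_risk = _period_person_time(population, years)
        if at_risk is not None:
            series = series.with_at_risk(at_risk)
        report.monthly[label] = {
            "counts": [int(c) for c in series.counts],
            "total": series.total,
            "tests": _season_tests(series, mc_reps, rng),
        }

    # ---- sex ratio over the whole span ----------------------------------
    by_sex = {
        s: sum(r.deaths for r in records
               if r.cause == cause and r.sex == s and r.age_group == "0-14"
               and r.region == "HU" and r.month is not None)
        for s in ("male", "female")
    }
    if by_sex["male"] and by_sex["female"]:
        ratio, ci = rates_mod.rate_ratio(by_sex["male"], 1.0, by_sex["female"], 1.0)
        report.comparisons["sex_ratio"] = {
            "male_deaths": by_sex["male"],
            "female_deaths": by_sex["female"],
            "ratio": float(ratio),
            "ci95": None if ci is None else [float(ci[0]), float(ci[1])],
            "note": "equal person-time assumed for the two sexes",
        }

    # ---- annual trend (requires population) ------------------------------
    if population is not None:
        annual_counts = {}
        for r in records:
            if (r.cause, r.sex, r.age_group, r.region) == (cause, "all", "0-14", "HU"):
                annual_counts[r.year] = annual_counts.get(r.year, 0) + r.deaths
        years = sorted(annual_counts)
        pt = population.groupby("year")["persons"].mean().reindex(years) \
            if "month" in population.columns else \
            population.set_index("year")["persons"].reindex(years)
        if not pt.isna().any() and len(years) >= 3:
            tr = fit_poisson_trend(
                [annual_counts[y] for y in years], pt.to_numpy(), years
            )
            report.trend = {
                "irr": tr.irr,
                "ci95": list(tr.ci95),
                "p": tr.p,
                "dispersion_p": tr.dispersion_p,
                "deviance": tr.deviance,
                "n_years": tr.nobs,
            }
            if len(years) >= 7:
                jp = joinpoint_scan(
                    [annual_counts[y] for y in years], pt.to_numpy(), years
                )
                report.joinpoint = {
                    "n_joinpoints": jp.n_joinpoints,
                    "breakpoint_year": jp.breakpoint_year,
                    "segment_irrs": [float(g) for g in jp.segment_irrs],
                }
    return report


def render_report(report: StudyReport, fmt: str, path=None):
    """Render a report as ``json``, ``csv`` or ``markdown``.

    Returns the rendered text (also written to ``path`` when given).
    CSV output is the monthly table: one row per period with counts,
    per-order p-values and peak labels in a stable column order.
    """
    if fmt == "json":
        text = report.to_json()
    elif fmt == "csv":
        rows = []
        for period, block in report.monthly.items():
            row = {"period": period, "total": block["total"]}
            for m, c in zip(MONTH_NAMES, block["counts"]):
                row[m] = c
            for key in ("order1", "order2", "joint"):
                t = block["tests"][key]
                row[f"p_{key}"] = t["p_display"]
                row[f"peak_{key}"] = ", ".join(t["peak_labels"])
            rows.append(row)
        text = pd.DataFrame(rows).to_csv(index=False)
    elif fmt == "markdown":
        lines = ["# Study report", "", "## Monthly seasonality", ""]
        header = "| period | N | p (1 peak) | p (2 peaks) | peaks |"
        lines += [header, "|" + "---|" * 5]
        peaks = report.peak_summary()
        for period, block in report.monthly.items():
            t1 = block["tests"]["order1"]
            t2 = block["tests"]["order2"]
            lines.append(
                f"| {period} | {block['total']} | {t1['p_display']} "
                f"| {t2['p_display']} | {peaks[period]} |"
            )
        if report.trend:
            lines += [
                "",
                "## Annual trend",
                "",
                f"IRR per annum {report.trend['irr']:.3f} "
                f"(95% CI {report.trend['ci95'][0]:.3f}-{report.trend['ci95'][1]:.3f}), "
                f"p = {format_p(report.trend['p'])}",
            ]
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown format {fmt!r}; use json, csv or markdown")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
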