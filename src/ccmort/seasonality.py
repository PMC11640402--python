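"""Seasonality tests for 12-month aggregated event counts.

Implements the square-root harmonic family of cyclic-trend tests used in
descriptive epidemiology:

* Edwards' geometric test -- square-root transformed monthly counts are
  placed on a circle at mid-month angles; the displacement of their
  centroid from the centre measures cyclic trend and is referred to a
  chi-square distribution with 2 degrees of freedom.
* The Walter-Elwood extension -- the same harmonic contrast applied to
  ``sqrt(observed) - sqrt(expected)`` residuals, where the expected
  monthly counts follow the (possibly varying) population at risk.
* Second-harmonic variants of both, modelling two antipodal peaks six
  months apart, and a joint two-harmonic test on 4 df.
* Harmonic (cosinor) Poisson regression with an offset, giving a
  likelihood-ratio test of seasonality and a goodness-of-fit check.
* Monte-Carlo calibration of any of the above statistics under a
  multinomial null, as a safeguard for the chi-square approximations at
  small counts.

The harmonic model behind all of these is an intensity proportional to
``1 + alpha * cos(k*theta - phi)``: ``k = 1`` gives a single annual peak
at phase ``phi``; ``k = 2`` gives two peaks six months apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .registry import MEAN_MONTH_DAYS, MONTH_NAMES, MonthlyCountSeries

__all__ = [
    "mid_month_angles",
    "SeasonalityResult",
    "edwards_test",
    "walter_elwood_test",
    "joint_harmonic_test",
    "HarmonicPoissonModel",
    "HarmonicPoissonResults",
    "poisson_harmonic_fit",
    "monte_carlo_p",
    "peak_to_month",
]

#: Threshold below which chi-square p-values on sparse tables should be
#: treated with caution and the Monte-Carlo p preferred.
SPARSE_TOTAL = 50


def mid_month_angles(order: int = 1) -> np.ndarray:
    """Angles assigned to the twelve months, mid-month convention.

    Month ``i`` (January = 1) sits at ``2*pi*(i - 0.5)/12``; ``order``
    multiplies the angles for higher harmonics.  The angles are exactly
    balanced: both ``sum(cos)`` and ``sum(sin)`` vanish and
    ``sum(cos^2) = 6`` for order 1 and 2.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    return order * 2.0 * np.pi * (np.arange(1, 13) - 0.5) / 12.0


def peak_to_month(phi: float, order: int = 1) -> tuple[int, ...]:
    """Map a peak angle to calendar month number(s).

    Month ``i`` owns the arc ``[2*pi*(i-1)/12, 2*pi*i/12)``; an angle of 0
    therefore falls in January.  For ``order = 2`` the angle lives in the
    doubled space and maps to two antipodal peaks six months apart,
    returned in calendar order.
    """
    phi = float(phi) % (2.0 * np.pi)
    if order == 1:
        return (int(phi / (2.0 * np.pi) * 12.0) + 1,)
    if order == 2:
        first = (phi / 2.0) % (2.0 * np.pi)
        months = sorted(
            int(a / (2.0 * np.pi) * 12.0) + 1 for a in (first, (first + np.pi) % (2 * np.pi))
        )
        return tuple(months)
    raise ValueError(f"order must be 1 or 2, got {order}")


@dataclass(frozen=True)
class SeasonalityResult:
    """Outcome of a seasonality test on one 12-month series.

    ``statistic`` is referred to chi-square with ``df`` degrees of
    freedom (``p_chi2``); ``p_mc`` is filled in when a Monte-Carlo
    calibration has been run.  ``amplitude`` estimates the relative
    seasonal excess ``alpha`` of the harmonic intensity model, and
    ``peak_months`` the calendar month(s) of peak mortality (two months,
    six apart, for a second-harmonic fit).
    """

    method: str
    order: int
    statistic: float
    df: int
    p_chi2: float
    amplitude: float
    peak_angle: float
    peak_months: tuple[int, ...]
    C: float
    S: float
    n_total: int
    label: str = ""
    p_mc: float | None = None
    sparse: bool = False
    components: Mapping[int, "SeasonalityResult"] | None = None

    @property
    def p(self) -> float:
        """Preferred p-value: Monte-Carlo when available, else chi-square."""
        return self.p_chi2 if self.p_mc is None else self.p_mc

    @property
    def peak_month_names(self) -> tuple[str, ...]:
        return tuple(MONTH_NAMES[m - 1] for m in self.peak_months)

    def with_mc(self, p_mc: float) -> "SeasonalityResult":
        from dataclasses import replace

        return replace(self, p_mc=p_mc)

    def summary(self) -> str:
        lines = [
            f"Seasonality test: {self.method} (harmonic order {self.order})",
            f"  series         {self.label or '<unnamed>'}  (N = {self.n_total})",
            f"  statistic      {self.statistic:.4f} on {self.df} df",
            f"  p (chi-square) {self.p_chi2:.4g}",
        ]
        if self.p_mc is not None:
            lines.append(f"  p (Monte-Carlo) {self.p_mc:.4g}")
        lines += [
            f"  amplitude      {self.amplitude:.3f}",
            f"  peak           {', '.join(self.peak_month_names)}"
            f"  (angle {np.degrees(self.peak_angle):.1f} deg)",
        ]
        if self.sparse:
            lines.append(
                f"  note: total count < {SPARSE_TOTAL}; chi-square approximation "
                "is rough, prefer the Monte-Carlo p"
            )
        return "\n".join(lines)


def _adjusted_counts(series: MonthlyCountSeries) -> np.ndarray:
    """Counts rescaled to a common month length (Edwards adjustment)."""
    n = np.asarray(series.counts, dtype=float)
    if series.month_days is None:
        raise ValueError("month_days required for month-length adjustment")
    return n * MEAN_MONTH_DAYS / np.asarray(series.month_days, dtype=float)


def _harmonic_result(
    method: str,
    series: MonthlyCountSeries,
    resid: np.ndarray,
    scale: float,
    order: int,
) -> SeasonalityResult:
    """Build a result from square-root-scale residuals.

    ``T = (2/3)(C^2 + S^2)`` follows from Var(sqrt(n)) ~ 1/4 and
    ``sum(cos^2) = 6`` under the Poisson null, giving a chi-square with
    2 df.  The centroid displacement ``d = |(C, S)| / scale`` estimates
    ``alpha / 4`` under the harmonic intensity model, hence the reported
    amplitude ``4 d``.
    """
    theta = mid_month_angles(order)
    C = float(resid @ np.cos(theta))
    S = float(resid @ np.sin(theta))
    T = (2.0 / 3.0) * (C * C + S * S)
    phi = float(np.arctan2(S, C) % (2.0 * np.pi))
    d = np.hypot(C, S) / scale
    return SeasonalityResult(
        method=method,
        order=order,
        statistic=T,
        df=2,
        p_chi2=float(stats.chi2.sf(T, 2)),
        amplitude=float(4.0 * d),
        peak_angle=phi,
        peak_months=peak_to_month(phi, order),
        C=C,
        S=S,
        n_total=series.total,
        label=series.label,
        sparse=series.total < SPARSE_TOTAL,
    )


def edwards_test(
    series: MonthlyCountSeries,
    order: int = 1,
    adjust_month_length: bool = False,
) -> SeasonalityResult:
    """Edwards' geometric seasonality test (no population at risk).

    Square roots of the monthly counts are placed at mid-month angles;
    the squared length of the resulting harmonic contrast, scaled to unit
    null variance, is the test statistic (chi-square, 2 df).  With
    ``adjust_month_length`` the counts are first rescaled to equal-length
    months using the series' mean calendar month lengths.
    """
    n = _adjusted_counts(series) if adjust_month_length else np.asarray(series.counts, float)
    s = np.sqrt(n)
    return _harmonic_result("edwards", series, s, s.sum(), order)


def walter_elwood_test(
    series: MonthlyCountSeries,
    order: int = 1,
    adjust_month_length: bool = False,
) -> SeasonalityResult:
    """Walter-Elwood seasonality test with variable population at risk.

    Expected monthly counts are proportional to the population at risk
    ``m_i`` (times the calendar month length when
    ``adjust_month_length``); the statistic is the harmonic contrast of
    the variance-stabilised residuals ``sqrt(n_i) - sqrt(e_i)``.  With a
    constant population the expected counts are equal across months and
    the test reduces exactly to Edwards'.
    """
    if series.at_risk is None:
        raise ValueError("walter_elwood_test requires the series' at_risk population")
    m = np.asarray(series.at_risk, dtype=float)
    if adjust_month_length:
        if series.month_days is None:
            raise ValueError("month_days required for month-length adjustment")
        m = m * np.asarray(series.month_days, dtype=float)
    e = series.total * m / m.sum()
    n = np.asarray(series.counts, dtype=float)
    resid = np.sqrt(n) - np.sqrt(e)
    return _harmonic_result("walter_elwood", series, resid, np.sqrt(n).sum(), order)


def joint_harmonic_test(
    series: MonthlyCountSeries,
    orders: Sequence[int] = (1, 2),
    adjust_month_length: bool = False,
) -> SeasonalityResult:
    """Joint test across harmonics: statistics add, degrees of freedom add.

    Uses the Walter-Elwood form when the series carries a population at
    risk, Edwards' otherwise.  The per-order component results are kept on
    the returned object for model choice (single vs double peak).
    """
    test = walter_elwood_test if series.at_risk is not None else edwards_test
    parts = {k: test(series, order=k, adjust_month_length=adjust_month_length) for k in orders}
    T = sum(r.statistic for r in parts.values())
    df = sum(r.df for r in parts.values())
    lead = max(parts.values(), key=lambda r: r.statistic)
    return SeasonalityResult(
        method=f"{lead.method}_joint",
        order=lead.order,
        statistic=float(T),
        df=int(df),
        p_chi2=float(stats.chi2.sf(T, df)),
        amplitude=lead.amplitude,
        peak_angle=lead.peak_angle,
        peak_months=lead.peak_months,
        C=lead.C,
        S=lead.S,
        n_total=series.total,
        label=series.label,
        sparse=series.total < SPARSE_TOTAL,
        components=parts,
    )


class HarmonicPoissonModel:
    """Harmonic (cosinor) Poisson regression for monthly counts.

    Models ``log mu_i = beta_0 + offset_i + sum_k a_k cos(k theta_i) +
    b_k sin(k theta_i)`` for ``k = 1..K`` harmonics at mid-month angles.
    The offset carries the log population at risk (or, for proportionate
    analyses, the log of a reference count series such as all-cause
    deaths); omit it for a constant-population analysis.

    Parameters
    ----------
    series
        The 12-month count series.
    offset
        Optional 12 positive exposures; entered as ``log(offset)``.
    n_harmonics
        K in {1, 2}.
    """

    def __init__(
        self,
        series: MonthlyCountSeries,
        offset: Sequence[float] | None = None,
        n_harmonics: int = 1,
    ):
        if n_harmonics not in (1, 2):
            raise ValueError(f"n_harmonics must be 1 or 2, got {n_harmonics}")
        self.series = series
        self.n_harmonics = n_harmonics
        y = np.asarray(series.counts, dtype=float)
        if offset is None:
            off = np.zeros(12)
        else:
            off = np.asarray(offset, dtype=float)
            if off.shape != (12,) or (off <= 0).any():
                raise ValueError("offset must be 12 positive values")
            off = np.log(off)
        cols = [np.ones(12)]
        names = ["const"]
        for k in range(1, n_harmonics + 1):
            theta = mid_month_angles(k)
            cols += [np.cos(theta), np.sin(theta)]
            names += [f"cos{k}", f"sin{k}"]
        self._y = y
        self._X = np.column_stack(cols)
        self._names = names
        self._offset = off

    def fit(self) -> "HarmonicPoissonResults":
        full = sm.GLM(self._y, self._X, family=sm.families.Poisson(), offset=self._offset).fit()
        null = sm.GLM(
            self._y, self._X[:, :1], family=sm.families.Poisson(), offset=self._offset
        ).fit()
        return HarmonicPoissonResults(self, full, null)


@dataclass
class HarmonicPoissonResults:
    """Fitted harmonic Poisson regression with its seasonality LR test."""

    model: HarmonicPoissonModel
    _full: "sm.GLM"
    _null: "sm.GLM"

    def __post_init__(self) -> None:
        self.params = dict(zip(self.model._names, self._full.params))
        self.lr_df = 2 * self.model.n_harmonics
        self.lr_stat = float(2.0 * (self._full.llf - self._null.llf))
        self.lr_p = float(stats.chi2.sf(self.lr_stat, self.lr_df))
        self.deviance = float(self._full.deviance)
        self.gof_df = 12 - 1 - self.lr_df
        self.gof_p = float(stats.chi2.sf(self.deviance, self.gof_df))

    def amplitude(self, k: int = 1) -> float:
        """Relative seasonal excess of harmonic ``k``: sqrt(a_k^2 + b_k^2)."""
        return float(np.hypot(self.params[f"cos{k}"], self.params[f"sin{k}"]))

    def phase(self, k: int = 1) -> float:
        """Peak angle of harmonic ``k`` in the doubled space for k = 2."""
        return float(
            np.arctan2(self.params[f"sin{k}"], self.params[f"cos{k}"]) % (2.0 * np.pi)
        )

    def peak_months(self, k: int | None = None) -> tuple[int, ...]:
        if k is None:
            k = max(
                range(1, self.model.n_harmonics + 1), key=self.amplitude
            )
        return peak_to_month(self.phase(k), order=k)

    def as_seasonality_result(self) -> SeasonalityResult:
        k = max(range(1, self.model.n_harmonics + 1), key=self.amplitude)
        return SeasonalityResult(
            method="poisson_harmonic",
            order=k,
            statistic=self.lr_stat,
            df=self.lr_df,
            p_chi2=self.lr_p,
            amplitude=self.amplitude(k),
            peak_angle=self.phase(k),
            peak_months=self.peak_months(k),
            C=float(self.params[f"cos{k}"]),
            S=float(self.params[f"sin{k}"]),
            n_total=self.model.series.total,
            label=self.model.series.label,
            sparse=self.model.series.total < SPARSE_TOTAL,
        )

    def summary(self) -> str:
        lines = [
            f"Harmonic Poisson regression, K = {self.model.n_harmonics} "
            f"(series {self.model.series.label or '<unnamed>'})",
            f"  LR seasonality test  {self.lr_stat:.4f} on {self.lr_df} df, "
            f"p = {self.lr_p:.4g}",
        ]
        for k in range(1, self.model.n_harmonics + 1):
            months = ", ".join(MONTH_NAMES[m - 1] for m in self.peak_months(k))
            lines.append(
                f"  harmonic {k}: amplitude {self.amplitude(k):.3f}, peak {months}"
            )
        lines.append(
            f"  goodness of fit: deviance {self.deviance:.3f} on {self.gof_df} df, "
            f"p = {self.gof_p:.3g}"
        )
        return "\n".join(lines)


def poisson_harmonic_fit(
    series: MonthlyCountSeries,
    offset: Sequence[float] | None = None,
    n_harmonics: int = 1,
) -> HarmonicPoissonResults:
    """Fit the harmonic Poisson model; see :class:`HarmonicPoissonModel`."""
    return HarmonicPoissonModel(series, offset=offset, n_harmonics=n_harmonics).fit()


def _null_probabilities(
    series: MonthlyCountSeries, adjust_month_length: bool = False
) -> np.ndarray:
    """Multinomial null cell probabilities: proportional to population at
    risk times (optionally) month length, uniform when neither applies."""
    p = np.ones(12)
    if series.at_risk is not None:
        p = p * np.asarray(series.at_risk, dtype=float)
    if adjust_month_length and series.month_days is not None:
        p = p * np.asarray(series.month_days, dtype=float)
    return p / p.sum()


def monte_carlo_p(
    series: MonthlyCountSeries,
    statistic_fn: Callable[[MonthlyCountSeries], float],
    n_reps: int = 9999,
    seed: int | np.random.Generator | None = None,
    adjust_month_length: bool = False,
) -> float:
    """Monte-Carlo p-value of a seasonality statistic under the
    multinomial null.

    Conditional on the total count N, the null distributes deaths over
    months as multinomial with probabilities proportional to the
    population at risk (uniform when none is attached).  ``statistic_fn``
    maps a :class:`MonthlyCountSeries` to its statistic; the returned
    p-value is ``(1 + #{T* >= T_obs}) / (n_reps + 1)`` and is exactly
    reproducible for a fixed seed.
    """
    if n_reps < 99:
        raise ValueError("n_reps must be at least 99")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = float(statistic_fn(series))
    p = _null_probabilities(series, adjust_month_length)
    draws = rng.multinomial(series.total, p, size=n_reps)
    exceed = 0
    for row in draws:
        resampled = MonthlyCountSeries(
            label=series.label,
            counts=tuple(int(v) for v in row),
            at_risk=series.at_risk,
            month_days=series.month_days,
        )
        try:
            t_star = float(statistic_fn(resampled))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"statistic failed on a Monte-Carlo resample of {series.label!r}"
            ) from exc
        if t_star >= t_obs:
            exceed += 1
    return (1.0 + exceed) / (n_reps + 1.0)


def harmonic_statistic_batch(counts: np.ndarray, order: int = 1) -> np.ndarray:
    """Vectorised Edwards statistic for a batch of 12-month count rows.

    Used for fast null-calibration studies; equivalent to
    ``edwards_test(series, order).statistic`` row by row.
    """
    s = np.sqrt(np.asarray(counts, dtype=float))
    theta = mid_month_angles(order)
    C = s @ np.cos(theta)
    S = s @ np.sin(theta)
    return (2.0 / 3.0) * (C * C + S * S)
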