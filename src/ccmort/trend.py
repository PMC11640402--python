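"""Annual mortality trends: log-linear Poisson regression with offset.

The trend model is ``log E[y_t] = b0 + b1 (t - t0) + log n_t`` for annual
death counts ``y_t`` and person-time ``n_t``; ``exp(b1)`` is the
per-annum incidence rate ratio (IRR).  The module also provides a
likelihood-ratio check of the Poisson equidispersion assumption against
a gamma-mixture (quadratic-variance) alternative, and a BIC-based
joinpoint scan that looks for a single change in slope as a sensitivity
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TrendResult",
    "JoinpointResult",
    "PoissonTrend",
    "fit_poisson_trend",
    "equidispersion_test",
    "joinpoint_scan",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class TrendResult:
    """Fitted annual trend: per-annum IRR with Wald CI and diagnostics."""

    irr: float
    ci95: tuple[float, float]
    p: float
    beta0: float
    beta1: float
    se_beta1: float
    deviance: float
    nobs: int
    dispersion_stat: float | None = None
    dispersion_p: float | None = None

    def summary(self) -> str:
        lines = [
            "Poisson annual trend",
            f"  IRR per annum  {self.irr:.4f}  (95% CI {self.ci95[0]:.4f}-{self.ci95[1]:.4f})",
            f"  Wald p         {self.p:.4g}",
            f"  deviance       {self.deviance:.3f} on {self.nobs - 2} df",
        ]
        if self.dispersion_p is not None:
            verdict = (
                "equidispersion not rejected"
                if self.dispersion_p > 0.05
                else "overdispersion detected"
            )
            lines.append(
                f"  equidispersion LR {self.dispersion_stat:.3f}, "
                f"p = {self.dispersion_p:.3g} ({verdict})"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class JoinpointResult:
    """Outcome of the single-joinpoint BIC scan."""

    n_joinpoints: int
    breakpoint_year: int | None
    segment_irrs: tuple[float, ...]
    selection_scores: Mapping[int, float]
    bic_no_joinpoint: float

    def summary(self) -> str:
        if self.n_joinpoints == 0:
            return (
                "Joinpoint scan: no slope change supported "
                f"(single-segment IRR {self.segment_irrs[0]:.4f})"
            )
        return (
            f"Joinpoint scan: slope change at {self.breakpoint_year}; segment IRRs "
            + ", ".join(f"{g:.4f}" for g in self.segment_irrs)
        )


def _validate(counts, person_time, years):
    y = np.asarray(counts, dtype=float)
    n = np.asarray(person_time, dtype=float)
    t = np.asarray(years, dtype=float)
    if not (y.shape == n.shape == t.shape) or y.ndim != 1:
        raise ValueError("counts, person_time and years must be equal-length 1-d")
    if y.size < 2:
        raise ValueError("need at least two years")
    if (n <= 0).any():
        raise ValueError("person_time must be positive")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if y.sum() == 0:
        raise ValueError("all counts are zero; trend undefined")
    if len(set(t)) != t.size:
        raise ValueError("years must be distinct")
    return y, n, t


class PoissonTrend:
    """Log-linear Poisson trend model for annual counts with an offset.

    The year covariate is centred at the first year for numerical
    stability; the IRR is invariant to the centring.
    """

    def __init__(self, counts: Sequence[float], person_time: Sequence[float],
                 years: Sequence[float]):
        self.counts, self.person_time, self.years = _validate(counts, person_time, years)

    def fit(self, dispersion: bool = True) -> TrendResult:
        y, n, t = self.counts, self.person_time, self.years
        X = sm.add_constant(t - t.min())
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(n)).fit(
            tol=1e-10, maxiter=200
        )
        if not res.converged:
            raise RuntimeError("Poisson trend fit did not converge")
        b0, b1 = res.params
        se1 = res.bse[1]
        disp_stat = disp_p = None
        if dispersion and y.size >= 3:
            disp_stat, disp_p = equidispersion_test(y, n, t)
        return TrendResult(
            irr=float(np.exp(b1)),
            ci95=(float(np.exp(b1 - _Z95 * se1)), float(np.exp(b1 + _Z95 * se1))),
            p=float(2.0 * stats.norm.sf(abs(b1 / se1))) if se1 > 0 else 1.0,
            beta0=float(b0),
            beta1=float(b1),
            se_beta1=float(se1),
            deviance=float(res.deviance),
            nobs=int(y.size),
            dispersion_stat=disp_stat,
            dispersion_p=disp_p,
        )


def fit_poisson_trend(
    counts: Sequence[float], person_time: Sequence[float], years: Sequence[float],
    dispersion: bool = True,
) -> TrendResult:
    """Convenience wrapper: ``PoissonTrend(...).fit()``."""
    return PoissonTrend(counts, person_time, years).fit(dispersion=dispersion)


def equidispersion_test(
    counts: Sequence[float], person_time: Sequence[float], years: Sequence[float]
) -> tuple[float, float]:
    """Likelihood-ratio test of Poisson equidispersion.

    Compares the Poisson trend model against a gamma-mixture count model
    with quadratic variance (negative binomial, one extra dispersion
    parameter).  Because the dispersion parameter sits on the boundary of
    its space under the null, the p-value uses the half-chi-square(1)
    mixture.  ``p > 0.05`` means equidispersion is not rejected.
    """
    y, n, t = _validate(counts, person_time, years)
    if y.size < 3:
        raise ValueError("equidispersion test needs at least three observations")
    X = sm.add_constant(t - t.min())
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(n)).fit(tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nb_model = sm.NegativeBinomial(y, X, exposure=n)
        start = np.append(pois.params, 0.01)
        try:
            nb = nb_model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        except Exception:
            nb = nb_model.fit(start_params=start, method="nm", maxiter=2000, disp=0)
    lr = max(0.0, 2.0 * (nb.llf - pois.llf))
    p = 0.5 * float(stats.chi2.sf(lr, 1))
    return float(lr), p


def joinpoint_scan(
    counts: Sequence[float],
    person_time: Sequence[float],
    years: Sequence[float],
    max_joinpoints: int = 1,
) -> JoinpointResult:
    """BIC scan for a single change in the log-linear slope.

    Fits, at every interior candidate year, a continuous piecewise
    log-linear Poisson model (a hinge term ``max(t - c, 0)`` added to the
    trend) and selects the candidate with the lowest BIC; zero joinpoints
    are reported when no candidate beats the single-segment model.  The
    BIC of a joinpoint model charges four parameters -- intercept, slope,
    slope change and the searched breakpoint location -- which keeps the
    scan from latching onto noise.  This is a sensitivity analysis, not
    the full permutation-test joinpoint procedure.
    """
    if max_joinpoints not in (0, 1):
        raise ValueError("max_joinpoints must be 0 or 1")
    y, n, t = _validate(counts, person_time, years)
    if y.size < 7:
        raise ValueError("joinpoint scan needs at least seven years")
    order = np.argsort(t)
    y, n, t = y[order], n[order], t[order]
    x = t - t.min()
    off = np.log(n)

    def _bic(res, k):
        return float(-2.0 * res.llf + k * np.log(y.size))

    base = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson(), offset=off).fit(
        tol=1e-10
    )
    bic0 = _bic(base, 2)
    scores: dict[int, float] = {}
    best_year, best_bic, best_params = None, np.inf, None
    if max_joinpoints == 1:
        # candidates leave at least three years in each segment
        for c in t[2:-3]:
            X = np.column_stack([np.ones_like(x), x, np.maximum(t - c, 0.0)])
            res = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit(tol=1e-10)
            bic = _bic(res, 4)
            scores[int(c)] = bic
            if bic < best_bic:
                best_year, best_bic, best_params = int(c), bic, res.params
    if best_year is not None and best_bic < bic0:
        b1, b2 = best_params[1], best_params[2]
        return JoinpointResult(
            n_joinpoints=1,
            breakpoint_year=best_year,
            segment_irrs=(float(np.exp(b1)), float(np.exp(b1 + b2))),
            selection_scores=scores,
            bic_no_joinpoint=bic0,
        )
    return JoinpointResult(
        n_joinpoints=0,
        breakpoint_year=None,
        segment_irrs=(float(np.exp(base.params[1])),),
        selection_scores=scores,
        bic_no_joinpoint=bic0,
    )
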