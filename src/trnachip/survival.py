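"""Survival screening: quartile Kaplan–Meier comparisons and Cox regression.

Each expression unit (a tRNA gene or family) is screened for association
with patient survival in two complementary ways, both after administrative
censoring of follow-up at a fixed horizon (5 years by default):

* a Kaplan–Meier comparison of the highest versus the lowest expression
  quartile, with a two-group log-rank test;
* a proportional-hazards fit with (standardized) expression as a continuous
  predictor, reporting the hazard ratio per SD, Wald p and 95% CI.

Kaplan–Meier, log-rank and the Efron-ties Cox fit are delegated to
lifelines; a compact single-covariate Newton solver with Breslow ties is
included for cross-checking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank

log = logging.getLogger(__name__)

_DAYS_PER_YEAR = 365.25
_UNIT_TO_YEARS = {"days": 1.0 / _DAYS_PER_YEAR, "months": 1.0 / 12.0, "years": 1.0}


@dataclass
class SurvivalTable:
    """Per-patient follow-up time and event status.

    ``frame`` is indexed by unique patient id with columns ``time`` (> 0, in
    ``time_unit``) and ``event`` (1 = death, 0 = censored).
    """

    frame: pd.DataFrame
    time_unit: Literal["days", "months", "years"] = "days"

    def __post_init__(self) -> None:
        required = {"time", "event"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"survival table needs columns {sorted(required)}")
        if self.frame.index.duplicated().any():
            raise ValueError("patient_ids must be unique")
        if (self.frame["time"] <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not self.frame["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")
        if self.time_unit not in _UNIT_TO_YEARS:
            raise ValueError(f"unknown time_unit {self.time_unit!r}")

    def horizon_in_unit(self, horizon_years: float) -> float:
        return horizon_years / _UNIT_TO_YEARS[self.time_unit]

    @classmethod
    def read_tsv(
        cls, path: str | Path, time_unit: Literal["days", "months", "years"] = "days"
    ) -> "SurvivalTable":
        frame = pd.read_csv(path, sep="\t").set_index("patient_id")
        return cls(frame=frame[["time", "event"]], time_unit=time_unit)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="patient_id")


def administrative_censor(
    times: np.ndarray, events: np.ndarray, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate follow-up at ``horizon``: later events become censored."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    beyond = times > horizon
    return np.where(beyond, horizon, times), np.where(beyond, 0, events)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray  # distinct death times, ascending
    survival: np.ndarray     # S(t) just after each death time
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t); 1.0 before the first death."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Censored subjects leave the risk set without producing a step. With no
    censoring the curve equals 1 − the empirical CDF of the event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_["KM_estimate"]
    death_times = np.unique(times[events == 1])
    surv = np.array([float(sf.loc[t]) for t in death_times])
    return KMCurve(
        event_times=death_times, survival=surv,
        n=int(times.size), n_events=int(events.sum()),
    )


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[int],
    times_b: Sequence[float], events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p.

    With zero events overall the statistic is undefined and ``(nan, nan)``
    is returned with a warning.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        log.warning("logrank_test: no events in either group; p undefined")
        return float("nan"), float("nan")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class KMComparison:
    unit: str
    cutpoints: tuple[float, float]          # (Q1, Q3) of expression
    n_low: int
    n_high: int
    statistic: float
    p: float
    curve_low: KMCurve | None
    curve_high: KMCurve | None
    horizon_years: float


def quartile_km_compare(
    expression: pd.Series,
    survival: SurvivalTable,
    horizon_years: float = 5.0,
    unit: str = "",
) -> KMComparison:
    """Compare survival of the top vs bottom expression quartile.

    Patients with expression <= Q1 form the low group and >= Q3 the high
    group (ties included on the closed side; the middle half is excluded).
    Follow-up is administratively censored at the horizon before the
    Kaplan–Meier curves and log-rank test are computed.
    """
    joined = survival.frame.join(expression.rename("expr"), how="inner").dropna(
        subset=["expr"]
    )
    if len(joined) < 8:
        raise ValueError(
            f"need >=8 patients with expression, got {len(joined)}"
        )
    q1, q3 = np.quantile(joined["expr"], [0.25, 0.75])
    if q1 == q3:
        raise ValueError("no quartile separation: Q1 equals Q3")
    low = joined[joined["expr"] <= q1]
    high = joined[joined["expr"] >= q3]
    horizon = survival.horizon_in_unit(horizon_years)
    t_lo, e_lo = administrative_censor(low["time"], low["event"], horizon)
    t_hi, e_hi = administrative_censor(high["time"], high["event"], horizon)
    if e_lo.sum() + e_hi.sum() == 0:
        log.warning("quartile_km_compare: no events before the horizon; p missing")
        stat, p = float("nan"), float("nan")
    else:
        stat, p = logrank_test(t_lo, e_lo, t_hi, e_hi)
    return KMComparison(
        unit=unit, cutpoints=(float(q1), float(q3)),
        n_low=len(low), n_high=len(high),
        statistic=stat, p=p,
        curve_low=km_curve(t_lo, e_lo), curve_high=km_curve(t_hi, e_hi),
        horizon_years=horizon_years,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class HazardScreenResult:
    unit: str
    hr: float
    beta: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    converged: bool = True
    note: str | None = None


def _cox_newton_breslow(
    x: np.ndarray, times: np.ndarray, events: np.ndarray,
    tol: float = 1e-8, max_iter: int = 50,
) -> tuple[float, float, bool]:
    """Single-covariate Cox partial-likelihood Newton solver, Breslow ties.

    Returns (beta, se, converged). Kept deliberately simple as an oracle for
    cross-checks against the Efron-ties fit.
    """
    order = np.argsort(times)
    x, times, events = x[order], times[order], events[order]
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        r = np.exp(beta * x)
        # reverse cumulative sums over the risk set (all with time >= t_i)
        s0 = np.cumsum(r[::-1])[::-1]
        s1 = np.cumsum((r * x)[::-1])[::-1]
        s2 = np.cumsum((r * x * x)[::-1])[::-1]
        # risk set at a death time includes all subjects with time >= it;
        # map each death to the first index of its tie group
        first = np.searchsorted(times, times, side="left")
        d = events == 1
        mean = s1[first[d]] / s0[first[d]]
        score = np.sum(x[d] - mean)
        info = np.sum(s2[first[d]] / s0[first[d]] - mean**2)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(step) < tol:
            converged = True
            break
    se = 1.0 / np.sqrt(info) if info > 0 else float("inf")
    return float(beta), float(se), converged


def cox_fit(
    expression: pd.Series,
    survival: SurvivalTable,
    ties: Literal["efron", "breslow"] = "efron",
    standardize: bool = True,
    horizon_years: float | None = None,
    unit: str = "",
) -> HazardScreenResult:
    """Proportional-hazards fit with expression as a continuous predictor.

    Expression is z-scored by default so the hazard ratio is per SD and
    comparable across units; pass ``standardize=False`` for the raw scale.
    A monotone partial likelihood (perfect separation) is returned as a
    flagged, non-converged result rather than an exception.
    """
    joined = survival.frame.join(expression.rename("expr"), how="inner").dropna(
        subset=["expr"]
    )
    if joined["event"].sum() < 1:
        raise ValueError("need at least one event")
    if joined["expr"].nunique() < 2:
        raise ValueError("expression does not vary")
    times = joined["time"].to_numpy(dtype=float)
    events = joined["event"].to_numpy(dtype=int)
    if horizon_years is not None:
        times, events = administrative_censor(
            times, events, survival.horizon_in_unit(horizon_years)
        )
        if events.sum() < 1:
            raise ValueError("no events before the horizon")
    x = joined["expr"].to_numpy(dtype=float)
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)

    if ties == "breslow":
        beta, se, converged = _cox_newton_breslow(x, times, events)
    elif ties == "efron":
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                cph.fit(df, duration_col="time", event_col="event")
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            beta = float(cph.params_["x"])
            se = float(cph.standard_errors_["x"])
        except ConvergenceError as exc:
            log.warning("cox_fit(%s): %s", unit or "<unit>", exc)
            return HazardScreenResult(
                unit=unit, hr=float("inf"), beta=float("inf"), se=float("inf"),
                p=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                n=len(joined), n_events=int(events.sum()),
                converged=False, note="monotone likelihood / non-convergence",
            )
    else:
        raise ValueError(f"unknown ties method {ties!r}")

    from scipy import stats as sps

    z = beta / se if se > 0 else float("inf")
    p = 2.0 * sps.norm.sf(abs(z))
    ci = 1.959963984540054 * se
    note = None
    if not converged:
        note = "convergence warning (possible monotone likelihood)"
        log.warning("cox_fit(%s): %s", unit or "<unit>", note)
    return HazardScreenResult(
        unit=unit, hr=float(np.exp(beta)), beta=beta, se=se, p=float(p),
        ci_low=float(np.exp(beta - ci)), ci_high=float(np.exp(beta + ci)),
        n=len(joined), n_events=int(events.sum()),
        converged=converged, note=note,
    )


def screen(
    expression: pd.DataFrame,
    survival: SurvivalTable,
    alpha: float = 0.05,
    horizon_years: float | None = 5.0,
    ties: Literal["efron", "breslow"] = "efron",
    standardize: bool = True,
) -> pd.DataFrame:
    """Cox screen over every unit (row) of an expression matrix.

    Each unit (gene or family; columns are patients) gets a single-covariate
    fit with administrative censoring at the horizon. Results are ordered by
    hazard ratio, descending. The ``significant`` flag uses the raw p at
    ``alpha`` (the primary criterion); a Benjamini–Hochberg q over the
    screened units is reported alongside. Per-unit failures are recorded in
    the ``error`` column and the screen continues.
    """
    from .heterogeneity import fdr_bh

    rows = []
    for unit in expression.index:
        expr = expression.loc[unit]
        expr.index = expression.columns
        try:
            res = cox_fit(
                expr, survival, ties=ties, standardize=standardize,
                horizon_years=horizon_years, unit=str(unit),
            )
            rows.append({
                "unit": str(unit), "hr": res.hr, "beta": res.beta, "se": res.se,
                "p": res.p, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "n": res.n, "n_events": res.n_events,
                "converged": res.converged, "error": None,
            })
        except ValueError as exc:
            log.warning("screen: unit %s skipped: %s", unit, exc)
            rows.append({
                "unit": str(unit), "hr": np.nan, "beta": np.nan, "se": np.nan,
                "p": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "n": 0, "n_events": 0, "converged": False, "error": str(exc),
            })
    columns = ["unit", "hr", "beta", "se", "p", "ci_low", "ci_high",
               "n", "n_events", "converged", "error"]
    table = pd.DataFrame(rows, columns=columns).set_index("unit")
    table["q"] = fdr_bh(table["p"].to_numpy())
    table["significant"] = table["p"] < alpha
    table["significant_bh"] = table["q"] < alpha
    return table.sort_values("hr", ascending=False)
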