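"""Survival statistics: Kaplan-Meier curves, log-rank tests, summaries and
power-law dose-response fits.

Death calls become a right-censored survival dataset (one row per animal:
time in hours, event flag, group label).  Curves are the standard
product-limit estimator; group differences use the two-group log-rank test.
Median lifespan across stressor concentrations is summarized by a power-law
model ``y = a * x^b`` fitted by least squares on the log-log scale (the
convention behind spreadsheet "power fit" trendlines), which supports
equivalent-dose inversion: the concentration at which the model predicts a
given median, and hence the relative sensitivity of a mutant versus its
control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .vitality import DeathCall

__all__ = [
    "SurvivalDataset",
    "SurvivalCurve",
    "DoseResponseFit",
    "LogRankResult",
    "km_curve",
    "log_rank",
    "summarize",
    "fit_power_law",
    "equivalent_dose",
    "relative_sensitivity",
]


@dataclass
class SurvivalDataset:
    """Right-censored survival data: per-subject time, event flag, group."""

    times: np.ndarray  # hours, > 0
    events: np.ndarray  # 1 = death observed, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if len(self.times) != len(self.events):
            raise ValueError("times and events must have equal length")
        if len(self.times) == 0:
            raise ValueError("survival dataset needs at least one subject")
        if np.any(self.times <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_death_calls(
        cls, calls: list[DeathCall], group: str = "", include_multi: bool = True
    ) -> "SurvivalDataset":
        """Build a dataset from vitality death calls.

        Excluded and empty arenas are dropped; multi-occupancy arenas are
        kept by default (their call marks the last resident's death) but can
        be dropped with ``include_multi=False``.
        """
        times, events = [], []
        for c in calls:
            if c.status not in ("dead", "censored"):
                continue
            if c.multi_occupancy and not include_multi:
                continue
            t = float(c.time_h)
            if t <= 0:  # death at the very first frame carries no duration
                t = 1e-6
            times.append(t)
            events.append(1 if c.status == "dead" else 0)
        if not times:
            raise ValueError("no scored arenas in death calls")
        return cls(np.array(times), np.array(events), group=group)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str = "") -> "SurvivalDataset":
        return cls(df["time_h"].to_numpy(), df["event"].to_numpy(), group=group)


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with risk-set bookkeeping."""

    times: np.ndarray  # distinct event times
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    median: float  # nan = not reached
    q25: float  # 25% mortality time (S <= 0.75)
    q75: float  # 75% mortality time (S <= 0.25)
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): fraction surviving beyond time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _quantile_time(times: np.ndarray, survival: np.ndarray, q: float) -> float:
    """Smallest event time with S(t) <= q, nan if never reached.

    No interpolation: hourly sampling would make interpolated quantiles
    false precision.
    """
    hit = np.nonzero(survival <= q + 1e-12)[0]
    return float(times[hit[0]]) if len(hit) else float("nan")


def km_curve(data: SurvivalDataset) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time t_i, ``S *= 1 - d_i / n_i`` with d_i deaths
    among n_i at risk; censored subjects leave the risk set after their
    censor time.  Median = smallest t with S(t) <= 0.5 (not reached when the
    curve never drops that far).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(data.times, event_observed=data.events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    deaths = event_rows["observed"].to_numpy(dtype=int)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    sf = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(sf.loc[t]) for t in times])
    return SurvivalCurve(
        times=times,
        at_risk=at_risk,
        deaths=deaths,
        survival=survival,
        median=_quantile_time(times, survival, 0.5),
        q25=_quantile_time(times, survival, 0.75),
        q75=_quantile_time(times, survival, 0.25),
        n=len(data),
    )


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int = 1


def log_rank(a: SurvivalDataset, b: SurvivalDataset) -> LogRankResult:
    """Two-group log-rank test (chi-square, 1 df).

    Identical groups give statistic 0 and p = 1; the statistic is symmetric
    in group order.
    """
    res = logrank_test(a.times, b.times, event_observed_A=a.events, event_observed_B=b.events)
    return LogRankResult(float(res.test_statistic), float(res.p_value), df=1)


def summarize(data: SurvivalDataset, lethality_at: list[float] | None = None) -> dict:
    """Summary statistics of a survival dataset.

    Mean and SEM are computed over observed death times only (the censored
    count is reported separately; no imputation is attempted — the result is
    flagged when censoring is present).  Median and quartiles come from the
    Kaplan-Meier curve.  Lethality at time t = deaths with time <= t over
    subjects still under observation at t or with an earlier event, which
    equals 1 - S(t) when no censoring precedes t.
    """
    curve = km_curve(data)
    event_times = data.times[data.events == 1]
    n_events = len(event_times)
    n_censored = len(data) - n_events
    if n_events:
        mean = float(event_times.mean())
        sem = float(event_times.std(ddof=1) / math.sqrt(n_events)) if n_events > 1 else float("nan")
    else:
        mean = sem = float("nan")
    summary = {
        "n": len(data),
        "n_events": n_events,
        "n_censored": n_censored,
        "mean_h": mean,
        "sem_h": sem,
        "mean_over_events_only": n_censored > 0,
        "median_h": curve.median,
        "q25_h": curve.q25,
        "q75_h": curve.q75,
        "lethality": {},
    }
    for t in lethality_at or []:
        died = int(np.sum((data.events == 1) & (data.times <= t)))
        under_obs = int(np.sum(data.times >= t) + np.sum((data.events == 1) & (data.times < t)))
        summary["lethality"][float(t)] = 100.0 * died / under_obs if under_obs else float("nan")
    return summary


@dataclass
class DoseResponseFit:
    """Power-law model ``median = a * dose^b`` on the log-log scale."""

    a: float  # hours; model median at unit dose
    b: float  # dimensionless exponent (negative: higher dose, faster death)
    r_squared: float
    doses: tuple[float, ...] = ()
    medians: tuple[float, ...] = ()

    def predict(self, dose: float) -> float:
        return self.a * dose**self.b


def fit_power_law(doses: list[float], medians: list[float]) -> DoseResponseFit:
    """Least-squares fit of ``ln(median) = ln(a) + b * ln(dose)``.

    This is the standard "power fit" trendline convention; the reported R²
    is that of the log-log regression.  Exact power-law inputs are
    reproduced to machine precision.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(medians, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least 2 dose/median pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("doses and medians must be strictly positive")
    lx, ly = np.log(x), np.log(y)
    b, ln_a = np.polyfit(lx, ly, 1)
    resid = ly - (ln_a + b * lx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    # numerically perfect fits (incl. a flat response) report R^2 = 1
    tiny = 1e-14 * len(ly) * max(1.0, float(np.abs(ly).max())) ** 2
    r2 = 1.0 if ss_res <= tiny else 1.0 - ss_res / ss_tot
    return DoseResponseFit(
        a=float(np.exp(ln_a)),
        b=float(b),
        r_squared=r2,
        doses=tuple(float(v) for v in x),
        medians=tuple(float(v) for v in y),
    )


def equivalent_dose(fit: DoseResponseFit, observed_median: float) -> float:
    """Dose at which the model's median equals ``observed_median``:
    ``x = (y / a) ** (1 / b)``."""
    if fit.b == 0:
        raise ValueError("equivalent dose undefined for a flat dose-response (b = 0)")
    if observed_median <= 0:
        raise ValueError("observed median must be positive")
    return (observed_median / fit.a) ** (1.0 / fit.b)


def relative_sensitivity(
    fit: DoseResponseFit, actual_dose: float, observed_median: float
) -> float:
    """Percent extra effective dose: how much more stressor the control
    would need to match the observed response.

    ``100 * (equivalent_dose / actual_dose - 1)``; e.g. a mutant whose
    median at 0.25 mM matches the control model at 0.413 mM is ~65% more
    sensitive.
    """
    if actual_dose <= 0:
        raise ValueError("actual_dose must be positive")
    return 100.0 * (equivalent_dose(fit, observed_median) / actual_dose - 1.0)
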