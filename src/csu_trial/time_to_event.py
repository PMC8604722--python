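"""Kaplan-Meier estimation for time-to-MID endpoints.

Event times are in weeks (the first week a patient's UAS7 reduction reaches
the minimally important difference); patients who never reach it are censored
at their last validly-scored on-treatment week.  The product-limit curve is
computed with lifelines; the median uses the inclusive convention (smallest
time with survival <= 0.5), with the midpoint convention at an exact-0.5
plateau: if the curve sits exactly at 0.5 from t1 until the next drop at t2,
the median is reported as (t1 + t2) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["KmCurve", "km_fit", "km_median"]


@dataclass
class KmCurve:
    """Product-limit estimate on the event-time grid."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    n_events: np.ndarray
    median: float              # NaN when survival never reaches 0.5

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
        return s


def km_fit(times, events) -> KmCurve:
    """Kaplan-Meier product-limit fit of (time, event-indicator) records.

    Ties are handled with events preceding censorings at the same time (the
    standard convention).  Raises on empty input.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no time-to-event records")
    if (t <= 0).any():
        raise ValueError("event/censoring times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    grid = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    curve = KmCurve(
        times=grid,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        n_events=ev["observed"].to_numpy(dtype=float),
        median=np.nan,
    )
    curve.median = km_median(curve)
    return curve


def km_median(curve: KmCurve) -> float:
    """Median survival time: smallest t with S(t) <= 0.5 (inclusive), using
    the midpoint of an exact-0.5 plateau; NaN if survival stays above 0.5."""
    at_half = np.isclose(curve.survival, 0.5, rtol=1e-9, atol=1e-12)
    below = np.flatnonzero((curve.survival < 0.5) | at_half)
    if below.size == 0:
        return float("nan")
    i = below[0]
    if at_half[i] and i + 1 < len(curve.times):
        return float((curve.times[i] + curve.times[i + 1]) / 2.0)
    return float(curve.times[i])


def km_by_group(records: pd.DataFrame, group_col: str = "arm") -> pd.DataFrame:
    """Fit one curve per group of a (time_weeks, event, group) table; returns
    a tidy summary with per-group median times."""
    rows = []
    for g, grp in records.groupby(group_col, sort=True):
        curve = km_fit(grp["time_weeks"], grp["event"])
        rows.append(
            {group_col: g, "n": len(grp), "events": int(grp["event"].sum()),
             "median_weeks": curve.median}
        )
    return pd.DataFrame(rows)
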