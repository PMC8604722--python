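"""Diary-based endpoint derivation: daily UAS, UAS7, responders, time-to-MID.

The urticaria activity score (UAS) is a twice-daily patient-reported composite
of itch severity (0-3) and hive count severity (0-3).  The daily UAS is the
average of the morning and evening session sums (0-6); the UAS7 is the 7-day
weekly sum (0-42).  Weekly itch and hive scores (0-21 each) are derived the
same way from the individual components, so UAS7 = itch7 + hive7 exactly.

Scoring conventions where the instrument leaves room:

* If exactly one of the two daily sessions was recorded, that session's sum is
  the daily score; if neither, the day is missing.
* A week is valid when at least ``min_days`` (default 4) days were observed;
  the weekly sum is prorated by ``7 / days_observed`` and rounded to one
  decimal, applied to the itch and hive sums separately so the decomposition
  stays exact.
* Week 0 is the baseline week: the 7 calendar days ending on day 0 (the day
  before the first dose).  Week w >= 1 covers study days 7(w-1)+1 .. 7w, so
  week 8 ends on the last dosing day (day 56).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "score_daily_uas",
    "daily_scores",
    "derive_weekly_scores",
    "change_from_baseline",
    "classify_responders",
    "time_to_mid_series",
    "rescue_free_fraction",
    "MIN_DAYS_PER_WEEK",
]

MIN_DAYS_PER_WEEK = 4


def _check_score(v, name: str) -> None:
    if v not in (0, 1, 2, 3):
        raise ValueError(f"{name} score must be in {{0,1,2,3}}, got {v!r}")


def score_daily_uas(sessions: list[tuple[int, int]]) -> float | None:
    """Daily UAS (0-6) from up to two (itch, hive) session records.

    Both sessions present -> mean of the two session sums; one present ->
    that session's sum; none -> ``None`` (missing day).
    """
    if len(sessions) > 2:
        raise ValueError(f"at most 2 sessions per day, got {len(sessions)}")
    sums = []
    for itch, hive in sessions:
        _check_score(itch, "itch")
        _check_score(hive, "hive")
        sums.append(itch + hive)
    if not sums:
        return None
    return float(np.mean(sums))


def daily_scores(diary: pd.DataFrame) -> pd.DataFrame:
    """Per patient-day itch/hive/UAS daily scores from the long diary table.

    Missing sessions (``missing`` flag or NA scores) are excluded; a day with
    no usable session gets NA scores.  Returns columns patient_id, study_day,
    itch_daily, hive_daily, uas_daily, sessions_observed.
    """
    d = diary.copy()
    usable = ~(d["missing"].astype(bool) | d["itch"].isna() | d["hive"].isna())
    d = d.loc[usable]
    if d.empty:
        return pd.DataFrame(
            columns=["patient_id", "study_day", "itch_daily", "hive_daily",
                     "uas_daily", "sessions_observed"]
        )
    bad = ~(d["itch"].isin([0, 1, 2, 3]) & d["hive"].isin([0, 1, 2, 3]))
    if bad.any():
        row = d.loc[bad].iloc[0]
        raise ValueError(
            f"session scores outside 0..3 for patient {row['patient_id']} "
            f"day {row['study_day']}"
        )
    g = d.groupby(["patient_id", "study_day"], sort=True)
    out = g.agg(
        itch_daily=("itch", "mean"),
        hive_daily=("hive", "mean"),
        sessions_observed=("itch", "size"),
    ).reset_index()
    out["uas_daily"] = out["itch_daily"] + out["hive_daily"]
    return out


def _week_of_day(day: np.ndarray) -> np.ndarray:
    """Week index: days -6..0 -> 0 (baseline); days 7(w-1)+1..7w -> w."""
    return np.where(day <= 0, 0, (day + 6) // 7).astype(int)


def _prorate(total: float, days: int) -> float:
    return round(total * 7.0 / days, 1)


def derive_weekly_scores(
    diary: pd.DataFrame, min_days: int = MIN_DAYS_PER_WEEK, max_week: int | None = None
) -> pd.DataFrame:
    """Weekly UAS7 / itch7 / hive7 per patient-week with observed-day counts.

    Weeks with fewer than ``min_days`` observed days are kept but flagged
    ``valid = False`` with NA scores.  ``uas7 = itch7 + hive7`` exactly.
    """
    ds = daily_scores(diary)
    if ds.empty:
        return pd.DataFrame(
            columns=["patient_id", "week", "uas7", "itch7", "hive7",
                     "days_observed", "valid"]
        )
    ds = ds[ds["study_day"] >= -6]
    ds["week"] = _week_of_day(ds["study_day"].to_numpy())
    if max_week is not None:
        ds = ds[ds["week"] <= max_week]
    g = ds.groupby(["patient_id", "week"], sort=True)
    agg = g.agg(
        itch_sum=("itch_daily", "sum"),
        hive_sum=("hive_daily", "sum"),
        days_observed=("uas_daily", "size"),
    ).reset_index()
    valid = agg["days_observed"] >= min_days
    itch7 = np.array(
        [_prorate(s, d) if ok else np.nan
         for s, d, ok in zip(agg["itch_sum"], agg["days_observed"], valid)]
    )
    hive7 = np.array(
        [_prorate(s, d) if ok else np.nan
         for s, d, ok in zip(agg["hive_sum"], agg["days_observed"], valid)]
    )
    return pd.DataFrame(
        {
            "patient_id": agg["patient_id"],
            "week": agg["week"],
            "uas7": itch7 + hive7,
            "itch7": itch7,
            "hive7": hive7,
            "days_observed": agg["days_observed"],
            "valid": valid.to_numpy(),
        }
    )


def change_from_baseline(
    weekly: pd.DataFrame, scores: tuple[str, ...] = ("uas7", "itch7", "hive7")
) -> tuple[pd.DataFrame, list[str]]:
    """Per-week change from the baseline week (week 0) for each score.

    Patients without a valid baseline week are excluded from the change
    table; their ids are returned as the exclusion log.
    """
    base = weekly[(weekly["week"] == 0) & weekly["valid"]]
    base = base.set_index("patient_id")[list(scores)]
    excluded = sorted(set(weekly["patient_id"]) - set(base.index))
    w = weekly[weekly["patient_id"].isin(base.index)].copy()
    for s in scores:
        w[f"{s}_change"] = w[s] - w["patient_id"].map(base[s])
    return w, excluded


def classify_responders(
    changes: pd.DataFrame,
    dropout_day: pd.Series | dict | None = None,
    mid_uas7: float = 11.0,
) -> pd.DataFrame:
    """Responder flags per patient-week with the nonresponder rule applied.

    well_controlled: UAS7 <= 6; complete_response: UAS7 = 0; mid_uas7:
    reduction from baseline >= ``mid_uas7`` points.  Patients who discontinued
    treatment before completing a week's window (dropout day < 7w) count as
    nonresponders at that week regardless of any observed scores, and weeks
    without a valid score are nonresponder weeks as well.
    """
    w = changes[changes["week"] > 0].copy()
    if dropout_day is None:
        dd = pd.Series(np.nan, index=w.index)
    else:
        dd = w["patient_id"].map(dict(dropout_day) if not isinstance(dropout_day, pd.Series) else dropout_day)
    dd = pd.to_numeric(dd, errors="coerce").to_numpy(dtype=float)
    disc = ~np.isnan(dd) & (dd < 7 * w["week"].to_numpy())
    scored = w["valid"].to_numpy() & ~w["uas7"].isna().to_numpy()
    ok = scored & ~disc
    uas7 = w["uas7"].to_numpy(dtype=float)
    red = -w["uas7_change"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "patient_id": w["patient_id"].to_numpy(),
            "week": w["week"].to_numpy(),
            "well_controlled": ok & (uas7 <= 6.0),
            "complete_response": ok & (uas7 == 0.0),
            "mid_uas7": ok & (red >= mid_uas7),
            "discontinued_before_week": disc,
        }
    )


def time_to_mid_series(
    weekly_changes: pd.DataFrame,
    mid: float = 11.0,
    last_week: int = 8,
    score: str = "uas7_change",
) -> pd.DataFrame:
    """First week each patient reaches the MID reduction; censored otherwise.

    The event time is the first on-treatment week (1..last_week) whose
    reduction from baseline is >= ``mid``.  Patients who never reach it are
    censored at their last validly-scored on-treatment week (follow-up weeks
    beyond ``last_week`` do not contribute).  Returns columns patient_id,
    time_weeks, event.
    """
    rows = []
    w = weekly_changes[
        (weekly_changes["week"] >= 1) & (weekly_changes["week"] <= last_week)
    ]
    for pid, grp in w.groupby("patient_id", sort=True):
        grp = grp.sort_values("week")
        valid = grp[grp["valid"] & grp[score].notna()]
        if valid.empty:
            continue
        hit = valid[-valid[score] >= mid]
        if len(hit):
            rows.append({"patient_id": pid, "time_weeks": int(hit["week"].iloc[0]),
                         "event": True})
        else:
            rows.append({"patient_id": pid, "time_weeks": int(valid["week"].iloc[-1]),
                         "event": False})
    return pd.DataFrame(rows, columns=["patient_id", "time_weeks", "event"])


def rescue_free_fraction(diary: pd.DataFrame, week: int | None = None) -> pd.Series:
    """Per-patient fraction of observed diary days with no rescue medication."""
    d = diary[~diary["missing"].astype(bool) & diary["rescue"].notna()].copy()
    if week is not None:
        d = d[_week_of_day(d["study_day"].to_numpy()) == week]
    day_used = (
        d.groupby(["patient_id", "study_day"])["rescue"]
        .apply(lambda s: bool(s.astype(bool).any()))
    )
    return 1.0 - day_used.groupby("patient_id").mean()
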