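"""Ground-truth outcome variables: ALSFRS progression slope and censored survival.

Progression is the slope of the total ALSFRS (or ALSFRS-R) score between the
first and last in-window records, in points per month, with days converted to
months as ``t_months = t_days / 365 * 12``.  Survival is time until death or
tracheostomy; subjects with no event are censored at their last clinic visit,
and subjects whose final record falls on or before day 90 are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import ClinicalTable, OUTCOME_WINDOW, TimeWindow, ValidationError, window

__all__ = [
    "SlopeOutcome",
    "SurvivalOutcome",
    "DegenerateInputError",
    "alsfrs_slope",
    "survival_outcome",
    "slope_table",
    "survival_table",
    "days_for_months",
    "write_slope_outcomes",
    "write_survival_outcomes",
    "read_slope_outcomes",
    "read_survival_outcomes",
]

SURVIVAL_EXCLUSION_DAY = 90


class DegenerateInputError(ValueError):
    """Distinct values at a single time point make the slope undefined."""


@dataclass(frozen=True)
class SlopeOutcome:
    subject_id: str
    slope: float  # ALSFRS points per month, typically negative


@dataclass(frozen=True)
class SurvivalOutcome:
    subject_id: str
    time_days: int
    event: bool  # True = death or tracheostomy; False = censored at last visit


def days_for_months(months: float) -> int:
    """Day cutoff for a month horizon on the 365-day-year convention."""
    return round(months / 12 * 365)


def _months(days: float) -> float:
    return days / 365 * 12


def alsfrs_slope(
    table: ClinicalTable,
    subject: str,
    frs_feature: str,
    time_window: TimeWindow = OUTCOME_WINDOW,
) -> SlopeOutcome | None:
    """Progression slope in points/month, or ``None`` with <2 in-window records.

    ``t1`` is the earliest and ``t2`` the latest in-window record day; when
    several records share that day their mean value is used.  Two records on
    the same day with different values (so ``t1 == t2``) are a degenerate
    input.
    """
    recs = window(table, time_window, subject, frs_feature)
    if len(recs) < 2:
        return None
    days = [d for d, _ in recs]
    values = [float(v) for _, v in recs]
    t1, t2 = days[0], days[-1]
    if t1 == t2:
        if len(set(values)) > 1:
            raise DegenerateInputError(
                f"subject {subject}: conflicting {frs_feature} values at day {t1}"
            )
        return None  # a single effective time point
    v1 = sum(v for d, v in zip(days, values) if d == t1) / days.count(t1)
    v2 = sum(v for d, v in zip(days, values) if d == t2) / days.count(t2)
    return SlopeOutcome(subject, (v2 - v1) / _months(t2 - t1))


def survival_outcome(
    table: ClinicalTable,
    subject: str,
    death_feature: str = "death_days",
) -> SurvivalOutcome | None:
    """Survival time and event status, or ``None`` if the subject is excluded.

    Records of ``death_feature`` carry the death/tracheostomy day in their
    value column.  Without such a record the subject is censored at the last
    visit day.  Subjects whose final record is on or before day 90 (and any
    outcome time not exceeding day 90) are excluded.
    """
    df = table.for_subject(subject)
    if df.empty:
        return None
    death_rows = df[df["feature_name"] == death_feature]
    other = df[df["feature_name"] != death_feature]
    first_day = int(df["delta_days"].min())
    if death_rows.empty:
        if other.empty:
            return None
        time_days, event = int(other["delta_days"].max()), False
    else:
        death_day = int(float(death_rows["value"].iloc[0]))
        if death_day < first_day:
            raise ValidationError(
                f"subject {subject}: death day {death_day} precedes first record day {first_day}"
            )
        time_days, event = death_day, True
    final_record_day = int(df["delta_days"].max())
    if final_record_day <= SURVIVAL_EXCLUSION_DAY or time_days <= SURVIVAL_EXCLUSION_DAY:
        return None
    return SurvivalOutcome(subject, time_days, event)


def slope_table(
    table: ClinicalTable,
    frs_feature: str,
    time_window: TimeWindow = OUTCOME_WINDOW,
) -> pd.DataFrame:
    """Slope outcomes for every eligible subject, as ``subject_id,slope``."""
    rows = []
    for subject in table.subjects():
        out = alsfrs_slope(table, subject, frs_feature, time_window)
        if out is not None:
            rows.append({"subject_id": out.subject_id, "slope": out.slope})
    return pd.DataFrame(rows, columns=["subject_id", "slope"])


def survival_table(table: ClinicalTable, death_feature: str = "death_days") -> pd.DataFrame:
    """Survival outcomes for every non-excluded subject."""
    rows = []
    for subject in table.subjects():
        out = survival_outcome(table, subject, death_feature)
        if out is not None:
            rows.append(
                {"subject_id": out.subject_id, "time_days": out.time_days, "event": out.event}
            )
    return pd.DataFrame(rows, columns=["subject_id", "time_days", "event"])


def write_slope_outcomes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_survival_outcomes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, index=False)


def read_slope_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return df[["subject_id", "slope"]]


def read_survival_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    df["event"] = df["event"].astype(bool)
    return df[["subject_id", "time_days", "event"]]
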