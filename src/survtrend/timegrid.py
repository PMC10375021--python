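"""Canonical time identifiers for the surveillance time series.

Interviews are indexed on two grids:

* ISO-8601 calendar weeks (``"YYYY-Www"``, week-based year), and
* monthly periods running from the middle of one calendar month to the
  middle of the following one, matching the field periods of the telephone
  surveys the pipeline was built for.

Both grids carry continuous integer counters measured from the start of the
series.  The counters count *calendar* units, so gaps in data collection are
preserved on the axis: a smoother fitted on ``week_index`` sees true elapsed
time, not observed-interview order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MonthPeriod",
    "TimeAxis",
    "iso_week_label",
    "iso_week_start",
    "month_period_of",
    "build_time_axis",
]

#: Day of month on which a new monthly period opens (half-open convention:
#: the boundary day belongs to the *new* period).  Configurable per call.
DEFAULT_BOUNDARY_DAY = 15


@dataclass(frozen=True)
class MonthPeriod:
    """One mid-month-to-mid-month period.

    ``index`` is an absolute month ordinal (``year*12 + month-1``); the
    series-relative counter is assigned by :func:`build_time_axis`.
    """

    index: int
    label: str
    start_date: dt.date
    end_date: dt.date

    def __contains__(self, d: dt.date) -> bool:
        return self.start_date <= d <= self.end_date


@dataclass
class TimeAxis:
    """Gap-aware week/month counters spanning the whole observed series."""

    start_date: dt.date
    end_date: dt.date
    week_labels: list[str]
    week_index: dict[str, int]
    month_labels: list[str] = field(default_factory=list)
    month_index: dict[str, int] = field(default_factory=dict)
    boundary_day: int = DEFAULT_BOUNDARY_DAY

    def __len__(self) -> int:
        return len(self.week_labels)


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    if isinstance(d, str):
        try:
            return dt.date.fromisoformat(d)
        except ValueError as exc:
            raise ValueError(f"invalid ISO date string: {d!r}") from exc
    if isinstance(d, pd.Timestamp):
        return d.date()
    raise TypeError(f"cannot interpret {d!r} as a calendar date")


def iso_week_label(date) -> str:
    """ISO-8601 calendar-week label ``"YYYY-Www"``.

    The year component is the ISO *week-based* year, which differs from the
    calendar year for up to three days around New Year (e.g. 2021-01-01 lies
    in week 53 of 2020).
    """
    d = _as_date(date)
    year, week, _ = d.isocalendar()
    return f"{year}-W{week:02d}"


def iso_week_start(date) -> dt.date:
    """Monday of the ISO week containing ``date``."""
    d = _as_date(date)
    return d - dt.timedelta(days=d.isoweekday() - 1)


def month_period_of(date, boundary_day: int = DEFAULT_BOUNDARY_DAY) -> MonthPeriod:
    """Map a date to its mid-month-to-mid-month period.

    Dates on or after ``boundary_day`` of month *m* open period *m*; earlier
    dates still belong to period *m-1*.  The period labelled ``"YYYY-MM"``
    therefore runs ``[YYYY-MM-boundary_day, next month boundary_day)``.
    """
    if not 1 <= boundary_day <= 28:
        raise ValueError("boundary_day must be in 1..28")
    d = _as_date(date)
    year, month = d.year, d.month
    if d.day < boundary_day:
        month -= 1
        if month == 0:
            month, year = 12, year - 1
    start = dt.date(year, month, boundary_day)
    nyear, nmonth = (year, month + 1) if month < 12 else (year + 1, 1)
    end = dt.date(nyear, nmonth, boundary_day) - dt.timedelta(days=1)
    return MonthPeriod(
        index=year * 12 + (month - 1),
        label=f"{year}-{month:02d}",
        start_date=start,
        end_date=end,
    )


def period_from_label(label: str, boundary_day: int = DEFAULT_BOUNDARY_DAY) -> MonthPeriod:
    """Period object for a ``"YYYY-MM"`` label."""
    year, month = (int(p) for p in label.split("-"))
    return month_period_of(dt.date(year, month, boundary_day), boundary_day)


def build_time_axis(records: pd.DataFrame, date_col: str = "interview_date",
                    boundary_day: int = DEFAULT_BOUNDARY_DAY) -> TimeAxis:
    """Construct the calendar-based week/month axis spanning all records.

    Counters include calendar units with zero observations, so data gaps do
    not compress the axis.
    """
    if records.empty:
        raise ValueError("cannot build a time axis from an empty record table")
    dates = pd.to_datetime(records[date_col]).dt.date
    if dates.isna().any():
        raise ValueError("records contain invalid interview dates")
    dmin, dmax = min(dates), max(dates)

    w0 = iso_week_start(dmin)
    n_weeks = (iso_week_start(dmax) - w0).days // 7 + 1
    week_labels = [iso_week_label(w0 + dt.timedelta(weeks=i)) for i in range(n_weeks)]
    week_index = {lab: i for i, lab in enumerate(week_labels)}

    p0 = month_period_of(dmin, boundary_day)
    p1 = month_period_of(dmax, boundary_day)
    month_labels, month_index = [], {}
    for i in range(p1.index - p0.index + 1):
        ordinal = p0.index + i
        lab = f"{ordinal // 12}-{ordinal % 12 + 1:02d}"
        month_labels.append(lab)
        month_index[lab] = i
    return TimeAxis(
        start_date=dmin,
        end_date=dmax,
        week_labels=week_labels,
        week_index=week_index,
        month_labels=month_labels,
        month_index=month_index,
        boundary_day=boundary_day,
    )


def annotate_time(records: pd.DataFrame, axis: TimeAxis | None = None,
                  date_col: str = "interview_date") -> tuple[pd.DataFrame, TimeAxis]:
    """Add week/month label and counter columns to a record table.

    Returns a copy of ``records`` with columns ``week_label``, ``week_index``,
    ``month_label``, ``month_index`` plus the axis used.
    """
    if axis is None:
        axis = build_time_axis(records, date_col=date_col)
    out = records.copy()
    dates = pd.to_datetime(out[date_col]).dt.date
    out["week_label"] = [iso_week_label(d) for d in dates]
    w0 = iso_week_start(axis.start_date)
    out["week_index"] = [(iso_week_start(d) - w0).days // 7 for d in dates]
    p0_index = month_period_of(axis.start_date, axis.boundary_day).index
    periods = [month_period_of(d, axis.boundary_day) for d in dates]
    out["month_label"] = [p.label for p in periods]
    out["month_index"] = [p.index - p0_index for p in periods]
    return out, axis
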