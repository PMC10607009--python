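"""Hitting-ratio verification of daily migration predictions.

Each trap site has, for every day of the evaluation period (May of the survey
years), a daily prediction row ("yes, moths arrive", with a source label and
flight time FT, or "no") and a pheromone-trap catch series. Because a male
moth may take several days after physical arrival to find a lure, a positive
prediction is verified against a multi-day window:

* positive case — the prediction on a row date is a hit when at least one
  catch is recorded in a window of L consecutive days (L = 3 or 5) starting
  at the predicted arrival; otherwise it fails;
* negative case — a day with no prediction is a hit when no catch is
  recorded on that date, evaluated on the single day only; days falling
  within L days after any positive prediction row are excluded, because
  catches there may stem from the earlier predicted immigration (a negative
  bias guard);
* hitting ratio = hits / (hits + fails) over the evaluated days.

The predicted-arrival instant of a row dated d (JST) is the take-off of the
previous evening (10:00 UTC = 19:00 JST on d-1) plus FT hours. The window
starts on the arrival's JST date when the moths arrive before noon, else on
the following date: a moth arriving in the afternoon or evening flies its
first full night at the site too late to reach the trap before the next
collection morning.

Catch collections are daily or at 2-5-day intervals. A catch is recorded
*on its collection date*; a zero count certifies that every day its interval
covers is catch-free; interval coverage of either sign marks days as having
data at all. Windows truncated by the end of the data are evaluated on the
available days; a positive-case window with no data at all is unevaluable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "UnevaluableError",
    "DayClassification",
    "arrival_instant_jst",
    "arrival_window_start",
    "classify_positive_day",
    "classify_negative_day",
    "classify_days",
    "site_hitting_ratio",
    "aggregate_ratios",
    "evaluation_report",
    "load_predictions",
    "load_catches",
    "round2",
]

TAKEOFF_UTC_HOUR = 10
JST_UTC_OFFSET_H = 9
NOON_CUTOFF_H = 12


class UnevaluableError(ValueError):
    """A positive-prediction window overlaps no catch data at all."""


@dataclass(frozen=True)
class DayClassification:
    site: str
    date: dt.date
    case: str       # 'positive' | 'negative'
    category: str   # 'hit' | 'fail' | 'excluded'
    reason: str = ""  # 'shadowed' or 'no_data' for exclusions
    window_start: dt.date | None = None

    @property
    def mark(self) -> str:
        return {"hit": "H", "fail": "F", "excluded": "-"}[self.category]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (0.765 -> 0.77)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def arrival_instant_jst(row_date: dt.date, ft_h: float) -> dt.datetime:
    """Predicted arrival (JST) for a prediction row dated ``row_date``:
    take-off 10:00 UTC (19:00 JST) the previous evening plus FT hours."""
    takeoff_jst = dt.datetime.combine(
        row_date - dt.timedelta(days=1),
        dt.time(TAKEOFF_UTC_HOUR + JST_UTC_OFFSET_H, 0),
    )
    return takeoff_jst + dt.timedelta(hours=float(ft_h))


def arrival_window_start(arrival_jst: dt.datetime, cutoff_hour: int = NOON_CUTOFF_H) -> dt.date:
    """Evaluation-window start date: the arrival's JST date for arrivals
    before ``cutoff_hour`` (noon), else the following date."""
    tod = (arrival_jst.hour, arrival_jst.minute, arrival_jst.second, arrival_jst.microsecond)
    if tod < (cutoff_hour, 0, 0, 0):
        return arrival_jst.date()
    return arrival_jst.date() + dt.timedelta(days=1)


class _CatchCalendar:
    """Per-day catch status derived from (collection_date, count, interval_days).

    ``caught(d)``   — a collection dated d has count > 0
    ``has_data(d)`` — some collection's covered interval contains d
    """

    def __init__(self, catches: pd.DataFrame):
        self._caught: set[dt.date] = set()
        self._covered: set[dt.date] = set()
        intervals = []
        for _, row in catches.iterrows():
            date = _as_date(row["collection_date"])
            count = int(row["count"])
            span = int(row.get("interval_days", 1) or 1)
            if count < 0 or span < 1:
                raise ValueError("catch counts must be >= 0 and interval_days >= 1")
            days = [date - dt.timedelta(days=i) for i in range(span)]
            intervals.append(set(days))
            self._covered.update(days)
            if count > 0:
                self._caught.add(date)
        for i, a in enumerate(intervals):
            for b in intervals[i + 1:]:
                if a & b:
                    raise ValueError("catch collection intervals overlap")

    def caught(self, d: dt.date) -> bool:
        return d in self._caught

    def has_data(self, d: dt.date) -> bool:
        return d in self._covered


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def classify_positive_day(
    row_date: dt.date,
    ft_h: float,
    catches: "_CatchCalendar | pd.DataFrame",
    window_len: int,
    cutoff_hour: int = NOON_CUTOFF_H,
) -> tuple[str, dt.date]:
    """Hit/fail for a positive prediction row; returns (category, window_start)."""
    cal = catches if isinstance(catches, _CatchCalendar) else _CatchCalendar(catches)
    start = arrival_window_start(arrival_instant_jst(row_date, ft_h), cutoff_hour)
    days = [start + dt.timedelta(days=i) for i in range(window_len)]
    with_data = [d for d in days if cal.has_data(d)]
    if not with_data:
        raise UnevaluableError(
            f"no catch data overlaps the {window_len}-day window starting {start}"
        )
    hit = any(cal.caught(d) for d in days)
    return ("hit" if hit else "fail"), start


def classify_negative_day(
    date: dt.date,
    positive_row_dates,
    catches: "_CatchCalendar | pd.DataFrame",
    window_len: int,
) -> str:
    """Hit/fail/excluded for a day with no prediction.

    Excluded when the date lies within [p, p + L - 1] of any positive row
    date p (immigrants from that earlier predicted arrival could still be
    trapped); also excluded when no collection covers the date at all.
    """
    cal = catches if isinstance(catches, _CatchCalendar) else _CatchCalendar(catches)
    for p in positive_row_dates:
        p = _as_date(p)
        if p <= date <= p + dt.timedelta(days=window_len - 1):
            return "excluded"
    if not cal.has_data(date):
        return "excluded"
    return "hit" if not cal.caught(date) else "fail"


def classify_days(
    predictions: pd.DataFrame,
    catches: pd.DataFrame,
    window_len: int,
    site: str = "",
    cutoff_hour: int = NOON_CUTOFF_H,
) -> list[DayClassification]:
    """Classify every prediction row of one site for one window length.

    ``predictions`` columns: date, predicted (bool or Y/N), source, ft_h.
    ``catches`` columns: collection_date, count, interval_days.
    """
    cal = _CatchCalendar(catches)
    preds = predictions.copy()
    preds["date"] = preds["date"].map(_as_date)
    preds["predicted"] = preds["predicted"].map(
        lambda v: v if isinstance(v, (bool, np.bool_)) else str(v).strip().upper() in ("Y", "YES", "TRUE", "1")
    )
    positive_dates = [r["date"] for _, r in preds.iterrows() if r["predicted"]]

    out = []
    for _, row in preds.sort_values("date").iterrows():
        date = row["date"]
        if row["predicted"]:
            category, start = classify_positive_day(
                date, float(row["ft_h"]), cal, window_len, cutoff_hour
            )
            out.append(DayClassification(site, date, "positive", category,
                                         window_start=start))
        else:
            category = classify_negative_day(date, positive_dates, cal, window_len)
            reason = ""
            if category == "excluded":
                shadowed = any(
                    p <= date <= p + dt.timedelta(days=window_len - 1)
                    for p in positive_dates
                )
                reason = "shadowed" if shadowed else "no_data"
            out.append(DayClassification(site, date, "negative", category, reason))
    return out


def site_hitting_ratio(classifications: list[DayClassification]) -> float:
    """hits / (hits + fails), half-up-rounded to 2 decimals."""
    hits = sum(1 for c in classifications if c.category == "hit")
    fails = sum(1 for c in classifications if c.category == "fail")
    if hits + fails == 0:
        raise ValueError("no evaluated days (all excluded)")
    return round2(hits / (hits + fails))


def aggregate_ratios(ratios) -> float:
    """Arithmetic mean of per-site ratios, half-up-rounded to 2 decimals."""
    ratios = list(ratios)
    if not ratios:
        raise ValueError("no ratios to aggregate")
    return round2(sum(ratios) / len(ratios))


def evaluation_report(
    site_data: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    window_lens=(3, 5),
    cutoff_hour: int = NOON_CUTOFF_H,
) -> pd.DataFrame:
    """Per-site, per-window summary: hits, fails, evaluated days and ratio.

    ``site_data`` maps site name -> (predictions, catches) frames.
    """
    rows = []
    for site, (preds, catches) in site_data.items():
        for L in window_lens:
            cls = classify_days(preds, catches, L, site=site, cutoff_hour=cutoff_hour)
            hits = sum(1 for c in cls if c.category == "hit")
            fails = sum(1 for c in cls if c.category == "fail")
            rows.append(
                {
                    "site": site,
                    "window_days": L,
                    "hits": hits,
                    "fails": fails,
                    "evaluated": hits + fails,
                    "hitting_ratio": round2(hits / (hits + fails)) if hits + fails else np.nan,
                }
            )
    return pd.DataFrame(rows)


def load_predictions(path) -> pd.DataFrame:
    """Prediction CSV: date, predicted, source, ft_h ('#' lines are comments)."""
    df = pd.read_csv(path, comment="#")
    missing = {"date", "predicted"} - set(df.columns)
    if missing:
        raise ValueError(f"prediction file missing columns: {sorted(missing)}")
    return df


def load_catches(path) -> pd.DataFrame:
    """Catch CSV: collection_date, count, interval_days ('#' lines are comments)."""
    df = pd.read_csv(path, comment="#")
    missing = {"collection_date", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"catch file missing columns: {sorted(missing)}")
    if "interval_days" not in df.columns:
        df["interval_days"] = 1
    if df.empty:
        raise ValueError("catch file has no records")
    return df
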