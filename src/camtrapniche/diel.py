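"""Diel-period classification and selection ratios.

The 24-h day is split into crepuscular (the 1-h windows before and after
sunrise and sunset, 4 h in total), diurnal (remaining daylight) and
nocturnal (remaining night) periods from a monthly mean sunrise/sunset
calendar. Preference for a period is the selection ratio w_i = o_i / π_i
— the proportion of detections in the period over the period's share of the
day; w > 1 indicates selective use, w < 1 avoidance. Non-random use is
tested by one-way ANOVA on per-month, period-length-standardised detection
rates (between-groups df = 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import stats

PERIODS = ("crepuscular", "diurnal", "nocturnal")

#: crepuscular window half-width around sunrise/sunset, hours
CREPUSCULAR_HALF_WIDTH = 1.0


@dataclass(frozen=True)
class PeriodProportions:
    crepuscular: float
    diurnal: float
    nocturnal: float

    def as_dict(self) -> dict[str, float]:
        return {
            "crepuscular": self.crepuscular,
            "diurnal": self.diurnal,
            "nocturnal": self.nocturnal,
        }


def _month_proportions(sunrise: float, sunset: float) -> PeriodProportions:
    """Period shares of one day from sunrise/sunset in fractional hours."""
    w = CREPUSCULAR_HALF_WIDTH
    if sunset - sunrise < 2 * w:
        raise ValueError("crepuscular windows overlap: day shorter than 2 h")
    if (24.0 - (sunset - sunrise)) < 2 * w:
        raise ValueError("crepuscular windows overlap: night shorter than 2 h")
    crep = 4.0 * w
    diurnal = (sunset - w) - (sunrise + w)
    nocturnal = 24.0 - crep - diurnal
    return PeriodProportions(crep / 24.0, diurnal / 24.0, nocturnal / 24.0)


def period_proportions(calendar: pd.DataFrame, months: list[int]) -> PeriodProportions:
    """Mean period proportions over the given months.

    ``calendar`` has columns month, sunrise, sunset (fractional hours, as
    returned by the calendar reader). Monthly proportions are averaged
    unweighted; the crepuscular share is 4/24 in every month by
    construction.
    """
    cal = calendar.set_index("month")
    missing = [m for m in months if m not in cal.index]
    if missing:
        raise KeyError(f"months absent from calendar: {missing}")
    parts = [_month_proportions(cal.at[m, "sunrise"], cal.at[m, "sunset"]) for m in months]
    return PeriodProportions(
        crepuscular=float(np.mean([p.crepuscular for p in parts])),
        diurnal=float(np.mean([p.diurnal for p in parts])),
        nocturnal=float(np.mean([p.nocturnal for p in parts])),
    )


def classify_period(timestamp: datetime, calendar: pd.DataFrame) -> str:
    """Diel period of one timestamp, using its month's mean sunrise/sunset.

    Boundary instants belong to the crepuscular windows (closed intervals).
    """
    cal = calendar.set_index("month")
    month = timestamp.month
    if month not in cal.index:
        raise KeyError(f"month {month} absent from calendar")
    sunrise = cal.at[month, "sunrise"]
    sunset = cal.at[month, "sunset"]
    hours = timestamp.hour + timestamp.minute / 60.0 + timestamp.second / 3600.0
    w = CREPUSCULAR_HALF_WIDTH
    if abs(hours - sunrise) <= w or abs(hours - sunset) <= w:
        return "crepuscular"
    if sunrise + w < hours < sunset - w:
        return "diurnal"
    return "nocturnal"


def selection_ratio(
    counts: dict[str, int], proportions: PeriodProportions
) -> pd.DataFrame:
    """Selection ratios w_i = o_i / π_i for the three diel periods.

    ``counts`` maps period name to its detection count. Returns a frame with
    one row per period: count, o (detection proportion), pi (period share)
    and w, at full precision (round to 2 decimals at report time).
    """
    total = sum(counts.get(p, 0) for p in PERIODS)
    if total <= 0:
        raise ValueError("no detections to compute selection ratios from")
    pi = proportions.as_dict()
    rows = []
    for p in PERIODS:
        c = counts.get(p, 0)
        o = c / total
        rows.append({"period": p, "count": c, "o": o, "pi": pi[p], "w": o / pi[p]})
    return pd.DataFrame(rows)


def nonrandom_use_test(rates_by_period: dict[str, np.ndarray]):
    """One-way ANOVA across the three diel periods on per-unit rates.

    The replicate unit is typically the month: each value is a detection
    rate standardised by the period's length in that month (detections per
    hour of that period). Between-groups df = 2.

    Returns (F, df_between, p).
    """
    groups = []
    for p in PERIODS:
        vals = np.asarray(rates_by_period.get(p, []), dtype=float)
        if len(vals) < 2:
            raise ValueError(f"period {p!r} needs >= 2 replicate units")
        groups.append(vals)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # no variation anywhere: F = 0 by convention
        return 0.0, len(groups) - 1, 1.0
    f, pval = stats.f_oneway(*groups)
    return float(f), len(groups) - 1, float(pval)


def monthly_period_rates(
    detections: pd.DataFrame, calendar: pd.DataFrame, effort: pd.DataFrame | None = None
) -> dict[str, np.ndarray]:
    """Detections per hour of each period, by month — ANOVA replicate units.

    ``detections`` needs a ``timestamp`` column (already filtered to one
    species and period of interest). Hours available per period in a month
    scale with that month's camera-days when ``effort`` is given, otherwise
    with calendar days alone; the ANOVA is invariant to a common factor, so
    effort matters only when it is uneven across months.
    """
    ts = pd.to_datetime(detections["timestamp"])
    labels = [classify_period(t, calendar) for t in ts]
    df = pd.DataFrame({"month": ts.dt.month, "period": labels})
    cal = calendar.set_index("month")
    months = sorted(df["month"].unique())
    if effort is not None:
        eff_month = pd.to_datetime(effort["date"].astype(str)).dt.month
        days_per_month = eff_month.value_counts()
    rates: dict[str, list[float]] = {p: [] for p in PERIODS}
    for m in months:
        props = _month_proportions(cal.at[m, "sunrise"], cal.at[m, "sunset"])
        n_days = float(days_per_month.get(m, 0)) if effort is not None else 1.0
        if n_days <= 0:
            continue
        sub = df[df["month"] == m]
        for p in PERIODS:
            hours = props.as_dict()[p] * 24.0 * n_days
            rates[p].append(len(sub[sub["period"] == p]) / hours)
    return {p: np.asarray(v) for p, v in rates.items()}
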