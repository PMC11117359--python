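"""Relative activity indices and their statistical comparisons.

RAI1 is a per-site spatial index (independent detections per 100 camera-days
at the site); RAI2 is a per-calendar-month temporal index with months pooled
across survey years. Full precision is kept internally; rounding happens only
in report writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float
    degenerate: bool = False


def rai1(
    detections: pd.DataFrame, effort: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Per-camera relative activity index for one species.

    Parameters
    ----------
    detections
        Independent detections with columns ``camera_id`` and ``species``
        (already restricted to the period of interest).
    effort
        Camera-day table (one row per active camera-day, already restricted
        to the same period).

    Returns
    -------
    DataFrame with columns camera_id, detections, camera_days, rai1 — one row
    per camera present in the effort table. Cameras with zero camera-days get
    ``rai1 = NaN`` and are flagged in the log.
    """
    counts = (
        detections[detections["species"] == species]
        .groupby("camera_id")
        .size()
        .rename("detections")
    )
    days = effort.groupby("camera_id").size().rename("camera_days")
    out = pd.concat([counts, days], axis=1).fillna({"detections": 0})
    out = out[out["camera_days"].notna()]
    out["camera_days"] = out["camera_days"].astype(int)
    out["detections"] = out["detections"].astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rai1"] = 100.0 * out["detections"] / out["camera_days"]
    undefined = out["camera_days"] == 0
    if undefined.any():
        logger.warning("RAI1 undefined for cameras with zero effort: %s",
                       list(out.index[undefined]))
        out.loc[undefined, "rai1"] = np.nan
    out.insert(0, "species", species)
    return out.reset_index().rename(columns={"index": "camera_id"})


def rai2(detections: pd.DataFrame, effort: pd.DataFrame, species: str) -> pd.DataFrame:
    """Monthly relative activity index, pooling detections and effort across years.

    Returns one row per calendar month 1–12 that has any effort, with columns
    month, detections, camera_days, rai2.
    """
    det = detections[detections["species"] == species]
    det_month = pd.to_datetime(det["timestamp"]).dt.month
    counts = det_month.value_counts().rename("detections")
    eff_month = pd.to_datetime(effort["date"].astype(str)).dt.month
    days = eff_month.value_counts().rename("camera_days")
    out = pd.concat([counts, days], axis=1).fillna({"detections": 0})
    out = out[out["camera_days"].notna()].sort_index()
    out["detections"] = out["detections"].astype(int)
    out["camera_days"] = out["camera_days"].astype(int)
    out["rai2"] = 100.0 * out["detections"] / out["camera_days"]
    out.insert(0, "species", species)
    out.index.name = "month"
    return out.reset_index()


def species_share(totals: dict[str, int]) -> dict[str, float]:
    """Percentage of independent detections per species (full precision)."""
    if not totals:
        raise ValueError("no species totals supplied")
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("all-zero detection totals")
    return {sp: 100.0 * n / grand for sp, n in totals.items()}


def compare_rai1(values_a: np.ndarray, values_b: np.ndarray) -> TestResult:
    """Welch's unequal-variance two-sample t-test on per-site RAI1 vectors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TestResult(0.0, float(len(a) + len(b) - 2), 1.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def seasonal_anova(rai2_by_season: dict[str, np.ndarray]):
    """One-way ANOVA of monthly RAI2 values across seasons, with Tukey HSD.

    Seasons with fewer than 2 observations are excluded with a warning.

    Returns
    -------
    (TestResult, DataFrame)
        The omnibus F-test and the all-pairs Tukey HSD table
        (group1, group2, meandiff, p_adj, reject).
    """
    groups = {}
    for season, vals in rai2_by_season.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            logger.warning("season %s has <2 observations — excluded", season)
            continue
        groups[season] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 seasons with >=2 observations")
    k = len(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:  # no variation anywhere: F = 0 by convention
        empty = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p-adj", "lower", "upper", "reject"]
        )
        return TestResult(0.0, float(k - 1), 1.0, degenerate=True), empty
    f, p = stats.f_oneway(*groups.values())
    n = sum(len(v) for v in groups.values())
    labels = np.concatenate([[s] * len(v) for s, v in groups.items()])
    data = np.concatenate(list(groups.values()))
    tukey = pairwise_tukeyhsd(data, labels)
    posthoc = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return TestResult(float(f), float(k - 1), float(p)), posthoc
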