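"""Station-level long-term trend detection for the six indicators.

A station-indicator series enters the trend screen only when sampling
covered at least five distinct years with at least six sampling events and
at least half of the samples are positive.  Eligible series are fit by
ordinary least squares of the individual sample values on integer
calendar year; the two-sided t-test on the slope is compared against a
Bonferroni-adjusted threshold.  The adjustment families are structural:
the four core-derived indicators share their cores (alpha' = 0.05/4) and
the two quadrat-derived indicators share their quadrats (alpha' = 0.05/2),
regardless of which indicators happen to have data at a station.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .field_derivations import AnnualIndicatorRecord, IndicatorId, SampleSource

__all__ = [
    "ALPHA",
    "MIN_YEARS",
    "MIN_EVENTS",
    "MIN_FRACTION_POSITIVE",
    "TrendDirection",
    "EligibilityResult",
    "TrendResult",
    "assess_eligibility",
    "fit_trend",
    "alpha_for",
    "call_direction",
    "run_trend_analysis",
    "trends_frame",
    "write_trends",
]

ALPHA = 0.05
MIN_YEARS = 5
MIN_EVENTS = 6
MIN_FRACTION_POSITIVE = 0.5

_CORE_FAMILY_SIZE = 4
_QUADRAT_FAMILY_SIZE = 2


class TrendDirection(str, enum.Enum):
    """I: significant increase; D: significant decrease; n: no change."""

    INCREASE = "I"
    DECREASE = "D"
    NONE = "n"


@dataclass(frozen=True)
class EligibilityResult:
    station_id: int
    indicator: IndicatorId
    eligible: bool
    years_sampled: int
    n_events: int
    n_samples: int
    frac_positive: float
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of one indicator at one station.

    ``slope`` is in indicator units per year.  ``p_value`` is None for a
    degenerate (zero-variance) series, which is always called n.
    """

    station_id: int
    indicator: IndicatorId
    slope: float | None
    t_statistic: float | None
    p_value: float | None
    alpha_adjusted: float
    direction: TrendDirection
    n_samples: int
    eligible: bool = True


def assess_eligibility(
    records: Sequence[AnnualIndicatorRecord],
) -> EligibilityResult:
    """Apply the three-rule inclusion screen to one station-indicator series.

    Rules: >= 5 distinct sampled years, >= 6 distinct sampling events,
    and > 0 values in at least 50% of the samples (an indicator absent
    from the bed for most of the record carries no trend information).
    """
    if not records:
        raise ValueError("assess_eligibility requires a nonempty series")
    sid = records[0].station_id
    ind = records[0].indicator
    years = {r.year for r in records}
    events = {d for r in records for d in r.dates}
    values = [v for r in records for v in r.values]
    frac_pos = sum(1 for v in values if v > 0) / len(values)
    reasons = []
    if len(years) < MIN_YEARS:
        reasons.append(f"only {len(years)} sampled years (need {MIN_YEARS})")
    if len(events) < MIN_EVENTS:
        reasons.append(f"only {len(events)} events (need {MIN_EVENTS})")
    if frac_pos < MIN_FRACTION_POSITIVE:
        reasons.append(
            f"only {frac_pos:.0%} of samples > 0 (need "
            f"{MIN_FRACTION_POSITIVE:.0%})"
        )
    return EligibilityResult(
        station_id=sid,
        indicator=ind,
        eligible=not reasons,
        years_sampled=len(years),
        n_events=len(events),
        n_samples=len(values),
        frac_positive=frac_pos,
        reasons=tuple(reasons),
    )


def fit_trend(
    records: Sequence[AnnualIndicatorRecord],
    observations: Literal["samples", "annual_means"] = "samples",
) -> tuple[float | None, float | None, float | None, int]:
    """OLS of indicator values on integer calendar year.

    Individual sample values are the observations by default; an
    annual-means mode exists for sensitivity checks.  Returns
    (slope, t, p, n) with Nones for a degenerate series (fewer than 3
    distinct years, or zero variance in x or y).
    """
    if observations == "samples":
        x = np.array([r.year for r in records for _ in r.values], float)
        y = np.array([v for r in records for v in r.values], float)
    else:
        x = np.array([r.year for r in records], float)
        y = np.array([sum(r.values) / len(r.values) for r in records], float)
    n = len(y)
    if len(np.unique(x)) < 3 or np.ptp(y) == 0.0:
        return None, None, None, n
    res = stats.linregress(x, y)
    if not np.isfinite(res.pvalue):
        return float(res.slope), None, None, n
    t = res.slope / res.stderr if res.stderr > 0 else None
    return float(res.slope), (float(t) if t is not None else None), \
        float(res.pvalue), n


def alpha_for(indicator: IndicatorId, alpha: float = ALPHA) -> float:
    """Bonferroni-adjusted significance threshold for an indicator.

    Core family (community biomass, both dominances, above/total ratio):
    alpha/4.  Quadrat family (productivity, shoot density): alpha/2.
    Family sizes are fixed by the protocol, not by data availability.
    """
    if indicator.source is SampleSource.CORE:
        return alpha / _CORE_FAMILY_SIZE
    return alpha / _QUADRAT_FAMILY_SIZE


def call_direction(
    slope: float | None,
    p_value: float | None,
    alpha_adjusted: float,
) -> TrendDirection:
    """I/D/n call from a fitted slope and its adjusted threshold."""
    if slope is None or p_value is None or p_value >= alpha_adjusted:
        return TrendDirection.NONE
    return TrendDirection.INCREASE if slope > 0 else TrendDirection.DECREASE


def run_trend_analysis(
    records: Iterable[AnnualIndicatorRecord],
    alpha: float = ALPHA,
    observations: Literal["samples", "annual_means"] = "samples",
) -> tuple[list[TrendResult], list[EligibilityResult]]:
    """Eligibility screen plus trend fit for every station-indicator series.

    Ineligible series carry ``eligible=False``, no fit and direction n.
    """
    series: dict[tuple[int, IndicatorId], list[AnnualIndicatorRecord]] = {}
    for r in records:
        series.setdefault((r.station_id, r.indicator), []).append(r)

    order = list(IndicatorId)
    trends: list[TrendResult] = []
    screens: list[EligibilityResult] = []
    for (sid, ind), recs in sorted(
        series.items(), key=lambda kv: (kv[0][0], order.index(kv[0][1]))
    ):
        recs = sorted(recs, key=lambda r: r.year)
        screen = assess_eligibility(recs)
        screens.append(screen)
        a_adj = alpha_for(ind, alpha)
        if not screen.eligible:
            trends.append(
                TrendResult(
                    station_id=sid, indicator=ind, slope=None,
                    t_statistic=None, p_value=None, alpha_adjusted=a_adj,
                    direction=TrendDirection.NONE,
                    n_samples=screen.n_samples, eligible=False,
                )
            )
            continue
        slope, t, p, n = fit_trend(recs, observations=observations)
        trends.append(
            TrendResult(
                station_id=sid, indicator=ind, slope=slope, t_statistic=t,
                p_value=p, alpha_adjusted=a_adj,
                direction=call_direction(slope, p, a_adj),
                n_samples=n, eligible=True,
            )
        )
    return trends, screens


def trends_frame(trends: Iterable[TrendResult]) -> pd.DataFrame:
    """Tabular view for trends.csv."""
    return pd.DataFrame(
        [
            {
                "station_id": t.station_id,
                "indicator": t.indicator.value,
                "slope": t.slope,
                "t": t.t_statistic,
                "p": t.p_value,
                "alpha_adjusted": t.alpha_adjusted,
                "direction": t.direction.value,
                "eligible": t.eligible,
                "n_samples": t.n_samples,
            }
            for t in trends
        ],
        columns=[
            "station_id", "indicator", "slope", "t", "p",
            "alpha_adjusted", "direction", "eligible", "n_samples",
        ],
    )


def write_trends(trends: Iterable[TrendResult], path: str | Path) -> None:
    trends_frame(trends).to_csv(path, index=False)
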