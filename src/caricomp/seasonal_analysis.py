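"""Intra-annual structure of turtlegrass leaf productivity.

Growth of turtlegrass tracks the solar cycle at subtropical latitudes.
This module assigns sampling events to the high/low growth season,
computes the per-event percent deviation from a station's general mean
productivity (dP), tests mean dP against zero per integer degree of
latitude, computes astronomical day length, and correlates monthly shoot
growth with sea surface temperature and day length.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domain_model import MonthlyEnvironment, SeasonScheme, Station
from .field_derivations import quadrat_growth_per_shoot, quadrat_productivity

logger = logging.getLogger(__name__)

__all__ = [
    "Season",
    "SeasonalDeviation",
    "LatitudeBandTest",
    "CorrelationResult",
    "MIN_EVENTS_FOR_DEVIATION",
    "assign_season",
    "event_productivities",
    "delta_p",
    "station_deviations",
    "latitude_band_ttest",
    "day_length",
    "monthly_growth_correlations",
]

#: A station enters the intra-annual analysis only with this many sampling
#: events, so that its general mean is a stable reference.
MIN_EVENTS_FOR_DEVIATION = 10

_HIGH_MONTHS = {
    SeasonScheme.NORTHERN: frozenset({5, 6, 7, 8, 9}),     # May-Sep
    SeasonScheme.STANDARD: frozenset({3, 4, 5, 6, 7, 8}),  # Mar-Aug
}


class Season(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"


def assign_season(date: Date, scheme: SeasonScheme) -> Season:
    """High or low growth season for a date under a station's scheme."""
    if date.month in _HIGH_MONTHS[scheme]:
        return Season.HIGH
    return Season.LOW


@dataclass(frozen=True)
class SeasonalDeviation:
    """dP: percent deviation of one event from the station's general mean."""

    station_id: int
    event_date: Date
    season: Season
    delta_p_pct: float


def event_productivities(quadrats) -> dict[tuple[int, Date], float]:
    """Per-event mean daily productivity, keyed by (station_id, date).

    An event's productivity is the mean of its quadrats' daily rates.
    """
    acc: dict[tuple[int, Date], list[float]] = {}
    for q in quadrats:
        acc.setdefault((q.station_id, q.date), []).append(
            quadrat_productivity(q)
        )
    return {k: sum(v) / len(v) for k, v in acc.items()}


def delta_p(
    events: Mapping[Date, float],
    station_id: int,
    scheme: SeasonScheme,
    min_events: int = MIN_EVENTS_FOR_DEVIATION,
) -> list[SeasonalDeviation]:
    """Deviations from the general mean productivity for one station.

    The general mean is the unweighted mean over all the station's event
    productivities; each event's deviation is expressed as a percentage of
    that mean, so the deviations of any station average to zero exactly.

    Returns [] (with a logged reason) for stations with fewer than
    ``min_events`` events; raises for an all-zero station, whose general
    mean cannot serve as a reference.
    """
    if len(events) < min_events:
        logger.info(
            "station %d excluded from intra-annual analysis: "
            "%d events < %d required",
            station_id, len(events), min_events,
        )
        return []
    mean = sum(events.values()) / len(events)
    if mean == 0.0:
        raise ValueError(
            f"station {station_id}: general mean productivity is 0; "
            "deviations are undefined"
        )
    return [
        SeasonalDeviation(
            station_id=station_id,
            event_date=d,
            season=assign_season(d, scheme),
            delta_p_pct=100.0 * (p - mean) / mean,
        )
        for d, p in sorted(events.items())
    ]


def station_deviations(
    stations: Sequence[Station],
    quadrats,
    min_events: int = MIN_EVENTS_FOR_DEVIATION,
) -> list[SeasonalDeviation]:
    """dP for every station with enough sampling events."""
    schemes = {s.station_id: s.season_scheme for s in stations}
    per_event = event_productivities(quadrats)
    by_station: dict[int, dict[Date, float]] = {}
    for (sid, d), p in per_event.items():
        by_station.setdefault(sid, {})[d] = p
    out: list[SeasonalDeviation] = []
    for sid in sorted(by_station):
        if sid not in schemes:
            logger.warning("station %d has samples but no metadata; skipped", sid)
            continue
        out.extend(
            delta_p(by_station[sid], sid, schemes[sid], min_events=min_events)
        )
    return out


@dataclass(frozen=True)
class LatitudeBandTest:
    """One-sample t-test of mean dP against 0 in one latitude band-season.

    ``testable`` is False for cells with < 2 events or zero variance.
    """

    latitude_band: int
    season: Season
    n_events: int
    mean_delta_p: float
    t_statistic: float | None
    p_value: float | None

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def latitude_band_ttest(
    deviations: Iterable[SeasonalDeviation],
    stations: Sequence[Station],
) -> list[LatitudeBandTest]:
    """Test whether mean dP differs from zero per latitude degree and season.

    Stations are pooled by the floor of their absolute latitude; each
    band-season cell gets a two-sided one-sample t-test of H0: mean dP = 0.
    """
    lat = {s.station_id: s.latitude_deg for s in stations}
    cells: dict[tuple[int, Season], list[float]] = {}
    for d in deviations:
        band = int(math.floor(abs(lat[d.station_id])))
        cells.setdefault((band, d.season), []).append(d.delta_p_pct)
    out: list[LatitudeBandTest] = []
    for (band, season), values in sorted(
        cells.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        if len(arr) < 2 or float(arr.std(ddof=1)) == 0.0:
            out.append(
                LatitudeBandTest(band, season, len(arr), mean, None, None)
            )
            continue
        t, p = stats.ttest_1samp(arr, 0.0)
        out.append(
            LatitudeBandTest(band, season, len(arr), mean, float(t), float(p))
        )
    return out


def day_length(latitude_deg: float, date: Date) -> float:
    """Hours of daylight from the standard solar-declination approximation.

    delta = 23.44 deg * sin(2 pi (284 + DOY) / 365);
    H = (24 / pi) * arccos(-tan(phi) tan(delta)), clamped to [0, 24] so
    polar day and night degrade gracefully.  No atmospheric refraction;
    accuracy is a few minutes at tropical latitudes.
    """
    doy = date.timetuple().tm_yday
    decl = math.radians(23.44) * math.sin(2.0 * math.pi * (284 + doy) / 365.0)
    x = -math.tan(math.radians(latitude_deg)) * math.tan(decl)
    if x >= 1.0:
        return 0.0
    if x <= -1.0:
        return 24.0
    return (24.0 / math.pi) * math.acos(x)


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation of monthly shoot growth with one environmental driver."""

    variable: Literal["sst_c", "daylight_h"]
    n_months: int
    r: float | None
    p_value: float | None


def monthly_growth_correlations(
    growth_by_month: Mapping[tuple[int, int], float],
    environment: Sequence[MonthlyEnvironment],
    latitude_deg: float | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> list[CorrelationResult]:
    """Correlate mean monthly growth per shoot with SST and day length.

    ``growth_by_month`` maps (year, month) to mean growth per shoot
    (g dry shoot-1 d-1).  Day length is taken from the environment table
    when present, otherwise computed from ``latitude_deg`` at mid-month.
    Requires >= 3 paired months; a constant series yields a missing
    correlation rather than an error.
    """
    env = {(e.year, e.month): e for e in environment}
    keys = sorted(set(growth_by_month) & set(env))
    growth = np.array([growth_by_month[k] for k in keys], dtype=float)
    sst = np.array([env[k].sst_c for k in keys], dtype=float)

    def daylight(k: tuple[int, int]) -> float:
        e = env[k]
        if e.daylight_h is not None:
            return e.daylight_h
        if latitude_deg is None:
            raise ValueError(
                "environment table lacks daylight_h and no latitude given"
            )
        return day_length(latitude_deg, Date(e.year, e.month, 15))

    day = np.array([daylight(k) for k in keys], dtype=float)

    def corr(var: Literal["sst_c", "daylight_h"], x) -> CorrelationResult:
        n = len(keys)
        if n < 3:
            raise ValueError(f"need >= 3 paired months, got {n}")
        if np.std(x) == 0.0 or np.std(growth) == 0.0:
            return CorrelationResult(var, n, None, None)
        if method == "pearson":
            r, p = stats.pearsonr(growth, x)
        else:
            r, p = stats.spearmanr(growth, x)
        return CorrelationResult(var, n, float(r), float(p))

    return [corr("sst_c", sst), corr("daylight_h", day)]


def monthly_mean_growth(quadrats) -> dict[int, dict[tuple[int, int], float]]:
    """Mean monthly growth per shoot, per station, from quadrat samples.

    Quadrats without shoots (growth undefined) are skipped.
    """
    acc: dict[int, dict[tuple[int, int], list[float]]] = {}
    for q in quadrats:
        g = quadrat_growth_per_shoot(q)
        if g is None:
            continue
        acc.setdefault(q.station_id, {}).setdefault(
            (q.date.year, q.date.month), []
        ).append(g)
    return {
        sid: {k: sum(v) / len(v) for k, v in months.items()}
        for sid, months in acc.items()
    }


def deviations_frame(deviations: Iterable[SeasonalDeviation]) -> pd.DataFrame:
    """Tabular view for seasonal.csv."""
    return pd.DataFrame(
        [
            {
                "station_id": d.station_id,
                "date": d.event_date.isoformat(),
                "season": d.season.value,
                "delta_p_pct": d.delta_p_pct,
            }
            for d in deviations
        ],
        columns=["station_id", "date", "season", "delta_p_pct"],
    )


def band_tests_frame(tests: Iterable[LatitudeBandTest]) -> pd.DataFrame:
    """Tabular view for band_tests.csv."""
    return pd.DataFrame(
        [
            {
                "latitude_band": t.latitude_band,
                "season": t.season.value,
                "n_events": t.n_events,
                "mean_delta_p": t.mean_delta_p,
                "t": t.t_statistic,
                "p": t.p_value,
            }
            for t in tests
        ],
        columns=["latitude_band", "season", "n_events", "mean_delta_p", "t", "p"],
    )
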