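"""Domain types and tidy-CSV readers/writers for seagrass monitoring data.

The pipeline consumes three tidy tables — ``stations.csv``, ``quadrats.csv``
and ``cores.csv`` — plus an optional ``environment.csv`` of monthly sea
surface temperature.  All masses are grams dry weight, all areas square
meters, all dates ISO-8601; this fixed unit system removes the need for
per-file unit metadata.

Validation is total: no input row raises an unhandled failure.  Rows that
violate an invariant are rejected with a row-indexed message collected in a
:class:`ValidationError` (readers) or :class:`ValidationReport`
(:func:`validate_dataset`).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InitialStatus",
    "SeasonScheme",
    "Station",
    "QuadratSample",
    "CoreSample",
    "MonthlyEnvironment",
    "SchemaError",
    "ValidationError",
    "ValidationIssue",
    "ValidationReport",
    "default_season_scheme",
    "read_stations",
    "read_quadrats",
    "read_cores",
    "read_environment",
    "write_stations",
    "write_quadrats",
    "write_cores",
    "validate_dataset",
]

#: Stations at or above this latitude default to the NORTHERN season scheme
#: (high growth season May-September); Bermuda and the Florida Keys are the
#: only network sites north of it.
NORTHERN_SCHEME_LATITUDE = 23.0


class InitialStatus(str, enum.Enum):
    """Disturbance status of a station at the onset of monitoring."""

    PRISTINE = "PRISTINE"
    INTERMEDIATE = "INTERMEDIATE"
    DISTURBED = "DISTURBED"


class SeasonScheme(str, enum.Enum):
    """Which calendar window counts as the high growth season.

    NORTHERN: high season May-September (subtropical sites, where growth
    lags the solar cycle by 1-2 months).  STANDARD: high season
    March-August (all tropical sites).
    """

    NORTHERN = "NORTHERN"
    STANDARD = "STANDARD"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """One or more rows violated a domain invariant.

    ``messages`` holds one row-indexed message per rejected row.
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


def default_season_scheme(latitude_deg: float) -> SeasonScheme:
    """Season scheme inferred from latitude when a station does not state one."""
    if latitude_deg >= NORTHERN_SCHEME_LATITUDE:
        return SeasonScheme.NORTHERN
    return SeasonScheme.STANDARD


@dataclass(frozen=True)
class Station:
    """One fixed monitoring station within a site.

    Latitude is decimal degrees north; depth is meters below mean tide
    level.  ``dominant_seagrass`` names the species used for the
    above/total biomass ratio (turtlegrass unless it disappeared from the
    bed, in which case manatee grass is substituted).
    """

    station_id: int
    site_id: int
    site_name: str
    latitude_deg: float
    longitude_deg: float
    depth_m: float
    secchi_m: float | None = None
    initial_status: InitialStatus = InitialStatus.INTERMEDIATE
    season_scheme: SeasonScheme | None = None
    dominant_seagrass: str = "Thalassia testudinum"

    def __post_init__(self) -> None:
        if not 0.0 <= self.latitude_deg <= 40.0:
            raise ValueError(
                f"latitude_deg {self.latitude_deg} outside [0, 40]"
            )
        if not self.depth_m > 0:
            raise ValueError(f"depth_m must be > 0, got {self.depth_m}")
        if self.season_scheme is None:
            object.__setattr__(
                self, "season_scheme", default_season_scheme(self.latitude_deg)
            )


@dataclass(frozen=True)
class QuadratSample:
    """One leaf-marking quadrat harvest.

    Leaves are hole-punched at the base, left to grow ``days_marked`` days
    (7-14 typical), then harvested; tissue below the marks is new growth.
    The default quadrat is 10 x 20 cm (0.02 m2).
    """

    station_id: int
    date: Date
    n_shoots: int
    mass_new_g: float
    mass_old_g: float
    days_marked: float
    area_m2: float = 0.02

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValueError(f"area_m2 must be > 0, got {self.area_m2}")
        if not self.days_marked > 0:
            raise ValueError(f"days_marked must be > 0, got {self.days_marked}")
        if self.n_shoots < 0:
            raise ValueError(f"n_shoots must be >= 0, got {self.n_shoots}")
        if self.mass_new_g < 0 or self.mass_old_g < 0:
            raise ValueError("leaf masses must be >= 0")
        if self.n_shoots == 0 and self.mass_new_g > 0:
            raise ValueError("n_shoots = 0 requires mass_new_g = 0")


@dataclass(frozen=True)
class CoreSample:
    """One biomass core, sorted into vegetation compartments.

    Compartments: turtlegrass above/below ground, pooled other seagrasses
    above/below ground, calcareous algae (somatic, i.e. decalcified,
    above-ground weight; below-ground parts are excluded by protocol), and
    fleshy algae above-ground.  Corers are 15-20 cm diameter PVC or steel.
    """

    station_id: int
    date: Date
    core_diameter_m: float
    mass_thal_above_g: float = 0.0
    mass_thal_below_g: float = 0.0
    mass_other_above_g: float = 0.0
    mass_other_below_g: float = 0.0
    mass_calc_somatic_g: float = 0.0
    mass_fleshy_above_g: float = 0.0

    _MASS_FIELDS = (
        "mass_thal_above_g",
        "mass_thal_below_g",
        "mass_other_above_g",
        "mass_other_below_g",
        "mass_calc_somatic_g",
        "mass_fleshy_above_g",
    )

    def __post_init__(self) -> None:
        if not self.core_diameter_m > 0:
            raise ValueError(
                f"core_diameter_m must be > 0, got {self.core_diameter_m}"
            )
        for name in self._MASS_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def area_m2(self) -> float:
        """Sampled area pi * (d/2)^2."""
        return math.pi * (self.core_diameter_m / 2.0) ** 2


@dataclass(frozen=True)
class MonthlyEnvironment:
    """Monthly mean sea surface temperature (and optionally day length)."""

    station_id: int
    year: int
    month: int
    sst_c: float
    daylight_h: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} outside 1..12")
        if not 15.0 <= self.sst_c <= 35.0:
            raise ValueError(f"sst_c {self.sst_c} outside [15, 35]")
        if self.daylight_h is not None and not 0.0 <= self.daylight_h <= 24.0:
            raise ValueError(f"daylight_h {self.daylight_h} outside [0, 24]")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_STATION_REQUIRED = [
    "station_id", "site_id", "site_name", "latitude_deg", "longitude_deg",
    "depth_m",
]
_QUADRAT_REQUIRED = [
    "station_id", "date", "n_shoots", "mass_new_g", "mass_old_g",
    "days_marked",
]
_CORE_REQUIRED = ["station_id", "date", "core_diameter_m"]
_ENV_REQUIRED = ["station_id", "year", "month", "sst_c"]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("%s: header only, no data rows", path)
    return df


def _opt(value: str) -> str | None:
    return value if value.strip() != "" else None


def read_stations(path: str | Path) -> list[Station]:
    """Read and validate a station table.

    ``season_scheme`` may be left blank; it then defaults from latitude
    (>= 23 deg N -> NORTHERN).  Duplicate ``station_id`` values are a
    validation error.
    """
    df = _read_table(path, _STATION_REQUIRED)
    stations: list[Station] = []
    errors: list[str] = []
    seen: set[int] = set()
    for idx, row in df.iterrows():
        try:
            sid = int(row["station_id"])
            if sid in seen:
                raise ValueError(f"duplicate station_id {sid}")
            seen.add(sid)
            raw_scheme = _opt(row["season_scheme"]) if "season_scheme" in df.columns else None
            raw_status = _opt(row["initial_status"]) if "initial_status" in df.columns else None
            raw_secchi = _opt(row["secchi_m"]) if "secchi_m" in df.columns else None
            raw_dom = _opt(row["dominant_seagrass"]) if "dominant_seagrass" in df.columns else None
            stations.append(
                Station(
                    station_id=sid,
                    site_id=int(row["site_id"]),
                    site_name=str(row["site_name"]),
                    latitude_deg=float(row["latitude_deg"]),
                    longitude_deg=float(row["longitude_deg"]),
                    depth_m=float(row["depth_m"]),
                    secchi_m=float(raw_secchi) if raw_secchi is not None else None,
                    initial_status=(
                        InitialStatus(raw_status)
                        if raw_status is not None
                        else InitialStatus.INTERMEDIATE
                    ),
                    season_scheme=(
                        SeasonScheme(raw_scheme) if raw_scheme is not None else None
                    ),
                    dominant_seagrass=raw_dom or "Thalassia testudinum",
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError(errors)
    return stations


def _read_samples(
    path: str | Path,
    required: Sequence[str],
    builder,
    stations: Iterable[Station] | None,
) -> list:
    df = _read_table(path, required)
    known = {s.station_id for s in stations} if stations is not None else None
    out: list = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            sample = builder(row)
            if known is not None and sample.station_id not in known:
                raise ValueError(
                    f"unknown station_id {sample.station_id}"
                )
            out.append(sample)
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError(errors)
    return out


def read_quadrats(
    path: str | Path, stations: Iterable[Station] | None = None
) -> list[QuadratSample]:
    """Read and validate leaf-marking quadrat samples.

    When ``stations`` is supplied, samples referencing an absent station
    are a referential error.
    """

    def build(row) -> QuadratSample:
        return QuadratSample(
            station_id=int(row["station_id"]),
            date=Date.fromisoformat(row["date"]),
            n_shoots=int(row["n_shoots"]),
            mass_new_g=float(row["mass_new_g"]),
            mass_old_g=float(row["mass_old_g"]),
            days_marked=float(row["days_marked"]),
            area_m2=float(row["area_m2"]) if _opt(row.get("area_m2", "")) else 0.02,
        )

    return _read_samples(path, _QUADRAT_REQUIRED, build, stations)


def read_cores(
    path: str | Path, stations: Iterable[Station] | None = None
) -> list[CoreSample]:
    """Read and validate biomass core samples."""

    def build(row) -> CoreSample:
        kwargs = {
            name: float(row[name]) if _opt(row.get(name, "")) else 0.0
            for name in CoreSample._MASS_FIELDS
        }
        return CoreSample(
            station_id=int(row["station_id"]),
            date=Date.fromisoformat(row["date"]),
            core_diameter_m=float(row["core_diameter_m"]),
            **kwargs,
        )

    return _read_samples(path, _CORE_REQUIRED, build, stations)


def read_environment(path: str | Path) -> list[MonthlyEnvironment]:
    """Read a monthly SST table."""

    def build(row) -> MonthlyEnvironment:
        raw_day = _opt(row.get("daylight_h", ""))
        return MonthlyEnvironment(
            station_id=int(row["station_id"]),
            year=int(row["year"]),
            month=int(row["month"]),
            sst_c=float(row["sst_c"]),
            daylight_h=float(raw_day) if raw_day is not None else None,
        )

    return _read_samples(path, _ENV_REQUIRED, build, None)


def _to_frame(records: Iterable) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {}
        for f in fields(r):
            v = getattr(r, f.name)
            if isinstance(v, enum.Enum):
                v = v.value
            row[f.name] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_stations(stations: Iterable[Station], path: str | Path) -> None:
    """Write stations to CSV in the canonical dialect (UTF-8, '.' decimal)."""
    _to_frame(stations).to_csv(path, index=False)


def write_quadrats(samples: Iterable[QuadratSample], path: str | Path) -> None:
    _to_frame(samples).to_csv(path, index=False)


def write_cores(samples: Iterable[CoreSample], path: str | Path) -> None:
    _to_frame(samples).to_csv(path, index=False)


def write_environment(
    records: Iterable[MonthlyEnvironment], path: str | Path
) -> None:
    _to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset-level validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    """One referential break or duplicate key found in a dataset."""

    kind: str  # "referential" | "duplicate"
    table: str  # "quadrats" | "cores"
    detail: str


@dataclass
class EventCountSummary:
    """Sampling effort at one station: distinct events and distinct years."""

    station_id: int
    n_events: int
    n_years: int


@dataclass
class ValidationReport:
    """Report-only summary of cross-table consistency."""

    issues: list[ValidationIssue] = field(default_factory=list)
    event_counts: list[EventCountSummary] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    stations: Sequence[Station],
    quadrats: Sequence[QuadratSample],
    cores: Sequence[CoreSample],
) -> ValidationReport:
    """Cross-check a dataset and summarise per-station sampling effort.

    Lists referential breaks (samples whose station is absent from the
    station table) and duplicate (station, date, replicate-ordinal) keys.
    Replicates are identified positionally, so duplicates can only arise
    from literally repeated rows; the check reports exact duplicate sample
    rows.  Never raises: the result is a report.
    """
    report = ValidationReport()
    known = {s.station_id for s in stations}
    for table, samples in (("quadrats", quadrats), ("cores", cores)):
        seen: set = set()
        for s in samples:
            if s.station_id not in known:
                report.issues.append(
                    ValidationIssue(
                        "referential", table,
                        f"station {s.station_id} not in station table",
                    )
                )
            key = s
            if key in seen:
                report.issues.append(
                    ValidationIssue(
                        "duplicate", table,
                        f"repeated sample row (station {s.station_id}, {s.date})",
                    )
                )
            seen.add(key)

    events: dict[int, set] = {}
    for s in (*quadrats, *cores):
        events.setdefault(s.station_id, set()).add(s.date)
    for sid in sorted(events):
        dates = events[sid]
        report.event_counts.append(
            EventCountSummary(
                station_id=sid,
                n_events=len(dates),
                n_years=len({d.year for d in dates}),
            )
        )
    return report
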