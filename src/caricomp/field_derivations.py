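"""Per-sample measures and the six annual community indicators.

Quadrat samples yield leaf productivity, leaf biomass, shoot density and
growth per shoot of turtlegrass; core samples yield areal biomass by
vegetation compartment, from which community biomass, relative dominance
of faster-growing groups and the above/total biomass ratio follow.

Indicator conventions
---------------------
==========================  ========  =============================
indicator                   source    units
==========================  ========  =============================
P1_COMMUNITY_BIOMASS        cores     g dry m-2
P2_OTHER_SEAGRASS_DOMINANCE cores     fraction of above-ground biomass
P3_FLESHY_ALGAE_DOMINANCE   cores     fraction of above-ground biomass
P4_ABOVE_TOTAL_RATIO        cores     fraction (per dominant seagrass)
P5_PRODUCTIVITY             quadrats  g dry m-2 d-1 (x365 annualized)
P6_SHOOT_DENSITY            quadrats  shoots m-2
==========================  ========  =============================

A compartment absent from a core is a structural zero; an indicator with a
zero denominator for an event (e.g. relative dominance of a bare core) is
missing, and that sample is excluded from the indicator rather than
recorded as 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .domain_model import CoreSample, QuadratSample, Station

__all__ = [
    "IndicatorId",
    "SampleSource",
    "BiomassDefinition",
    "CoreProfile",
    "AnnualIndicatorRecord",
    "quadrat_productivity",
    "quadrat_leaf_biomass",
    "quadrat_shoot_density",
    "quadrat_growth_per_shoot",
    "annual_productivity",
    "core_biomass_profile",
    "relative_dominance",
    "above_total_ratio",
    "build_indicator_table",
    "indicator_frame",
    "write_indicator_table",
]

BiomassDefinition = Literal["above_ground", "total"]


class SampleSource(str, enum.Enum):
    CORE = "CORE"
    QUADRAT = "QUADRAT"


class IndicatorId(str, enum.Enum):
    """The six community indicators screened for long-term change."""

    P1_COMMUNITY_BIOMASS = "P1_COMMUNITY_BIOMASS"
    P2_OTHER_SEAGRASS_DOMINANCE = "P2_OTHER_SEAGRASS_DOMINANCE"
    P3_FLESHY_ALGAE_DOMINANCE = "P3_FLESHY_ALGAE_DOMINANCE"
    P4_ABOVE_TOTAL_RATIO = "P4_ABOVE_TOTAL_RATIO"
    P5_PRODUCTIVITY = "P5_PRODUCTIVITY"
    P6_SHOOT_DENSITY = "P6_SHOOT_DENSITY"

    @property
    def source(self) -> SampleSource:
        """Whether the indicator derives from cores or quadrats."""
        if self in _QUADRAT_INDICATORS:
            return SampleSource.QUADRAT
        return SampleSource.CORE

    @property
    def units(self) -> str:
        return _UNITS[self]


_QUADRAT_INDICATORS = frozenset(
    {IndicatorId.P5_PRODUCTIVITY, IndicatorId.P6_SHOOT_DENSITY}
)
_UNITS = {
    IndicatorId.P1_COMMUNITY_BIOMASS: "g_dry_m-2",
    IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE: "fraction",
    IndicatorId.P3_FLESHY_ALGAE_DOMINANCE: "fraction",
    IndicatorId.P4_ABOVE_TOTAL_RATIO: "fraction",
    IndicatorId.P5_PRODUCTIVITY: "g_dry_m-2_d-1",
    IndicatorId.P6_SHOOT_DENSITY: "shoots_m-2",
}

DAYS_PER_YEAR = 365.0


# ---------------------------------------------------------------------------
# Quadrat-derived measures
# ---------------------------------------------------------------------------

def quadrat_productivity(sample: QuadratSample) -> float:
    """Areal daily leaf production (g dry m-2 d-1).

    The dry weight of the new-growth fraction accumulated over the marking
    interval, per unit quadrat area per day.
    """
    return sample.mass_new_g / (sample.area_m2 * sample.days_marked)


def quadrat_leaf_biomass(sample: QuadratSample) -> float:
    """Areal foliar biomass (g dry m-2): new plus old leaf fractions."""
    return (sample.mass_new_g + sample.mass_old_g) / sample.area_m2


def quadrat_shoot_density(sample: QuadratSample) -> float:
    """Foliar shoot density (shoots m-2)."""
    return sample.n_shoots / sample.area_m2


def quadrat_growth_per_shoot(sample: QuadratSample) -> float | None:
    """Leaf growth rate per shoot (g dry shoot-1 d-1).

    Undefined (returned as None, not 0) for a quadrat without shoots.
    """
    if sample.n_shoots == 0:
        return None
    return sample.mass_new_g / (sample.n_shoots * sample.days_marked)


def annual_productivity(samples: Sequence[QuadratSample]) -> float:
    """Annual leaf productivity (g dry m-2 y-1) for one station-year.

    Mean of the per-sample daily rates over all samples collected in the
    year (both growth seasons pooled), scaled by 365.
    """
    if not samples:
        raise ValueError("annual_productivity requires at least one sample")
    rates = [quadrat_productivity(s) for s in samples]
    return sum(rates) / len(rates) * DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# Core-derived measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreProfile:
    """Areal biomass (g dry m-2) of one core by vegetation compartment.

    Calcareous algae enter by somatic (decalcified) weight only and have
    no below-ground compartment; fleshy algae likewise count above-ground
    parts only.
    """

    thal_above: float
    thal_below: float
    other_above: float
    other_below: float
    calc_above: float
    fleshy_above: float

    @property
    def community_above(self) -> float:
        """Above-ground community biomass (all vegetation groups)."""
        return (
            self.thal_above + self.other_above
            + self.calc_above + self.fleshy_above
        )

    @property
    def community_total(self) -> float:
        """Above- plus below-ground community biomass."""
        return self.community_above + self.thal_below + self.other_below


def core_biomass_profile(core: CoreSample) -> CoreProfile:
    """Convert per-compartment core masses to areal biomass."""
    a = core.area_m2
    return CoreProfile(
        thal_above=core.mass_thal_above_g / a,
        thal_below=core.mass_thal_below_g / a,
        other_above=core.mass_other_above_g / a,
        other_below=core.mass_other_below_g / a,
        calc_above=core.mass_calc_somatic_g / a,
        fleshy_above=core.mass_fleshy_above_g / a,
    )


def relative_dominance(
    profile: CoreProfile,
    group: Literal["OTHER_SEAGRASS", "FLESHY_ALGAE"],
) -> float | None:
    """Fraction of above-ground community biomass held by a vegetation group.

    None (missing) when the core holds no above-ground biomass at all;
    0.0 when the community is present but the group is absent.
    """
    total = profile.community_above
    if total <= 0.0:
        return None
    if group == "OTHER_SEAGRASS":
        return profile.other_above / total
    if group == "FLESHY_ALGAE":
        return profile.fleshy_above / total
    raise ValueError(f"unknown group {group!r}")


def above_total_ratio(
    profile: CoreProfile,
    species: Literal["thalassia", "other"] = "thalassia",
) -> float | None:
    """Above-ground fraction of one seagrass's total biomass.

    Computed on turtlegrass by default; ``species="other"`` switches to
    the pooled other-seagrass group for beds where turtlegrass
    disappeared.  None when the species is absent from the core.
    """
    if species == "thalassia":
        above, below = profile.thal_above, profile.thal_below
    elif species == "other":
        above, below = profile.other_above, profile.other_below
    else:
        raise ValueError(f"unknown species {species!r}")
    total = above + below
    if total <= 0.0:
        return None
    return above / total


# ---------------------------------------------------------------------------
# Annual indicator table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnualIndicatorRecord:
    """All per-sample values of one indicator at one station in one year.

    ``values[i]`` was measured on the sampling event ``dates[i]``;
    individual samples are retained because the trend regressions operate
    on samples, not on annual means.
    """

    station_id: int
    year: int
    indicator: IndicatorId
    values: tuple[float, ...]
    dates: tuple[Date, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("values must be nonempty")
        if len(self.values) != len(self.dates):
            raise ValueError("values and dates must align")


def _core_indicator_values(
    core: CoreSample,
    station: Station | None,
    biomass_definition: BiomassDefinition,
) -> dict[IndicatorId, float | None]:
    profile = core_biomass_profile(core)
    p4_species: Literal["thalassia", "other"] = "thalassia"
    if station is not None and "filiforme" in station.dominant_seagrass.lower():
        p4_species = "other"
    if biomass_definition == "above_ground":
        p1 = profile.community_above
    else:
        p1 = profile.community_total
    return {
        IndicatorId.P1_COMMUNITY_BIOMASS: p1,
        IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE: relative_dominance(
            profile, "OTHER_SEAGRASS"
        ),
        IndicatorId.P3_FLESHY_ALGAE_DOMINANCE: relative_dominance(
            profile, "FLESHY_ALGAE"
        ),
        IndicatorId.P4_ABOVE_TOTAL_RATIO: above_total_ratio(
            profile, p4_species
        ),
    }


def build_indicator_table(
    stations: Sequence[Station],
    quadrats: Sequence[QuadratSample],
    cores: Sequence[CoreSample],
    biomass_definition: BiomassDefinition = "above_ground",
) -> list[AnnualIndicatorRecord]:
    """Derive the per-sample indicator series for every station and year.

    ``biomass_definition`` selects what the community-biomass indicator
    measures: ``"above_ground"`` (the definition the long-term trend
    classification uses) or ``"total"`` (above plus below ground).
    Samples for which an indicator is undefined (zero denominator) are
    dropped from that indicator only; records are sorted by
    (station, indicator, year).
    """
    by_station = {s.station_id: s for s in stations}
    acc: dict[tuple[int, int, IndicatorId], tuple[list[float], list[Date]]] = {}

    def push(sid: int, d: Date, ind: IndicatorId, value: float | None) -> None:
        if value is None:
            return
        vals, dates = acc.setdefault((sid, d.year, ind), ([], []))
        vals.append(value)
        dates.append(d)

    for q in quadrats:
        push(q.station_id, q.date, IndicatorId.P5_PRODUCTIVITY,
             quadrat_productivity(q))
        push(q.station_id, q.date, IndicatorId.P6_SHOOT_DENSITY,
             quadrat_shoot_density(q))
    for c in cores:
        values = _core_indicator_values(
            c, by_station.get(c.station_id), biomass_definition
        )
        for ind, v in values.items():
            push(c.station_id, c.date, ind, v)

    order = list(IndicatorId)
    records = [
        AnnualIndicatorRecord(
            station_id=sid, year=year, indicator=ind,
            values=tuple(vals), dates=tuple(dates),
        )
        for (sid, year, ind), (vals, dates) in acc.items()
    ]
    records.sort(key=lambda r: (r.station_id, order.index(r.indicator), r.year))
    return records


def indicator_frame(records: Iterable[AnnualIndicatorRecord]) -> pd.DataFrame:
    """Long-format view: one row per sample value."""
    rows = []
    for r in records:
        for ordinal, (v, d) in enumerate(zip(r.values, r.dates)):
            rows.append(
                {
                    "station_id": r.station_id,
                    "year": r.year,
                    "date": d.isoformat(),
                    "indicator": r.indicator.value,
                    "sample_ordinal": ordinal,
                    "value": v,
                    "units": r.indicator.units,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "station_id", "year", "date", "indicator",
            "sample_ordinal", "value", "units",
        ],
    )


def write_indicator_table(
    records: Iterable[AnnualIndicatorRecord], path: str | Path
) -> None:
    """Write the long-format indicators.csv."""
    indicator_frame(records).to_csv(path, index=False)
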