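"""Generator of monitoring-shaped datasets with known ground truth.

Simulates the bi-annual leaf-marking / core-sampling protocol: per
sampling event a station yields 4-6 quadrats and 2-4 cores, with event
dates placed at the seasonal peak and trough of the station's growth
scheme.  The generator's mean structure is controlled in closed form per
indicator:

* expected daily leaf productivity at date d,
  ``baseline * (1 + amplitude * s(d)) * trend * interannual``, with
  ``s(d)`` a unit sinusoid peaking mid high-season and the amplitude
  forced to 0 below the seasonality-threshold latitude;
* expected above-ground community biomass, group dominance fractions,
  the above/total ratio and shoot density each follow their own
  multiplicative linear-in-time trend factor.

Degradation modes move each indicator in its expected direction under the
scenario (nutrient enrichment or turbidity), so pipeline-level scenario
recovery is well-posed.  Observations are the expectations times
multiplicative lognormal noise (field biomass and productivity data are
positive and right-skewed); a shared per-year lognormal factor supplies
inter-annual variability.  Identical configuration and seed give
byte-identical output.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .domain_model import (
    CoreSample,
    MonthlyEnvironment,
    QuadratSample,
    SeasonScheme,
    Station,
)
from .field_derivations import IndicatorId
from .scenario_classification import EXPECTATION_MATRIX
from .seasonal_analysis import day_length
from .trend_analysis import TrendDirection

__all__ = [
    "TrendMode",
    "StormPulse",
    "CompartmentBaselines",
    "StationScenario",
    "SimulatedDataset",
    "SEASONALITY_THRESHOLD_LAT",
    "simulate_station",
    "simulate_network",
    "preset",
    "PRESETS",
]

#: Below this absolute latitude the generated seasonal amplitude is 0:
#: solar-cycle variation in growth is only detectable poleward of it.
SEASONALITY_THRESHOLD_LAT = 16.8

_PEAK_DOY = {SeasonScheme.NORTHERN: 196, SeasonScheme.STANDARD: 152}


class TrendMode(str, enum.Enum):
    NONE = "NONE"
    NUTRIENT = "NUTRIENT"
    TURBIDITY = "TURBIDITY"


@dataclass(frozen=True)
class StormPulse:
    """A one-event vegetation drop with linear recovery.

    ``magnitude`` is the fraction of vegetation removed at the event;
    recovery is linear over ``recovery_years``.
    """

    year: int
    magnitude: float
    recovery_years: float

    def factor(self, t_years_since_start: float, start_year: int) -> float:
        dt = t_years_since_start - (self.year - start_year)
        if dt < 0 or dt >= self.recovery_years:
            return 1.0
        return 1.0 - self.magnitude * (1.0 - dt / self.recovery_years)


@dataclass(frozen=True)
class CompartmentBaselines:
    """Baseline community composition of a simulated bed.

    ``above_total`` is above-ground community biomass (g dry m-2);
    ``frac_other``/``frac_fleshy``/``frac_calc`` partition it (the
    turtlegrass share is the remainder); ``thal_above_total`` is the
    above/total biomass ratio of turtlegrass (it invests most biomass
    below ground); ``other_below_ratio`` is below:above for the pooled
    faster-growing seagrasses.
    """

    above_total: float = 120.0
    frac_other: float = 0.12
    frac_fleshy: float = 0.08
    frac_calc: float = 0.05
    thal_above_total: float = 0.22
    other_below_ratio: float = 1.0


@dataclass(frozen=True)
class StationScenario:
    """Ground-truth configuration of one simulated station."""

    station: Station
    baseline_daily_productivity: float = 2.0  # g dry m-2 d-1 (~730 g y-1)
    baseline_shoot_density: float = 600.0     # shoots m-2
    baseline_leaf_biomass: float = 60.0       # g dry m-2 standing foliage
    compartments: CompartmentBaselines = field(
        default_factory=CompartmentBaselines
    )
    seasonal_amplitude: float = 0.0           # fraction of baseline, [0, 1)
    noise_cv: float = 0.3
    interannual_cv: float = 0.1
    trend_mode: TrendMode = TrendMode.NONE
    trend_rate: float = 0.0                   # fraction of baseline per year
    collapse_year: int | None = None
    storm: StormPulse | None = None
    quadrats_per_event: tuple[int, int] = (4, 6)
    cores_per_event: tuple[int, int] = (2, 4)
    core_diameter_m: float = 0.18
    days_marked_range: tuple[int, int] = (7, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if self.noise_cv <= 0.0:
            raise ValueError("noise_cv must be > 0")
        if self.trend_rate < 0.0:
            raise ValueError("trend_rate must be >= 0")
        if self.trend_mode is not TrendMode.NONE and self.trend_rate == 0.0:
            raise ValueError("trend_mode set but trend_rate is 0")


@dataclass
class SimulatedDataset:
    """A full simulated network with its ground-truth table."""

    stations: list[Station]
    quadrats: list[QuadratSample]
    cores: list[CoreSample]
    environment: list[MonthlyEnvironment]
    ground_truth: pd.DataFrame


def _sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    s = _sigma(cv)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _trend_directions(mode: TrendMode) -> dict[IndicatorId, TrendDirection | None]:
    if mode is TrendMode.NONE:
        return {ind: None for ind in IndicatorId}
    key = "N" if mode is TrendMode.NUTRIENT else "T"
    return {ind: EXPECTATION_MATRIX[ind][key] for ind in IndicatorId}


def _trend_factor(
    direction: TrendDirection | None, rate: float, t_years: float
) -> float:
    if direction is None or rate == 0.0:
        return 1.0
    if direction is TrendDirection.INCREASE:
        return 1.0 + rate * t_years
    return max(1.0 - rate * t_years, 0.05)


def expected_indicators(
    scenario: StationScenario,
    t_years: float,
    doy: int,
    seasonality_threshold_lat: float = SEASONALITY_THRESHOLD_LAT,
) -> dict[IndicatorId, float]:
    """Closed-form expectation of each indicator at a point in time.

    This is the noise-free mean structure the generator samples around
    (before the shared inter-annual factor and collapse/storm
    modifiers); tests converge to it as ``noise_cv`` shrinks.
    """
    dirs = _trend_directions(scenario.trend_mode)
    r = scenario.trend_rate
    f = {ind: _trend_factor(dirs[ind], r, t_years) for ind in IndicatorId}
    c = scenario.compartments
    amplitude = scenario.seasonal_amplitude
    if abs(scenario.station.latitude_deg) < seasonality_threshold_lat:
        amplitude = 0.0
    peak = _PEAK_DOY[scenario.station.season_scheme]
    seasonal = 1.0 + amplitude * math.cos(2.0 * math.pi * (doy - peak) / 365.0)
    q2 = min(c.frac_other * f[IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE], 0.85)
    q3 = min(c.frac_fleshy * f[IndicatorId.P3_FLESHY_ALGAE_DOMINANCE], 0.85)
    r4 = min(
        max(c.thal_above_total * f[IndicatorId.P4_ABOVE_TOTAL_RATIO], 0.01),
        0.98,
    )
    return {
        IndicatorId.P1_COMMUNITY_BIOMASS:
            c.above_total * f[IndicatorId.P1_COMMUNITY_BIOMASS],
        IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE: q2,
        IndicatorId.P3_FLESHY_ALGAE_DOMINANCE: q3,
        IndicatorId.P4_ABOVE_TOTAL_RATIO: r4,
        IndicatorId.P5_PRODUCTIVITY:
            scenario.baseline_daily_productivity
            * seasonal * f[IndicatorId.P5_PRODUCTIVITY],
        IndicatorId.P6_SHOOT_DENSITY:
            scenario.baseline_shoot_density * f[IndicatorId.P6_SHOOT_DENSITY],
    }


def _event_days(scheme: SeasonScheme, events_per_year: int) -> list[int]:
    """Day-of-year of each sampling event: peak, then evenly spaced."""
    peak = _PEAK_DOY[scheme]
    days = sorted(
        (peak + round(k * 365.0 / events_per_year)) % 365 + 1
        for k in range(events_per_year)
    )
    return days


def simulate_station(
    scenario: StationScenario,
    years: int = 10,
    events_per_year: int = 2,
    start_year: int = 1993,
    seasonality_threshold_lat: float = SEASONALITY_THRESHOLD_LAT,
) -> tuple[list[QuadratSample], list[CoreSample], list[MonthlyEnvironment]]:
    """Simulate one station's quadrats, cores and monthly environment.

    With ``events_per_year=2`` the events fall at the seasonal peak and
    trough of the station's growth scheme (one high-season, one
    low-season event per year, as the protocol prescribes).
    """
    if years < 1 or events_per_year < 1:
        raise ValueError("years and events_per_year must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    st = scenario.station
    c = scenario.compartments
    core_area = math.pi * (scenario.core_diameter_m / 2.0) ** 2
    qmin, qmax = scenario.quadrats_per_event
    cmin, cmax = scenario.cores_per_event
    dmin, dmax = scenario.days_marked_range
    event_days = _event_days(st.season_scheme, events_per_year)

    quadrats: list[QuadratSample] = []
    cores: list[CoreSample] = []
    env: list[MonthlyEnvironment] = []

    for y in range(years):
        year = start_year + y
        interannual = float(_lognoise(rng, scenario.interannual_cv)) \
            if scenario.interannual_cv > 0 else 1.0
        for doy in event_days:
            date = Date(year, 1, 1) + timedelta(days=doy - 1)
            t = y + doy / 365.0
            exp = expected_indicators(
                scenario, t, doy, seasonality_threshold_lat
            )
            modifier = interannual
            if scenario.storm is not None:
                modifier *= scenario.storm.factor(t, start_year)
            if scenario.collapse_year is not None and year > scenario.collapse_year:
                modifier = 0.0

            # --- quadrats -------------------------------------------------
            n_q = int(rng.integers(qmin, qmax + 1))
            for _ in range(n_q):
                days_marked = int(rng.integers(dmin, dmax + 1))
                area = 0.02
                rate = exp[IndicatorId.P5_PRODUCTIVITY] * modifier \
                    * float(_lognoise(rng, scenario.noise_cv))
                density = exp[IndicatorId.P6_SHOOT_DENSITY] * modifier \
                    * float(_lognoise(rng, scenario.noise_cv))
                n_shoots = int(round(density * area))
                mass_new = rate * area * days_marked
                leaf = scenario.baseline_leaf_biomass * modifier \
                    * float(_lognoise(rng, scenario.noise_cv))
                mass_old = max(leaf * area - mass_new, 0.0)
                if n_shoots == 0:
                    mass_new = 0.0
                quadrats.append(
                    QuadratSample(
                        station_id=st.station_id, date=date,
                        n_shoots=n_shoots, mass_new_g=mass_new,
                        mass_old_g=mass_old, days_marked=days_marked,
                        area_m2=area,
                    )
                )

            # --- cores ----------------------------------------------------
            above = exp[IndicatorId.P1_COMMUNITY_BIOMASS] * modifier
            q2 = exp[IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE]
            q3 = exp[IndicatorId.P3_FLESHY_ALGAE_DOMINANCE]
            qc = c.frac_calc
            thal_frac = max(1.0 - q2 - q3 - qc, 0.02)
            r4 = exp[IndicatorId.P4_ABOVE_TOTAL_RATIO]
            thal_above = above * thal_frac
            thal_below = thal_above * (1.0 - r4) / r4
            other_above = above * q2
            other_below = other_above * c.other_below_ratio
            exp_masses = {
                "mass_thal_above_g": thal_above,
                "mass_thal_below_g": thal_below,
                "mass_other_above_g": other_above,
                "mass_other_below_g": other_below,
                "mass_calc_somatic_g": above * qc,
                "mass_fleshy_above_g": above * q3,
            }
            n_c = int(rng.integers(cmin, cmax + 1))
            for _ in range(n_c):
                noisy = {
                    k: v * core_area * float(_lognoise(rng, scenario.noise_cv))
                    for k, v in exp_masses.items()
                }
                cores.append(
                    CoreSample(
                        station_id=st.station_id, date=date,
                        core_diameter_m=scenario.core_diameter_m, **noisy,
                    )
                )

        # --- monthly environment -----------------------------------------
        sst_mean = 28.5 - 0.08 * abs(st.latitude_deg)
        sst_amp = 1.0 + 0.12 * abs(st.latitude_deg)
        for month in range(1, 13):
            sst = sst_mean + sst_amp * math.cos(
                2.0 * math.pi * (month - 8) / 12.0
            )
            env.append(
                MonthlyEnvironment(
                    station_id=st.station_id, year=year, month=month,
                    sst_c=float(np.clip(sst, 15.0, 35.0)),
                    daylight_h=day_length(
                        st.latitude_deg, Date(year, month, 15)
                    ),
                )
            )
    return quadrats, cores, env


def _derive_seed(master_seed: int, station_id: int) -> int:
    """Stable per-station seed: network composition never perturbs a station."""
    ss = np.random.SeedSequence([int(master_seed), int(station_id)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_network(
    scenarios: Sequence[StationScenario],
    years: int = 10,
    events_per_year: int = 2,
    master_seed: int = 0,
    start_year: int = 1993,
) -> SimulatedDataset:
    """Simulate a network of stations with per-station derived seeds.

    Each station's seed is derived from (master_seed, station_id), so
    adding or reordering stations leaves every other station's data
    bit-identical.  The ground-truth table records each station's true
    degradation mode and rates for recovery testing.
    """
    if not scenarios:
        raise ValueError("at least one scenario required")
    ids = [sc.station.station_id for sc in scenarios]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate station_id across scenarios")

    ds = SimulatedDataset([], [], [], [], pd.DataFrame())
    truth_rows = []
    for sc in scenarios:
        seeded = replace(sc, seed=_derive_seed(master_seed, sc.station.station_id))
        q, co, e = simulate_station(
            seeded, years=years, events_per_year=events_per_year,
            start_year=start_year,
        )
        ds.stations.append(sc.station)
        ds.quadrats.extend(q)
        ds.cores.extend(co)
        ds.environment.extend(e)
        truth_rows.append(
            {
                "station_id": sc.station.station_id,
                "latitude_deg": sc.station.latitude_deg,
                "trend_mode": sc.trend_mode.value,
                "trend_rate": sc.trend_rate,
                "seasonal_amplitude": sc.seasonal_amplitude,
                "collapse_year": sc.collapse_year,
                "storm_year": sc.storm.year if sc.storm else None,
                "seed": seeded.seed,
            }
        )
    ds.ground_truth = pd.DataFrame(truth_rows)
    return ds


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _template(station_id: int, site_id: int, latitude: float,
              name: str) -> Station:
    return Station(
        station_id=station_id, site_id=site_id, site_name=name,
        latitude_deg=latitude, longitude_deg=-70.0 - 0.3 * station_id,
        depth_m=2.0,
    )


def _preset_baseline() -> list[StationScenario]:
    lats = [10.0, 14.0, 18.0, 22.0, 26.0, 30.0]
    return [
        StationScenario(
            station=_template(i + 1, i + 1, lat, f"baseline-{i + 1}"),
            seasonal_amplitude=0.3,
            seed=100 + i,
        )
        for i, lat in enumerate(lats)
    ]


def _preset_seasonal_gradient() -> list[StationScenario]:
    lats = [9.0, 12.0, 15.0, 18.0, 21.0, 24.0, 28.0, 32.0]
    return [
        StationScenario(
            station=_template(i + 1, i + 1, lat, f"gradient-{i + 1}"),
            seasonal_amplitude=0.35,
            seed=200 + i,
        )
        for i, lat in enumerate(lats)
    ]


def _degradation(mode: TrendMode, n_control: int = 20,
                 n_degraded: int = 20, rate: float = 0.05,
                 ) -> list[StationScenario]:
    out = []
    for i in range(n_control + n_degraded):
        degraded = i >= n_control
        lat = 10.0 + (i % 10) * 2.0
        out.append(
            StationScenario(
                station=_template(i + 1, i // 2 + 1, lat,
                                  f"{mode.value.lower()}-{i + 1}"),
                seasonal_amplitude=0.25,
                trend_mode=mode if degraded else TrendMode.NONE,
                trend_rate=rate if degraded else 0.0,
                seed=300 + i,
            )
        )
    return out


def _preset_collapse() -> list[StationScenario]:
    return [
        StationScenario(
            station=_template(1, 1, 18.0, "collapse-1"),
            seasonal_amplitude=0.25,
            collapse_year=1997,
            seed=400,
        )
    ]


def _preset_storm_pulse() -> list[StationScenario]:
    return [
        StationScenario(
            station=_template(1, 1, 17.0, "storm-1"),
            seasonal_amplitude=0.25,
            storm=StormPulse(year=1998, magnitude=0.7, recovery_years=3.0),
            seed=500,
        )
    ]


PRESETS = {
    "baseline": _preset_baseline,
    "seasonal_gradient": _preset_seasonal_gradient,
    "degradation_nutrient": lambda: _degradation(TrendMode.NUTRIENT),
    "degradation_turbidity": lambda: _degradation(TrendMode.TURBIDITY),
    "collapse": _preset_collapse,
    "storm_pulse": _preset_storm_pulse,
}


def preset(name: str) -> list[StationScenario]:
    """A documented scenario list with fixed seeds.

    Available: baseline (no-trend controls across latitudes),
    seasonal_gradient (amplitude suppressed below the threshold
    latitude), degradation_nutrient / degradation_turbidity (20 control +
    20 degraded stations at 5%/yr), collapse, storm_pulse.
    """
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
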