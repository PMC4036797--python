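"""Degradation-scenario engine.

Each of the six indicators has an expected direction of change under two
degradation scenarios — nutrient enrichment (N) and increasing turbidity
(T).  A station's significant trends are tagged by which scenario(s) they
are consistent with; a station with two or more trends consistent with
the same scenario is flagged as showing community change consistent with
environmental deterioration.

Expectation matrix (I increase, D decrease, . no expectation):

    indicator                     N   T
    community biomass             I   D
    other-seagrass dominance      I   I
    fleshy-algae dominance        I   I
    above/total biomass ratio     I   I
    leaf productivity             I   D
    foliar shoot density          .   D

The module also ships the published long-term trend matrix of the
monitoring network (35 stations at 17 sites) with its printed consistency
superscripts and star/collapse marks, used both as a regression reference
and as a worked example.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .field_derivations import IndicatorId
from .trend_analysis import TrendDirection, TrendResult

__all__ = [
    "EXPECTATION_MATRIX",
    "ConsistencyTag",
    "Scenario",
    "ScenarioCall",
    "ClassificationSummary",
    "ReferenceStationRow",
    "ReferenceTrendTable",
    "tag_consistency",
    "flag_station",
    "classify_all",
    "load_reference_trends",
    "classify_reference",
    "render_report",
]

#: Minimum number of same-scenario consistent trends that flags a station.
FLAG_THRESHOLD = 2


class ConsistencyTag(str, enum.Enum):
    """Which degradation scenario(s) a trend direction is consistent with."""

    N = "N"
    T = "T"
    NT = "NT"
    NONE = "none"
    MISSING = "missing"


class Scenario(str, enum.Enum):
    NUTRIENT = "NUTRIENT"
    TURBIDITY = "TURBIDITY"
    EITHER = "EITHER"
    NONE = "NONE"


#: Expected trend direction per indicator under each scenario (None = no
#: expectation).
EXPECTATION_MATRIX: dict[IndicatorId, dict[str, TrendDirection | None]] = {
    IndicatorId.P1_COMMUNITY_BIOMASS: {
        "N": TrendDirection.INCREASE, "T": TrendDirection.DECREASE,
    },
    IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE: {
        "N": TrendDirection.INCREASE, "T": TrendDirection.INCREASE,
    },
    IndicatorId.P3_FLESHY_ALGAE_DOMINANCE: {
        "N": TrendDirection.INCREASE, "T": TrendDirection.INCREASE,
    },
    IndicatorId.P4_ABOVE_TOTAL_RATIO: {
        "N": TrendDirection.INCREASE, "T": TrendDirection.INCREASE,
    },
    IndicatorId.P5_PRODUCTIVITY: {
        "N": TrendDirection.INCREASE, "T": TrendDirection.DECREASE,
    },
    IndicatorId.P6_SHOOT_DENSITY: {
        "N": None, "T": TrendDirection.DECREASE,
    },
}


def tag_consistency(
    indicator: IndicatorId, direction: TrendDirection
) -> ConsistencyTag:
    """Tag one significant trend direction against the expectation matrix."""
    if direction is TrendDirection.NONE:
        return ConsistencyTag.NONE
    expect = EXPECTATION_MATRIX[indicator]
    n = expect["N"] is direction
    t = expect["T"] is direction
    if n and t:
        return ConsistencyTag.NT
    if n:
        return ConsistencyTag.N
    if t:
        return ConsistencyTag.T
    return ConsistencyTag.NONE


@dataclass(frozen=True)
class ScenarioCall:
    """Scenario verdict for one station.

    NT tags count toward both scenarios.  ``scenario`` is EITHER when
    both counts independently reach the flag threshold.
    """

    station_id: int
    tags: dict[IndicatorId, ConsistencyTag]
    count_n: int
    count_t: int
    flagged: bool
    scenario: Scenario


def flag_station(
    tags: Mapping[IndicatorId, ConsistencyTag], station_id: int = 0
) -> ScenarioCall:
    """Count scenario-consistent trends and flag the station if >= 2 agree.

    Missing indicators contribute nothing; ``tags`` may omit them or mark
    them MISSING.
    """
    full = {
        ind: tags.get(ind, ConsistencyTag.MISSING) for ind in IndicatorId
    }
    count_n = sum(
        1 for t in full.values() if t in (ConsistencyTag.N, ConsistencyTag.NT)
    )
    count_t = sum(
        1 for t in full.values() if t in (ConsistencyTag.T, ConsistencyTag.NT)
    )
    flagged = max(count_n, count_t) >= FLAG_THRESHOLD
    if not flagged:
        scenario = Scenario.NONE
    elif count_n >= FLAG_THRESHOLD and count_t >= FLAG_THRESHOLD:
        scenario = Scenario.EITHER
    elif count_n >= count_t:
        scenario = Scenario.NUTRIENT
    else:
        scenario = Scenario.TURBIDITY
    return ScenarioCall(
        station_id=station_id, tags=full, count_n=count_n, count_t=count_t,
        flagged=flagged, scenario=scenario,
    )


@dataclass(frozen=True)
class ClassificationSummary:
    n_flagged: int
    n_total: int

    @property
    def percent(self) -> int:
        if self.n_total == 0:
            return 0
        return round(100.0 * self.n_flagged / self.n_total)


def classify_all(
    trends: Iterable[TrendResult],
    collapsed_stations: Iterable[int] = (),
) -> tuple[list[ScenarioCall], ClassificationSummary]:
    """Tag and flag every station appearing in a set of trend results.

    ``collapsed_stations`` lists stations whose decline has a documented
    non-water-quality cause (e.g. turtle grazing, storm burial); their
    trends are not tagged against the scenarios.  Collapse is a
    user-supplied annotation, never inferred from the data.  Ineligible
    indicator series count as missing.
    """
    collapsed = set(collapsed_stations)
    per_station: dict[int, dict[IndicatorId, ConsistencyTag]] = {}
    for tr in trends:
        tags = per_station.setdefault(tr.station_id, {})
        if not tr.eligible:
            tags[tr.indicator] = ConsistencyTag.MISSING
        elif tr.station_id in collapsed:
            tags[tr.indicator] = ConsistencyTag.NONE
        else:
            tags[tr.indicator] = tag_consistency(tr.indicator, tr.direction)
    calls = [
        flag_station(tags, station_id=sid)
        for sid, tags in sorted(per_station.items())
    ]
    summary = ClassificationSummary(
        n_flagged=sum(c.flagged for c in calls), n_total=len(calls)
    )
    return calls, summary


# ---------------------------------------------------------------------------
# Published reference trend matrix
# ---------------------------------------------------------------------------

_REFERENCE_RESOURCE = "reference_trends.csv"
_REFERENCE_SHA256 = (
    "cb1a19c79f413618dcaf73a542d19495f45461e57605a64db6f5bdefa2f32374"
)
_SHORT = {
    "p1": IndicatorId.P1_COMMUNITY_BIOMASS,
    "p2": IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE,
    "p3": IndicatorId.P3_FLESHY_ALGAE_DOMINANCE,
    "p4": IndicatorId.P4_ABOVE_TOTAL_RATIO,
    "p5": IndicatorId.P5_PRODUCTIVITY,
    "p6": IndicatorId.P6_SHOOT_DENSITY,
}


@dataclass(frozen=True)
class ReferenceStationRow:
    """One station of the published long-term trend matrix.

    ``directions`` holds the published I/D/n calls (indicators that were
    not determined are absent); ``published_tags`` the printed N/T/NT
    consistency superscripts (NONE for a direction printed without one).
    ``collapse`` marks beds lost to a documented non-water-quality cause;
    ``starred`` marks the stations the network judged consistent with
    environmental deterioration.
    """

    site_id: int
    station_id: int
    site_label: str
    collapse: bool
    starred: bool
    p4_species: str
    directions: dict[IndicatorId, TrendDirection]
    published_tags: dict[IndicatorId, ConsistencyTag]


@dataclass(frozen=True)
class ReferenceTrendTable:
    rows: tuple[ReferenceStationRow, ...]

    @property
    def n_stations(self) -> int:
        return len(self.rows)

    @property
    def n_sites(self) -> int:
        return len({r.site_id for r in self.rows})

    @property
    def starred_stations(self) -> frozenset[int]:
        return frozenset(r.station_id for r in self.rows if r.starred)


class FixtureIntegrityError(RuntimeError):
    """The packaged reference matrix does not match its recorded checksum."""


def load_reference_trends(path: str | Path | None = None) -> ReferenceTrendTable:
    """Load the packaged published trend matrix (35 stations, 17 sites).

    The packaged copy is checksum-verified; pass ``path`` to load an
    external matrix in the same layout instead (not verified).
    """
    if path is None:
        ref = resources.files("caricomp").joinpath("data", _REFERENCE_RESOURCE)
        raw = ref.read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _REFERENCE_SHA256:
            raise FixtureIntegrityError(
                f"reference matrix checksum {digest} != {_REFERENCE_SHA256}"
            )
        import io
        df = pd.read_csv(io.BytesIO(raw), dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)

    rows = []
    for _, row in df.iterrows():
        directions: dict[IndicatorId, TrendDirection] = {}
        published: dict[IndicatorId, ConsistencyTag] = {}
        for short, ind in _SHORT.items():
            d = row[f"{short}_dir"]
            if d == "-":
                continue
            directions[ind] = TrendDirection(d)
            published[ind] = ConsistencyTag(row[f"{short}_tag"])
        rows.append(
            ReferenceStationRow(
                site_id=int(row["site_id"]),
                station_id=int(row["station_id"]),
                site_label=row["site_label"],
                collapse=row["collapse"] == "1",
                starred=row["starred"] == "1",
                p4_species=row["p4_species"],
                directions=directions,
                published_tags=published,
            )
        )
    return ReferenceTrendTable(rows=tuple(rows))


def classify_reference(
    table: ReferenceTrendTable | None = None,
) -> tuple[list[ScenarioCall], ClassificationSummary]:
    """Run the scenario engine on the published trend matrix.

    Classification uses the printed consistency superscripts: for
    non-collapse stations these equal what :func:`tag_consistency`
    recomputes from the direction letters; for collapsed beds they encode
    the network's expert judgment that the decline had a documented
    non-water-quality cause and carry no scenario tags.
    """
    if table is None:
        table = load_reference_trends()
    calls = [
        flag_station(row.published_tags, station_id=row.station_id)
        for row in table.rows
    ]
    summary = ClassificationSummary(
        n_flagged=sum(c.flagged for c in calls), n_total=len(calls)
    )
    return calls, summary


def calls_frame(calls: Iterable[ScenarioCall]) -> pd.DataFrame:
    """Tabular view for calls.csv."""
    rows = []
    for c in calls:
        row = {"station_id": c.station_id}
        row.update({ind.value: c.tags[ind].value for ind in IndicatorId})
        row.update(
            {
                "count_N": c.count_n,
                "count_T": c.count_t,
                "flagged": c.flagged,
                "scenario": c.scenario.value,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    calls: Sequence[ScenarioCall], summary: ClassificationSummary
) -> str:
    """Plain-text summary table of scenario calls."""
    header = (
        f"{'station':>7}  {'P1':>4} {'P2':>4} {'P3':>4} {'P4':>4} "
        f"{'P5':>4} {'P6':>4}  {'N':>2} {'T':>2}  scenario"
    )
    lines = [header, "-" * len(header)]
    abbrev = {
        ConsistencyTag.MISSING: "-",
        ConsistencyTag.NONE: ".",
        ConsistencyTag.N: "N",
        ConsistencyTag.T: "T",
        ConsistencyTag.NT: "NT",
    }
    for c in calls:
        cells = " ".join(f"{abbrev[c.tags[ind]]:>4}" for ind in IndicatorId)
        star = "*" if c.flagged else " "
        lines.append(
            f"{c.station_id:>6}{star}  {cells}  {c.count_n:>2} {c.count_t:>2}"
            f"  {c.scenario.value if c.flagged else ''}"
        )
    lines.append("-" * len(header))
    lines.append(
        f"flagged {summary.n_flagged} of {summary.n_total} stations "
        f"({summary.percent}%)"
    )
    return "\n".join(lines)
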