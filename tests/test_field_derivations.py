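"""Per-sample measures and the annual indicator table."""

from __future__ import annotations

import math
from datetime import date as Date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caricomp import field_derivations as fd
from caricomp.domain_model import CoreSample, QuadratSample
from caricomp.field_derivations import IndicatorId


class TestQuadratMeasures:
    @pytest.mark.parametrize(
        "mass_new,area,days,expected",
        [(0.5, 0.02, 10, 2.5), (0.0, 0.02, 10, 0.0), (1.2, 0.02, 12, 5.0)],
    )
    def test_daily_productivity(self, make_quadrat, mass_new, area, days, expected):
        q = make_quadrat(mass_new=mass_new, area=area, days=days,
                         n_shoots=12 if mass_new else 0)
        assert fd.quadrat_productivity(q) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "new,old,expected", [(0.5, 1.5, 100.0), (0.0, 0.0, 0.0), (0.2, 0.0, 10.0)]
    )
    def test_leaf_biomass(self, make_quadrat, new, old, expected):
        q = make_quadrat(mass_new=new, mass_old=old,
                         n_shoots=12 if new else 0)
        assert fd.quadrat_leaf_biomass(q) == pytest.approx(expected)

    def test_shoot_density_and_growth_per_shoot(self, make_quadrat):
        q = make_quadrat(n_shoots=12, mass_new=0.36, days=10)
        assert fd.quadrat_shoot_density(q) == pytest.approx(600.0)
        assert fd.quadrat_growth_per_shoot(q) == pytest.approx(0.003)

    def test_bare_quadrat_density_zero_growth_missing(self, make_quadrat):
        q = make_quadrat(n_shoots=0, mass_new=0.0)
        assert fd.quadrat_shoot_density(q) == 0.0
        assert fd.quadrat_growth_per_shoot(q) is None


class TestAnnualProductivity:
    def test_constant_rate_scales_by_365(self, make_quadrat):
        quadrats = [make_quadrat(mass_new=0.4, days=10) for _ in range(4)]
        # each rate = 0.4/(0.02*10) = 2.0
        assert fd.annual_productivity(quadrats) == pytest.approx(730.0)

    def test_mean_then_scale(self, make_quadrat):
        quadrats = [
            make_quadrat(mass_new=0.2, days=10),  # rate 1.0
            make_quadrat(mass_new=0.6, days=10),  # rate 3.0
        ]
        assert fd.annual_productivity(quadrats) == pytest.approx(730.0)

    def test_single_sample(self, make_quadrat):
        q = make_quadrat(mass_new=0.11, days=10)  # rate 0.55
        assert fd.annual_productivity([q]) == pytest.approx(200.75)

    def test_empty_year_is_error(self):
        with pytest.raises(ValueError):
            fd.annual_productivity([])

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(0.1, 10.0))
    def test_linearity_in_new_growth_mass(self, scale):
        base = [
            QuadratSample(1, Date(2000, 6, 1), 10, m, 1.0, 10, 0.02)
            for m in (0.2, 0.5, 0.8)
        ]
        scaled = [
            QuadratSample(1, Date(2000, 6, 1), 10, m * scale, 1.0, 10, 0.02)
            for m in (0.2, 0.5, 0.8)
        ]
        assert fd.annual_productivity(scaled) == pytest.approx(
            scale * fd.annual_productivity(base)
        )


class TestCoreProfile:
    def test_areal_conversion(self, make_core):
        profile = fd.core_biomass_profile(make_core(diameter=0.20, thal_above=1.0))
        assert profile.thal_above == pytest.approx(31.83, abs=0.01)

    def test_smaller_corer(self, make_core):
        # independent area: pi * 0.075^2 = 0.0176715 m2
        profile = fd.core_biomass_profile(make_core(diameter=0.15, fleshy=0.5))
        assert profile.fleshy_above == pytest.approx(0.5 / (math.pi * 0.075**2))
        assert profile.fleshy_above == pytest.approx(28.29, abs=0.01)

    def test_empty_core_is_all_zero(self, make_core):
        profile = fd.core_biomass_profile(
            make_core(thal_above=0, thal_below=0, other_above=0,
                      other_below=0, calc=0, fleshy=0)
        )
        assert profile.community_total == 0.0

    def test_area_invariance(self, make_core):
        """Doubling core diameter with masses scaled by the area ratio
        leaves all areal values unchanged."""
        small = make_core(diameter=0.15)
        ratio = (0.30 / 0.15) ** 2
        big = make_core(
            diameter=0.30,
            thal_above=small.mass_thal_above_g * ratio,
            thal_below=small.mass_thal_below_g * ratio,
            other_above=small.mass_other_above_g * ratio,
            other_below=small.mass_other_below_g * ratio,
            calc=small.mass_calc_somatic_g * ratio,
            fleshy=small.mass_fleshy_above_g * ratio,
        )
        p_small = fd.core_biomass_profile(small)
        p_big = fd.core_biomass_profile(big)
        for name in ("thal_above", "thal_below", "other_above",
                     "other_below", "calc_above", "fleshy_above"):
            assert getattr(p_big, name) == pytest.approx(
                getattr(p_small, name), abs=1e-9
            )


class TestDominanceAndRatio:
    def test_relative_dominance_fractions(self, make_core):
        profile = fd.core_biomass_profile(
            make_core(thal_above=0.5, other_above=0.3, fleshy=0.2, calc=0.0)
        )
        assert fd.relative_dominance(profile, "OTHER_SEAGRASS") == pytest.approx(0.30)
        assert fd.relative_dominance(profile, "FLESHY_ALGAE") == pytest.approx(0.20)

    def test_monospecific_bed(self, make_core):
        profile = fd.core_biomass_profile(
            make_core(other_above=0, other_below=0, calc=0, fleshy=0)
        )
        assert fd.relative_dominance(profile, "OTHER_SEAGRASS") == 0.0

    def test_bare_core_dominance_missing(self, make_core):
        profile = fd.core_biomass_profile(
            make_core(thal_above=0, thal_below=1.0, other_above=0,
                      other_below=0, calc=0, fleshy=0)
        )
        assert fd.relative_dominance(profile, "OTHER_SEAGRASS") is None

    @pytest.mark.parametrize(
        "above,below,expected", [(0.4, 1.6, 0.20), (0.4, 0.0, 1.0)]
    )
    def test_above_total_ratio(self, make_core, above, below, expected):
        profile = fd.core_biomass_profile(
            make_core(thal_above=above, thal_below=below)
        )
        assert fd.above_total_ratio(profile) == pytest.approx(expected)

    def test_absent_species_missing(self, make_core):
        profile = fd.core_biomass_profile(
            make_core(thal_above=0, thal_below=0)
        )
        assert fd.above_total_ratio(profile) is None
        assert fd.above_total_ratio(profile, "other") is not None

    @settings(derandomize=True, max_examples=100)
    @given(
        masses=st.lists(
            st.floats(0.0, 10.0), min_size=4, max_size=4
        ).filter(lambda m: sum(m) > 0)
    )
    def test_dominance_sum_rule(self, masses):
        """Group dominances over the above-ground community sum to 1."""
        thal, other, calc, fleshy = masses
        profile = fd.core_biomass_profile(
            CoreSample(
                1, Date(2000, 6, 1), 0.18,
                mass_thal_above_g=thal, mass_thal_below_g=1.0,
                mass_other_above_g=other, mass_other_below_g=0.5,
                mass_calc_somatic_g=calc, mass_fleshy_above_g=fleshy,
            )
        )
        total = profile.community_above
        parts = (
            profile.thal_above / total
            + fd.relative_dominance(profile, "OTHER_SEAGRASS")
            + fd.relative_dominance(profile, "FLESHY_ALGAE")
            + profile.calc_above / total
        )
        assert parts == pytest.approx(1.0, abs=1e-12)


class TestBuildIndicatorTable:
    def _dataset(self, make_station, make_quadrat, make_core, years=2):
        station = make_station(1)
        quadrats, cores = [], []
        for y in range(years):
            for month in (4, 10):
                d = Date(2000 + y, month, 15)
                quadrats += [make_quadrat(date=d) for _ in range(2)]
                cores += [make_core(date=d) for _ in range(2)]
        return station, quadrats, cores

    def test_full_dataset_yields_all_indicators(
        self, make_station, make_quadrat, make_core
    ):
        station, quadrats, cores = self._dataset(
            make_station, make_quadrat, make_core
        )
        records = fd.build_indicator_table([station], quadrats, cores)
        assert len(records) == 12  # 6 indicators x 2 years
        assert {r.indicator for r in records} == set(IndicatorId)

    def test_quadrats_only_yield_quadrat_indicators(
        self, make_station, make_quadrat
    ):
        records = fd.build_indicator_table(
            [make_station(1)], [make_quadrat()], []
        )
        assert {r.indicator for r in records} == {
            IndicatorId.P5_PRODUCTIVITY, IndicatorId.P6_SHOOT_DENSITY,
        }

    def test_absent_fleshy_algae_is_structural_zero(
        self, make_station, make_core
    ):
        cores = [make_core(fleshy=0.0)]
        records = fd.build_indicator_table([make_station(1)], [], cores)
        p3 = [r for r in records
              if r.indicator is IndicatorId.P3_FLESHY_ALGAE_DOMINANCE]
        assert p3 and p3[0].values == (0.0,)

    def test_biomass_definition_switch(self, make_station, make_core):
        core = make_core()
        for definition, prop in (
            ("above_ground", "community_above"), ("total", "community_total")
        ):
            records = fd.build_indicator_table(
                [make_station(1)], [], [core], biomass_definition=definition
            )
            p1 = next(r for r in records
                      if r.indicator is IndicatorId.P1_COMMUNITY_BIOMASS)
            expected = getattr(fd.core_biomass_profile(core), prop)
            assert p1.values[0] == pytest.approx(expected)

    def test_matches_brute_force_recomputation(
        self, make_station, make_quadrat, make_core
    ):
        """Oracle: table values equal direct per-sample recomputation."""
        rng = np.random.default_rng(42)
        station = make_station(1)
        quadrats, cores = [], []
        for y in range(3):
            for month in (4, 10):
                d = Date(2000 + y, month, 15)
                for _ in range(3):
                    quadrats.append(
                        make_quadrat(
                            date=d,
                            mass_new=float(rng.uniform(0.05, 1.0)),
                            mass_old=float(rng.uniform(0.1, 2.0)),
                            n_shoots=int(rng.integers(1, 30)),
                            days=float(rng.integers(7, 15)),
                        )
                    )
                    cores.append(
                        make_core(
                            date=d,
                            thal_above=float(rng.uniform(0, 2)),
                            thal_below=float(rng.uniform(0, 8)),
                            other_above=float(rng.uniform(0, 1)),
                            other_below=float(rng.uniform(0, 1)),
                            calc=float(rng.uniform(0, 0.5)),
                            fleshy=float(rng.uniform(0, 1)),
                        )
                    )
        records = {
            (r.indicator, r.year): r
            for r in fd.build_indicator_table([station], quadrats, cores)
        }
        for year in (2000, 2001, 2002):
            qs = [q for q in quadrats if q.date.year == year]
            expected_p5 = [
                q.mass_new_g / (q.area_m2 * q.days_marked) for q in qs
            ]
            assert records[
                (IndicatorId.P5_PRODUCTIVITY, year)
            ].values == pytest.approx(expected_p5)

            cs = [c for c in cores if c.date.year == year]
            area = math.pi * 0.1**2
            expected_p2 = [
                c.mass_other_above_g
                / (c.mass_thal_above_g + c.mass_other_above_g
                   + c.mass_calc_somatic_g + c.mass_fleshy_above_g)
                for c in cs
            ]
            assert records[
                (IndicatorId.P2_OTHER_SEAGRASS_DOMINANCE, year)
            ].values == pytest.approx(expected_p2)
            expected_p1 = [
                (c.mass_thal_above_g + c.mass_other_above_g
                 + c.mass_calc_somatic_g + c.mass_fleshy_above_g) / area
                for c in cs
            ]
            assert records[
                (IndicatorId.P1_COMMUNITY_BIOMASS, year)
            ].values == pytest.approx(expected_p1)

    def test_long_format_writer(self, tmp_path, make_station, make_quadrat):
        records = fd.build_indicator_table(
            [make_station(1)], [make_quadrat()], []
        )
        out = tmp_path / "indicators.csv"
        fd.write_indicator_table(records, out)
        text = out.read_text()
        assert text.startswith(
            "station_id,year,date,indicator,sample_ordinal,value,units"
        )
        assert "P5_PRODUCTIVITY" in text
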