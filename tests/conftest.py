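from __future__ import annotations

from datetime import date as Date

import pytest

from caricomp.domain_model import CoreSample, QuadratSample, Station


@pytest.fixture
def make_station():
    def _make(station_id=1, latitude=18.0, **kwargs):
        defaults = dict(
            station_id=station_id,
            site_id=kwargs.pop("site_id", station_id),
            site_name=kwargs.pop("site_name", f"site-{station_id}"),
            latitude_deg=latitude,
            longitude_deg=kwargs.pop("longitude_deg", -75.0),
            depth_m=kwargs.pop("depth_m", 2.0),
        )
        defaults.update(kwargs)
        return Station(**defaults)

    return _make


@pytest.fixture
def make_quadrat():
    def _make(station_id=1, date=Date(2000, 6, 1), n_shoots=12,
              mass_new=0.5, mass_old=1.0, days=10, area=0.02):
        return QuadratSample(
            station_id=station_id, date=date, n_shoots=n_shoots,
            mass_new_g=mass_new, mass_old_g=mass_old,
            days_marked=days, area_m2=area,
        )

    return _make


@pytest.fixture
def make_core():
    def _make(station_id=1, date=Date(2000, 6, 1), diameter=0.20,
              thal_above=1.0, thal_below=4.0, other_above=0.3,
              other_below=0.3, calc=0.1, fleshy=0.2):
        return CoreSample(
            station_id=station_id, date=date, core_diameter_m=diameter,
            mass_thal_above_g=thal_above, mass_thal_below_g=thal_below,
            mass_other_above_g=other_above, mass_other_below_g=other_below,
            mass_calc_somatic_g=calc, mass_fleshy_above_g=fleshy,
        )

    return _make
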