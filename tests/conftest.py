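import numpy as np
import pytest
from shapely.geometry import box

import flcoder as flc


@pytest.fixture(scope="session")
def lexicon():
    return flc.KeywordLexicon.default()


@pytest.fixture(scope="session")
def small_city():
    """A 500-cell synthetic city shared by pipeline-level tests."""
    spec = flc.CitySpec(seed=11, width_m=5000.0, height_m=1000.0, n_facilities=600)
    return flc.generate_city(spec)


@pytest.fixture(scope="session")
def small_city_grid(small_city):
    return small_city.grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def rect_300x200():
    # offset away from the WGS84 degree range so it reads as projected metres
    return box(500_000.0, 4_600_000.0, 500_300.0, 4_600_200.0)


def make_place(name, lon, lat, source="file", source_id=None, tags=None):
    return flc.RawPlace(
        source=source,
        source_id=source_id or f"{source}-{name}-{lon:.5f}",
        name=name,
        location=flc.GeoPoint(lon, lat),
        tags=tags or {},
    )
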