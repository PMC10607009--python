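import numpy as np
import pytest
from shapely.geometry import Polygon

from mothflight.dispersion import ParticleEnsemble
from mothflight.release import SourceArea
from mothflight.synthetic import (
    KzSpec,
    ScenarioParams,
    TempSpec,
    WindSpec,
    uniform_flow,
)

START = np.datetime64("2021-04-30T10:00", "ns")


@pytest.fixture
def still_air_met():
    """Calm, isothermal, diffusion-free column over a 10x10 degree box."""
    params = ScenarioParams(
        lat_min=25, lat_max=35, lon_min=120, lon_max=130, duration_h=12,
        levels=(0, 500, 1000, 1500, 2000, 2500, 3000),
        wind=WindSpec(kind="uniform", u0=0.0, v0=0.0),
        temp=TempSpec(surface_c=25.0, lapse_c_per_km=0.0),
        kz=KzSpec(kind="constant", k0=0.0),
    )
    return uniform_flow(params)


@pytest.fixture
def westerly_met():
    """Uniform 10 m/s westerly, warm and diffusion-free."""
    params = ScenarioParams(
        lat_min=20, lat_max=40, lon_min=115, lon_max=140, duration_h=12,
        wind=WindSpec(kind="uniform", u0=10.0, v0=0.0),
        temp=TempSpec(surface_c=25.0, lapse_c_per_km=0.0),
        kz=KzSpec(kind="constant", k0=0.0),
    )
    return uniform_flow(params)


@pytest.fixture
def toy_source():
    return SourceArea("toy", Polygon([(124, 29), (126, 29), (126, 31), (124, 31)]))


def make_ensemble(n, zstar, start=START, lat=30.0, lon=125.0, takeoff=None):
    """Bare particle ensemble for direct stepping in property tests."""
    z = np.broadcast_to(np.asarray(zstar, dtype=float), (n,)).copy()
    return ParticleEnsemble(
        ids=np.arange(n),
        sources=np.array(["x"] * n, dtype=object),
        takeoff=np.full(n, takeoff if takeoff is not None else start),
        lat=np.full(n, float(lat)),
        lon=np.full(n, float(lon)),
        zstar=z,
        active=np.ones(n, dtype=bool),
        start=start,
    )
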