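import numpy as np
import pytest

from coliastherm import (EnvSample, EnvSeries, Morphology, PhysicalParams,
                         SiteConfig, generate_diurnal_series)
from coliastherm import defaults as dflt


@pytest.fixture
def params() -> PhysicalParams:
    return PhysicalParams()


@pytest.fixture
def meadii_morph() -> Morphology:
    return Morphology(absorptivity=0.691, setal_length=1.27)


@pytest.fixture
def eriphyle_morph() -> Morphology:
    return Morphology(absorptivity=0.518, setal_length=0.63)


@pytest.fixture
def clear_site() -> SiteConfig:
    """A deterministic site: no clouds, no wind noise."""
    return SiteConfig(
        name="clear", elevation=1600.0, t_min=12.0, t_max=30.0, s_max=900.0,
        sunrise=360, sunset=1200, wind_median=1.0, wind_spread=0.0,
        cloud_autocorr=0.9, cloud_depth=0.0,
    )


@pytest.fixture
def olathe_series() -> EnvSeries:
    return generate_diurnal_series(dflt.OLATHE, seed=7)


def constant_series(n=60, t0=0.0, air=20.0, soil=20.0, solar=0.0, wind=1.0,
                    model_temp=None, direct_sun=True) -> EnvSeries:
    """A flat series for analytic checks."""
    t = t0 + np.arange(n, dtype=float)
    mt = None if model_temp is None else np.full(n, float(model_temp))
    return EnvSeries(
        time=t,
        air_temp=np.full(n, air),
        soil_temp=np.full(n, soil),
        solar=np.full(n, solar),
        wind=np.full(n, wind),
        model_temp=mt,
        direct_sun=direct_sun,
    )


def still_air_sample(air=20.0, wind=1.0) -> EnvSample:
    """No sun, radiant temperatures equal to air: equilibrium is Tb = air."""
    return EnvSample(time=0.0, air_temp=air, soil_temp=air, solar=0.0, wind=wind)
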