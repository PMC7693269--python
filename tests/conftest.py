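import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nj_script():
    """One scripted New Jersey annual cycle (shared: track generation is the slow part)."""
    from marshwave import synthetic as syn

    return syn.make_annual_script("nj_00", 39.2, -75.24, 94, 107, 127, 192, 216, seed=11)


@pytest.fixture(scope="session")
def nj_track(nj_script):
    from marshwave import synthetic as syn

    light, cond, truth = syn.gen_geolocator_track(nj_script)
    return light, cond, truth


@pytest.fixture(scope="session")
def biomass_default():
    from marshwave import synthetic as syn

    params = syn.BiomassParams(seed=21)
    return params, syn.gen_biomass_studies(params)
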