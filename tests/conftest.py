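import numpy as np
import pytest

import lesionkinetics as lk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_config():
    return lk.reference_config(noiseless=True)


@pytest.fixture(scope="session")
def noiseless_records(noiseless_config):
    return lk.simulate_experiment(noiseless_config, seed=1)


@pytest.fixture(scope="session")
def noisy_records():
    return lk.simulate_experiment(lk.reference_config(), seed=7)


@pytest.fixture
def valid_row():
    return {
        "power_w": "40", "cf_g": "10", "time_s": "30", "li_drop_ohm": "25.0",
        "depth_a_mm": "4.0", "diam_b_mm": "8.0", "depth_c_mm": "2.0",
        "surf_d_mm": "6.0", "steam_pop": "0", "replicate": "1",
    }


def make_record(power=40.0, cf=10.0, t=30.0, li=25.0, a=4.0, b=8.0, c=2.0,
                d=6.0, pop=False, replicate=1):
    return lk.AblationRecord(
        setting=lk.AblationSetting(power_w=power, cf_g=cf),
        duration_s=t, li_drop_ohm=li,
        geometry=lk.LesionGeometry(a=a, b=b, c=c, d=d),
        steam_pop=pop, replicate=replicate,
    )
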