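import numpy as np
import pandas as pd
import pytest

from eddyforage import PipelineConfig, SyntheticConfig, generate_bundle, run_pipeline


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, n_eddies=6, fraction_effect_eddies=0.5,
                           effect_size_nasc=1.5, noise_cv=0.3)


@pytest.fixture(scope="session")
def bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def noiseless_run():
    """Pipeline run with zero noise and a x1.3 inside-NASC effect on half
    the eddies: the setting where anomalies are exact by construction."""
    syn = SyntheticConfig(seed=5, n_eddies=4, fraction_effect_eddies=0.5,
                          effect_size_nasc=1.3, noise_cv=0.0,
                          sst_noise_sd_c=0.0, chl_noise_cv=0.0)
    return run_pipeline(PipelineConfig(synthetic=syn))


@pytest.fixture(scope="session")
def noisy_run(small_config):
    return run_pipeline(PipelineConfig(synthetic=small_config))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def constant_profiles():
    """Six analysis-ready profiles (3 day / 3 night) with constant NASC 100."""
    from eddyforage import NASC_COLUMNS

    n = 6
    df = pd.DataFrame({
        "profile_id": range(n),
        "time": pd.date_range("2015-03-01", periods=n, freq="6h", tz="UTC"),
        "lon": -140.0, "lat": -30.0, "seabed_depth_m": 4000.0,
        "period": ["day", "night"] * 3,
    })
    for c in NASC_COLUMNS:
        df[c] = 100.0
    return df
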