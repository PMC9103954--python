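import numpy as np
import pandas as pd
import pytest

import steamhybrid as sh


@pytest.fixture(scope="session")
def small_study():
    """30 sites x 80 days synthetic study with default truth parameters."""
    sites = sh.generate_network(30, seed=11)
    cov = sh.generate_covariates(sites, seed=12)
    meteo = sh.generate_meteorology(pd.date_range("2009-01-01", periods=80), seed=13)
    panel, truth = sh.generate_measurements(sites, cov, meteo, sh.TruthParams(), seed=14)
    return {"sites": sites, "covariates": cov, "meteo": meteo, "panel": panel, "truth": truth}


@pytest.fixture(scope="session")
def small_frame(small_study):
    s = small_study
    return sh.make_model_frame(s["panel"], s["sites"], s["covariates"], s["meteo"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
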