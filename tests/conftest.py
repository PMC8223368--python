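import numpy as np
import pandas as pd
import pytest

import spatepi as sp


@pytest.fixture(scope="session")
def small_survey():
    """One fixed synthetic survey with planted spatial structure."""
    cfg = sp.dhs_like_config(seed=11, n_clusters=80)
    individuals, locations = sp.simulate_survey(cfg)
    return cfg, individuals, locations


@pytest.fixture(scope="session")
def small_features(small_survey):
    cfg, individuals, locations = small_survey
    feats = sp.build_cluster_features(
        individuals, locations, covariates=list(cfg.covariate_prevalence))
    return cfg, feats


@pytest.fixture(scope="session")
def random_points():
    rng = np.random.default_rng(7)
    lon = rng.uniform(33, 48, 40)
    lat = rng.uniform(4, 14, 40)
    return lon, lat
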