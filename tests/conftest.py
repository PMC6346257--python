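"""Shared fixtures: small seeded synthetic worlds."""
import warnings

import numpy as np
import pytest

from cgfmap import (GPHyperParams, SurveyDesign, WorldConfig, make_world,
                    simulate_surveys, simulate_truth)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_world():
    """10x10 grid, 6 years, 2 countries — enough structure for every module."""
    cfg = WorldConfig(n_rows=10, n_cols=10, years=tuple(range(2000, 2006)))
    grid, covs = make_world(cfg, seed=11)
    return grid, covs


@pytest.fixture(scope="session")
def small_truth(small_world):
    grid, covs = small_world
    gp = GPHyperParams(spatial_range=3.0, spatial_var=0.3, ar1_rho=0.8)
    beta = np.array([0.3, -0.2, 0.25, 0.15, -0.1])
    return simulate_truth(grid, covs, gp, beta, seed=11)


@pytest.fixture(scope="session")
def small_surveys(small_world, small_truth):
    grid, _ = small_world
    design = SurveyDesign(clusters_per_year=30, point_fraction=0.7,
                          microdata=False)
    obs, _ = simulate_surveys(small_truth, grid, design, seed=12)
    return obs
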