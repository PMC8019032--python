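import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from beescape.zinb import ZinbData

# property tests must be reproducible across runs
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20160520)


def simulate_zinb_dataset(
    seed,
    n_sites=25,
    n_periods=4,
    per_cell=20,
    beta=(1.0, 1.0),
    theta=1.5,
    pi=0.15,
    sigma_site=0.5,
    sigma_period=0.3,
    offset_minutes=30.0,
    n_covariates=None,
):
    """Draw one crossed-design ZINB dataset with known parameters.

    Returns (ZinbData, true beta array).  Covariates are iid standard
    normal; the offset is log(minutes).
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = beta.size - 1 if n_covariates is None else n_covariates
    n = n_sites * n_periods * per_cell
    site = np.repeat(np.arange(n_sites), n_periods * per_cell)
    period = np.tile(np.repeat(np.arange(n_periods), per_cell), n_sites)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p)])
    u = rng.normal(0, sigma_site, n_sites)
    v = rng.normal(0, sigma_period, n_periods)
    offset = np.full(n, np.log(offset_minutes))
    mu = np.exp(X @ beta + offset + u[site] + v[period])
    y = rng.negative_binomial(theta, theta / (theta + mu))
    if pi > 0:
        y = np.where(rng.random(n) < pi, 0, y)
    data = ZinbData(
        y=y,
        X=X,
        offset=offset,
        site_idx=site,
        period_idx=period,
        term_names=("(Intercept)",) + tuple(f"x{i+1}" for i in range(p)),
    )
    return data, beta


@pytest.fixture
def species_table(rng):
    """Synthetic species table with a known log-linear reward structure."""
    from beescape.simulate import SimulationConfig, generate_species_pool

    return generate_species_pool(SimulationConfig(seed=7, n_species=40), rng)


@pytest.fixture
def small_mosaic():
    """Four rectangular patches tiling a 2 km square around the origin."""
    from shapely.geometry import box

    from beescape.landscape import LandPatch

    half = 1000.0
    return [
        LandPatch("NW", box(-half, 0, 0, half), "meadow", "resource_providing"),
        LandPatch("NE", box(0, 0, half, half), "cereal_crop", "non_resource"),
        LandPatch("SW", box(-half, -half, 0, 0), "soybean", "soybean"),
        LandPatch("SE", box(0, -half, half, 0), "unknown_crop", "unknown"),
    ]
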