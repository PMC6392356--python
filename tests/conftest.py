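import numpy as np
import pandas as pd
import pytest

import reefranges as rr

D_REF = 6000.0


@pytest.fixture(scope="session")
def pool():
    return rr.make_species_pool(rr.default_pool_config(seed=1))


@pytest.fixture(scope="session")
def ranges(pool):
    return rr.simulate_range_sizes(pool, rr.default_effect_config(), seed=2)


@pytest.fixture(scope="session")
def species_focal(pool):
    return rr.assign_focal_subset(pool, rr.headline_bias_config(), seed=3)


@pytest.fixture(scope="session")
def small_pool():
    """A compact pool for resampling-heavy tests."""
    cfg = rr.PoolConfig(n_species=80, n_orders=3, families_per_order=3,
                        genera_per_family=2, seed=7)
    return rr.make_species_pool(cfg)
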