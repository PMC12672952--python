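import numpy as np
import pytest

from vascareless import (
    CarelessPattern,
    ItemsMeta,
    McmcSpec,
    SimulationCondition,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small contaminated dataset used by several estimation tests."""
    cond = SimulationCondition(
        careless_pattern=CarelessPattern(kind="beta_extremes"),
        prop_careless=0.25, seed=424242, n_persons=120, n_items=8, n_negative=4,
    )
    return generate_dataset(cond)


@pytest.fixture(scope="session")
def small_meta(small_dataset):
    return ItemsMeta(wording=np.array([it.wording for it in small_dataset.items]))


@pytest.fixture(scope="session")
def short_spec():
    """Short two-chain MCMC spec for smoke-level fitting tests."""
    return McmcSpec(chains=2, iterations=1200, seed=99, thin=2)
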