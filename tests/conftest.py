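import numpy as np
import pandas as pd
import pytest

from crisprar import (
    CrisprParams,
    PromoterKinetics,
    SyntheticDesign,
    default_library,
    default_single_modules,
)


@pytest.fixture
def wt():
    """Wild-type promoter: unit switching rates, tau=1, scale 200."""
    return PromoterKinetics(k_on=1.0, k_off=1.0, tau=1.0, C=200.0)


@pytest.fixture
def params():
    return CrisprParams()


@pytest.fixture
def library():
    return default_library()


@pytest.fixture
def small_design(wt, params):
    """A cheap synthetic design: four paired + four single groups, small events."""
    lib = default_library()[:4]
    singles = [m for m in default_single_modules() if m.name in ("A1", "A2", "R2", "R3")]
    return SyntheticDesign(
        library=lib,
        single_modules=singles,
        params=params,
        wt=wt,
        n_replicates=3,
        n_events=2000,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
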