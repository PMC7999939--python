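import numpy as np
import pandas as pd
import pytest

from embryomet.datatypes import CohortConfig, Effect


@pytest.fixture
def default_config():
    return CohortConfig(seed=1)


@pytest.fixture
def planted_config():
    """Cohort with one strong CM and one strong Day-0 plasma biomarker at birth."""
    return CohortConfig(
        seed=7,
        effect_table=(
            Effect("CM_M01", "CM", "birth", 2.0),
            Effect("PL_M01", "plasma_d0", "birth", 2.0),
        ),
    )


@pytest.fixture
def small_null_config():
    """Reduced panels for replicate-heavy simulations (null structure)."""
    return CohortConfig(
        seed=11,
        n_cm_metabolites=8,
        n_plasma_metabolites=12,
        missing_day0=0,
    )


def make_series(values, ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"S{i:02d}" for i in range(values.size)]
    return pd.Series(values, index=ids)


@pytest.fixture
def series_factory():
    return make_series
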