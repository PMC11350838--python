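import numpy as np
import pandas as pd
import pytest

from radonrisk import CohortConfig, TrueDoseResponse, generate_cohort

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def jshape_cohort() -> pd.DataFrame:
    """Mid-size cohort with a mirror-point (J-shaped) truth at 58 Bq/m^3."""
    cfg = CohortConfig(
        n_total=6000, seed=42, dose_response=TrueDoseResponse(kind="lmp", beta=0.9, delta=58.0)
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Mid-size cohort with a flat (null) dose-response."""
    cfg = CohortConfig(n_total=6000, seed=11, dose_response=TrueDoseResponse(kind="flat"))
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
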