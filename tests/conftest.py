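"""Shared fixtures for the profilex test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from profilex.cohort import CohortConfig, FixedShares, PredictorSpec, default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cfg() -> CohortConfig:
    return default_config()


@pytest.fixture(scope="session")
def small_cohort(default_cfg) -> pd.DataFrame:
    """A default-configured cohort (n=517) used by several test modules."""
    return generate_cohort(default_cfg, seed=1)


@pytest.fixture(scope="session")
def separated_cfg() -> CohortConfig:
    """Two well-separated classes (>= 6 within-class SDs apart on every indicator)."""
    return CohortConfig(
        n=400,
        class_model=FixedShares(pi_high=0.4),
        predictors={"gender_male": PredictorSpec(kind="binary", rate=0.5)},
        indicator_means_high=(36.0, 20.0, 110.0),
        indicator_means_low=(12.0, 50.0, 38.0),
        indicator_sds=(2.0, 3.0, 5.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
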