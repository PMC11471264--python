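import numpy as np
import pytest

from income_qba import (
    default_config,
    expand_crosstab,
    generate_cohort,
    load_published_predictive_values,
    load_validation_crosstab,
)


@pytest.fixture(scope="session")
def validation_tab():
    """Published observed-by-true quintile counts, stratified by mortality."""
    return load_validation_crosstab()


@pytest.fixture(scope="session")
def fixture_records(validation_tab):
    """Record-level expansion of the published counts (no covariates)."""
    return expand_crosstab(validation_tab)


@pytest.fixture(scope="session")
def published_pvms():
    """Published covariate-adjusted predictive values with 95% CIs."""
    return load_published_predictive_values()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n = 21,560)."""
    return generate_cohort(default_config(seed=42))


@pytest.fixture(scope="session")
def big_cohort():
    """Large synthetic cohort for large-sample empirical checks."""
    return generate_cohort(default_config(n=200_000, seed=0))


@pytest.fixture(scope="session")
def identity_pv_matrices():
    """Identity predictive-value matrices with zero-width intervals."""
    from income_qba import PredictiveValueMatrix

    ident = np.eye(5)
    return {y: PredictiveValueMatrix(y, ident, ident, ident) for y in (0, 1)}
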