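import numpy as np
import pytest

from vsalert import (
    GeneratorParams,
    apply_exclusions,
    attach_outcomes,
    derive_table,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study population (n=958, default seed)."""
    return generate_cohort(GeneratorParams())


@pytest.fixture(scope="session")
def analysis_table(default_cohort):
    """Excluded, derived (max-SI worst point) and outcome-annotated table."""
    retained, _ = apply_exclusions(default_cohort)
    return attach_outcomes(derive_table(retained), retained)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
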