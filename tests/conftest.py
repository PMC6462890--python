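import numpy as np
import pytest

from hearscreen import (
    ScaleTable,
    cohort_from_groups,
    protocol_preset,
    run_protocol_on_cohort,
    study_cohort_spec,
)


@pytest.fixture
def table():
    return ScaleTable()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_cohort():
    """The 170-ear validation cohort reconstructed from its group summary."""
    return cohort_from_groups(study_cohort_spec())


@pytest.fixture(scope="session")
def study_hst_results(study_cohort):
    """The cohort screened once with the adaptive scale protocol."""
    return run_protocol_on_cohort(study_cohort, protocol_preset("HST"), seed=0)
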