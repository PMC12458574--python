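import numpy as np
import pytest

import ruleshift as rs


@pytest.fixture(scope="session")
def levels():
    return rs.make_default_levels()


@pytest.fixture(scope="session")
def preset_cohort():
    """One default-preset cohort (patient intercept -12, CC weight +3)."""
    ocd, control = rs.default_group_specs()
    return rs.simulate_cohort(ocd, control, seed=2024)


@pytest.fixture(scope="session")
def preset_traces(preset_cohort):
    return rs.cohort_traces(preset_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap 8+8 cohort for structural tests."""
    ocd, control = rs.default_group_specs(n_per_group=8)
    return rs.simulate_cohort(ocd, control, seed=77)


def make_display(*stimuli):
    return rs.StimulusDisplay(tuple(tuple(s) for s in stimuli))
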