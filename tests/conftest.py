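import numpy as np
import pandas as pd
import pytest

import dabold
from dabold.synth import CONDITIONS, GROUPS


@pytest.fixture(scope="session")
def schedule():
    return dabold.make_schedule(dabold.DEFAULT_SCHEDULE_SPEC)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across the session."""
    return dabold.generate_cohort(dabold.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small-grid cohort for fast PLS-level tests."""
    return dabold.generate_cohort(
        dabold.CohortConfig(seed=5, grid_shape=(6, 6, 6), signal_radius_vox=2.0)
    )


def truth_blocks(cohort):
    """BoldBlocks partitioned by the cohort's true groups."""
    groups = np.asarray(cohort.truth["group"])
    blocks = []
    for g in GROUPS:
        subs = list(np.flatnonzero(groups == g))
        for c in CONDITIONS:
            blocks.append(dabold.BoldBlock(group=g, condition=c,
                                           data=cohort.bold[c][subs], subjects=subs))
    return blocks


def truth_da(cohort):
    return pd.DataFrame({"composite": cohort.truth["composite"]})
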