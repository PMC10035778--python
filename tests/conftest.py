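import numpy as np
import pytest

import symptomnet as sn
from symptomnet.items import NODE_LABELS, item_columns


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, small enough for fast unit tests."""
    return sn.generate_cohort(sn.CohortConfig(n_per_arm=300, seed=7))


@pytest.fixture(scope="session")
def item_frames(small_cohort):
    """(session-2 items, final items) with node-name columns."""
    pre = small_cohort[item_columns("s2")].set_axis(NODE_LABELS, axis=1)
    post = small_cohort[item_columns("final")].set_axis(NODE_LABELS, axis=1)
    return pre, post


def change_frames(cohort, baseline="s2"):
    pre = cohort[item_columns(baseline)].set_axis(NODE_LABELS, axis=1)
    post = cohort[item_columns("final")].set_axis(NODE_LABELS, axis=1)
    return pre, post


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230215)
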