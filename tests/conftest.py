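import numpy as np
import pandas as pd
import pytest

import phenotrans as pt
from phenotrans.io import ObservationTable, ProportionMatrix


@pytest.fixture
def space2():
    return pt.build_state_space(["M1"])


@pytest.fixture
def space4():
    return pt.build_state_space(["A", "B"])


@pytest.fixture
def space16():
    return pt.build_state_space(["CD133", "CD44", "CD15", "A2B5"])


@pytest.fixture
def chain2(space2):
    """The 2-state lazy chain with off-diagonals 0.1 / 0.2."""
    return pt.TransitionMatrix(np.array([[0.9, 0.1], [0.2, 0.8]]), space=space2)


@pytest.fixture
def identity_w0():
    def make(space):
        return ProportionMatrix(np.eye(space.n_states), t=0, space=space)

    return make


def make_table(records, value_kind="counts"):
    return ObservationTable(pd.DataFrame.from_records(records), value_kind=value_kind)


@pytest.fixture
def toy_counts_table():
    """2-state counts: from '+': 80/20, from '-': 30/70."""
    recs = []
    for init, plus, minus in [("P1", 80, 20), ("P2", 30, 70)]:
        recs.append(dict(condition="c", initial_state=init, time_days=10,
                         observed_state="P1", value=plus))
        recs.append(dict(condition="c", initial_state=init, time_days=10,
                         observed_state="P2", value=minus))
    return make_table(recs)
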