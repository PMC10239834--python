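import numpy as np
import pytest

from cortexflow import fixtures as fx
from cortexflow import neural_field as nf


@pytest.fixture(scope="session")
def tiny_params():
    return nf.FieldParams(
        dims=3, rf=3, r_exc=1.0, r_inhb=2.0, epochs=2,
        gamma_exc=1.5, gamma_inhb=1.0, inhb_mass=2.0,
        aff_window=(0.0, 0.5), settle_window=(0.1, 1.2),
    )


@pytest.fixture()
def tiny_state(tiny_params):
    return nf.init_field(tiny_params, seed=0)


@pytest.fixture(scope="session")
def dot_seq_0deg():
    return fx.single_dot_sequence(0, 1.0, 5, 15, (2, 2))


def dense_laterals(state):
    """Dense copies of a field's lateral matrices for loop oracles."""
    return state.E.toarray(), state.I.toarray()
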