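import numpy as np
import pytest

from agequant import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_survival_table():
    """Mixed censoring, two groups, small enough to check by hand."""
    from agequant.cls import survival_table

    times = [1, 2, 2, 3, 5, 6, 1, 4, 4, 5, 7, 8]
    events = [True, True, False, True, True, False,
              True, True, True, False, True, True]
    groups = ["a"] * 6 + ["b"] * 6
    return survival_table(times, events, groups)


@pytest.fixture(scope="session")
def null_protein_matrix():
    mat, bound = synth.simulate_protein_matrix(
        n_proteins=200, n_bound=0, missing_model=(-np.inf, 0.0), seed=99
    )
    assert not bound
    return mat
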