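import numpy as np
import pytest

from ssrmine import synthetic_data as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def small_truth():
    """A small noisy simulation shared by read-only tests."""
    params = syn.SimParams(seed=99, n_genes=15)
    truth = syn.simulate_genome(params)
    records, truth = syn.simulate_ests(truth, params)
    return params, truth, records
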