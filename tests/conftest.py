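from dataclasses import replace

import pytest

from watervisits.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact fully-linked synthetic study shared across tests."""
    cfg = replace(SimConfig(), I=4, J=30, K=3, seed=20240101 % 2**31)
    return simulate_dataset(cfg)
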