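import numpy as np
import pandas as pd
import pytest

from mprasplice.simgen import random_contexts


@pytest.fixture(scope="session")
def contexts():
    # keep contexts with >= 35 nt upstream of the donor and >= 30 nt
    # downstream of the acceptor so every designed window fits
    pool = random_contexts(120, "retained_intron", seed=11, intron_bounds=(70, 88))
    picked = [
        c
        for c in pool
        if c.splice_site_positions[0] >= 35
        and len(c.sequence) - c.splice_site_positions[1] >= 30
    ]
    assert len(picked) >= 6
    return picked[:6]


@pytest.fixture(scope="session")
def tandem_contexts():
    pool = random_contexts(40, "tandem5", seed=12)
    picked = [c for c in pool if c.splice_site_positions[0] >= 12]
    assert len(picked) >= 4
    return picked[:4]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
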