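import numpy as np
import pytest

from dyadscan.montage import Montage
from dyadscan.synthetic import CouplingSpec, generate_dyad


@pytest.fixture(scope="session")
def minimal_montages():
    return Montage.standard(1), Montage.standard(1, exclude_regions=("temporal",))


@pytest.fixture(scope="session")
def coupled_session(minimal_montages):
    """One strongly coupled 300-s dyad session (strength 0.8, human leads
    by 2 s) with stored ground-truth envelopes."""
    mh, md = minimal_montages
    session, truth = generate_dyad(
        CouplingSpec(strength=0.8, lag=1000),
        duration=300.0,
        seed=11,
        montage_human=mh,
        montage_dog=md,
    )
    return session, truth


@pytest.fixture(scope="session")
def uncoupled_session(minimal_montages):
    mh, md = minimal_montages
    session, truth = generate_dyad(
        CouplingSpec(strength=0.0),
        duration=300.0,
        seed=12,
        montage_human=mh,
        montage_dog=md,
    )
    return session, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
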