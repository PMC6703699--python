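import pytest

import sinadapt as sa


@pytest.fixture(scope="session")
def single_block_trials():
    """One 75-trial pre-adaptation block + one 384-trial adaptation block
    at 6 cycles per block (the per-condition fitting unit)."""
    return sa.build_session(sa.single_block_design(6))


@pytest.fixture(scope="session")
def freq_trials():
    """The full 2370-trial, 11-block session with adaptation frequencies
    1/3/6/12/24 cycles per block."""
    return sa.build_session(sa.freq_design())


@pytest.fixture(scope="session")
def kam_observer_noisy():
    """One synthetic observer from the retention+drift single-error learner
    (K=0.02, A=0.99, m=-0.004) with sigma=0.1 observation noise."""
    truth = sa.GenerativeParams(K=0.02, A=0.99, m=-0.004)
    return sa.generate_observer(sa.single_block_design(6), "KAm", truth, 0.1, seed=42), truth
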