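import numpy as np
import pytest

from despin import ExchangeSystem, LocalSpinPair


@pytest.fixture
def default_pair() -> LocalSpinPair:
    """The high-spin d5-d6 pair (5/2, 2)."""
    return LocalSpinPair()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220120)


def brute_force_ground_spin(system: ExchangeSystem) -> float:
    """Independent oracle: exhaustive argmin over every (S, branch) energy."""
    best = (np.inf, np.inf)
    for S in system.spins.allowed_spins:
        for sign in (-1.0, +1.0):
            e = -system.J * S * (S + 1.0) + sign * system.B * (S + 0.5)
            if (e, S) < best:
                best = (e, S)
    return best[1]
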