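import numpy as np
import pytest

from foragesim import Arena, generate_sequence


@pytest.fixture(scope="session")
def arena() -> Arena:
    return Arena()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def high_seq(arena):
    """Short repeated-placement sequence (identical trials)."""
    return generate_sequence("high", n_sessions=4, seed=7, snap_to_grid=True)


@pytest.fixture(scope="session")
def medium_seq(arena):
    """Short drifting sequence with per-trial resampled scatter."""
    return generate_sequence(
        "medium", n_sessions=4, seed=8, snap_to_grid=True, resample_scatter=True
    )


@pytest.fixture(scope="session")
def low_seq(arena):
    """Short actively randomized sequence."""
    return generate_sequence("low", n_sessions=4, seed=9, snap_to_grid=True)
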