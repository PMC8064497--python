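import numpy as np
import pytest

from rpwmtr.seqio import EncodedSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_window(rng):
    """A 650-nt window with equiprobable composition."""
    return EncodedSequence("win", rng.integers(1, 5, size=650))


def make_tandem(unit: np.ndarray, copies: int, flank: int = 0,
                rng: np.random.Generator | None = None,
                id: str = "tandem") -> EncodedSequence:
    """A perfect tandem array with optional random flanks."""
    core = np.tile(unit, copies)
    if flank:
        assert rng is not None
        core = np.concatenate([rng.integers(1, 5, flank), core,
                               rng.integers(1, 5, flank)])
    return EncodedSequence(id, core)
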