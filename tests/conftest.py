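import numpy as np
import pytest

from pigexplore import runner


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def embodiment_frames():
    """Per-class embodiment-index batches shared by the learning-curve
    acceptance checks (greedy-PIG vs the unembodied control, 50 worlds
    per class at the class-default horizons)."""
    return {
        cls: runner.embodiment_batch(cls, n_worlds=50, master_seed=7)
        for cls in ("dense", "onetwothree", "maze")
    }
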