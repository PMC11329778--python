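import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_fiber_spec():
    """A fast-to-render fiber field for pipeline smoke tests."""
    from detensio import FiberFieldSpec

    return FiberFieldSpec(
        image_size_px=(128, 128), n_fibers=40, kappa=8.0, seed=7
    )
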