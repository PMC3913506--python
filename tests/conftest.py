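import numpy as np
import pytest

from edopt import (
    CombinatorialLandscape,
    CompoundKey,
    EDOConfig,
    SyntheticLandscapeSpec,
    generate_landscape,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_landscape():
    """3x3 fully observed toy grid with a unique maximum at (2, 3)."""
    values = {
        (1, 1): 1.0, (1, 2): 2.0, (1, 3): 3.0,
        (2, 1): 4.0, (2, 2): 5.0, (2, 3): 9.0,
        (3, 1): 6.0, (3, 2): 7.0, (3, 3): 8.0,
    }
    return CombinatorialLandscape(
        3, 3, {CompoundKey(a, b): v for (a, b), v in values.items()}, name="tiny"
    )


@pytest.fixture(scope="session")
def mmp12_like():
    """Default 50x50 synthetic landscape emulating the MMP-12 test set."""
    return generate_landscape(SyntheticLandscapeSpec(seed=42))


@pytest.fixture(scope="session")
def mmp12_like_run(mmp12_like):
    """One completed default EDO run on the session landscape."""
    from edopt import run_edo

    return run_edo(mmp12_like, EDOConfig(seed=3))
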