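import numpy as np
import pytest

from ab10drive import PRESETS, DriveParams


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def maize_solid():
    return PRESETS["maize_solid"]


@pytest.fixture
def maize_dashed():
    return PRESETS["maize_dashed"]


@pytest.fixture
def mimulus():
    return PRESETS["mimulus"]


def random_params(rng: np.random.Generator, n: int) -> list[DriveParams]:
    """n independent uniform draws of all nine parameters."""
    return [DriveParams(*rng.uniform(0.0, 1.0, 9)) for _ in range(n)]
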