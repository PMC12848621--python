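import numpy as np
import pytest

from mmpolar.core import (
    mueller_depolarizer,
    mueller_diattenuator,
    mueller_retarder,
    mueller_rotator,
)


def random_physical_matrix(rng: np.random.Generator) -> np.ndarray:
    """Random physical Mueller matrix: product of elementary elements with a
    positive overall transmittance scale."""
    depol = mueller_depolarizer(*rng.uniform(0.1, 1.0, size=3))
    ret = mueller_retarder(rng.uniform(0.0, np.pi), rng.uniform(0.0, np.pi))
    rot = mueller_rotator(rng.uniform(0.0, np.pi))
    d = rng.uniform(-0.5, 0.5, size=3)
    d *= rng.uniform(0.0, 0.9) / max(np.linalg.norm(d), 1e-12)
    diatt = mueller_diattenuator(d)
    return rng.uniform(0.2, 1.0) * (depol @ rot @ ret @ diatt)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
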