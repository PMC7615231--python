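import numpy as np
import pytest

from guidenet.model import GuideNet, PolicyPair
from guidenet.simulate import ScanSimConfig, simulate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sequence():
    """One fast synthetic scan with reduced feature dimensionality."""
    return simulate_sequence(ScanSimConfig(T=40, feature_dim=24, seed=7))


@pytest.fixture
def tiny_model():
    """Reduced-width model for functional tests (full widths are exercised
    by the structural checks)."""
    return GuideNet(PolicyPair("OP", "OG"), feature_dim=24, embed=16, hidden=16, proj=24, seed=0)


def quat_to_matrix(q):
    """Independent rotation-matrix construction from a scalar-first unit
    quaternion (textbook formula; the oracle route for quaternion ops)."""
    w, x, y, z = np.asarray(q, dtype=float)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
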