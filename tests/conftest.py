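import numpy as np
import pytest

from ecohab_maxent import HabitatTopology, LocationMatrix, parse_clock


@pytest.fixture(scope="session")
def ring():
    return HabitatTopology.default_ring()


def make_loc(sigma, valid=None, resolution=2.0, t0_clock="13:00", q=4):
    """LocationMatrix from a plain (N, T) label array on a 2-s grid."""
    sigma = np.asarray(sigma, dtype=np.int8)
    n, t = sigma.shape
    if valid is None:
        valid = np.ones((n, t), dtype=bool)
    return LocationMatrix(
        sigma=sigma, valid=np.asarray(valid, bool),
        time_s=resolution * np.arange(t),
        mouse_ids=[f"m{i + 1:02d}" for i in range(n)],
        t0_clock_s=parse_clock(t0_clock), resolution=resolution, q=q,
    )


@pytest.fixture()
def uniform_pair_loc():
    """Two mice cycling so that all 16 joint compartment combinations are
    visited equally often — exactly independent, exactly uniform."""
    t = 1600
    s1 = (np.arange(t) % 4) + 1
    s2 = (np.arange(t) // 4 % 4) + 1
    return make_loc(np.stack([s1, s2]))
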