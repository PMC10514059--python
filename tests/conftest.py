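import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_blob(rng):
    """Small random 8-connected blob grown from a seed pixel."""
    def make(n_pixels=50, shape=(40, 40), seed=0):
        r = np.random.default_rng(seed)
        mask = np.zeros(shape, dtype=bool)
        pos = [(shape[0] // 2, shape[1] // 2)]
        mask[pos[0]] = True
        while mask.sum() < n_pixels:
            i, j = pos[r.integers(len(pos))]
            di, dj = r.integers(-1, 2), r.integers(-1, 2)
            ni, nj = np.clip(i + di, 1, shape[0] - 2), np.clip(j + dj, 1, shape[1] - 2)
            if not mask[ni, nj]:
                mask[ni, nj] = True
                pos.append((ni, nj))
        return mask
    return make
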