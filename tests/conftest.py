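import numpy as np
import pytest

from flashkin import FlashSpec, KokParams, SimConfig, SStateDistribution


@pytest.fixture
def s1():
    """Dark-adapted initial state: 100% S1."""
    return SStateDistribution.pure(1)


@pytest.fixture
def kok_default():
    """Typical miss/double-hit probabilities."""
    return KokParams(miss=0.1, double_hit=0.05)


@pytest.fixture
def config():
    return SimConfig()


@pytest.fixture
def saturating_st():
    """The standard saturating flash: 40 µs at 5% of maximal intensity."""
    return FlashSpec(width=40.0, intensity=0.05)


def local_maxima(series):
    """1-based strict local maxima (independent re-implementation for tests)."""
    s = np.asarray(series, dtype=float)
    out = []
    for i in range(s.size):
        left = s[i - 1] if i > 0 else -np.inf
        right = s[i + 1] if i < s.size - 1 else -np.inf
        if s[i] > left and s[i] > right:
            out.append(i + 1)
    return out
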