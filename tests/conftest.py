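import numpy as np
import pytest
from dataclasses import replace

from wristpulse.synthetic import CohortConfig, default_feature_presets


@pytest.fixture(scope="session")
def presets():
    return default_feature_presets()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free study conditions for ground-truth recovery checks."""
    return replace(CohortConfig(), noise_sd=0.0, wander_amp=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def naive_sample_entropy(y, m, r):
    """Independent O(N^2) template-counting oracle for SampEn.

    Direct transcription of the definition: B counts unordered pairs of
    m-length templates within Chebyshev distance r (self-matches excluded),
    A the same at length m+1; both drawn from the same N-m template starts.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(y[i + k] - y[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(y[i + m] - y[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)
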