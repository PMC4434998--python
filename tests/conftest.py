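import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rearrmap import Sequence

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def brute_force_counts(y: str, k: int) -> dict[tuple[str, str], int]:
    """Independent substring-enumeration oracle for FCM training counts."""
    counts: dict[tuple[str, str], int] = {}
    for i in range(k, len(y)):
        key = (y[i - k : i], y[i])
        counts[key] = counts.get(key, 0) + 1
    return counts


@pytest.fixture
def toy_sequence():
    return Sequence("toy", "ACGTACGT")


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
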