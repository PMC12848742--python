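import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_alignment():
    """Five aligned sequences with known column profiles.

    Columns: 0-3 conserved (M, K, L, V), 4 two-state {A, V},
    5 occurrence-skewed {A x4, V}, 6 gapped {A, A, A, -, -},
    7 three-state {D, E, N, D, E}, 8-9 conserved (G, Y).
    """
    return [
        ("p1", "MKLVAAAD" "GY"),
        ("p2", "MKLVVAAE" "GY"),
        ("p3", "MKLVAAAN" "GY"),
        ("p4", "MKLVVA-D" "GY"),
        ("p5", "MKLVAV-E" "GY"),
    ]
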