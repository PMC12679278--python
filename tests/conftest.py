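import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metgge import from_records

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_dataset():
    """2 genotypes x 2 environments x 2 replicates with hand-computable ANOVA.

    Cells: A-X (10, 12), A-Y (20, 22), B-X (14, 16), B-Y (16, 18); the
    definitional sums of squares are SS_E = 72, SS_G = 0, SS_GE = 32,
    SS_err = 8.
    """
    return from_records(
        [
            ("A", "X", "1", {"t": 10.0}),
            ("A", "X", "2", {"t": 12.0}),
            ("A", "Y", "1", {"t": 20.0}),
            ("A", "Y", "2", {"t": 22.0}),
            ("B", "X", "1", {"t": 14.0}),
            ("B", "X", "2", {"t": 16.0}),
            ("B", "Y", "1", {"t": 16.0}),
            ("B", "Y", "2", {"t": 18.0}),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
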