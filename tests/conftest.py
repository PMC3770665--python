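import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def six_condition_expr():
    """Tiny log2 expression frame with hand-checkable values."""
    return pd.DataFrame(
        {
            "NF0": [8.0, 7.0, 6.0],
            "NF1": [8.1, 7.0, 6.0],
            "RF0": [8.4, 7.0, 6.5],
            "RF1": [8.3, 7.0, 6.5],
            "CF0": [8.2, 7.0, 6.0],
            "CF1": [8.0, 7.0, 6.0],
        },
        index=["g1", "g2", "g3"],
    )
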