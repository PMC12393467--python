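import warnings

import numpy as np
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

# scipy warns about near-identical data in zero-variance t-tests; the code
# under test handles those rows explicitly
warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
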