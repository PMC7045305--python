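import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


def match_events(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.5):
    """Greedy one-to-one matching of detected to ground-truth event times."""
    used = np.zeros(len(truth), dtype=bool)
    tp = fp = 0
    for d in detected:
        idx = np.flatnonzero((np.abs(truth - d) <= tol_s) & ~used)
        if len(idx):
            used[idx[0]] = True
            tp += 1
        else:
            fp += 1
    fn = int((~used).sum())
    return tp, fp, fn
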