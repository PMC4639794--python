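import warnings

import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    """Model enumeration intentionally visits degenerate candidates."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module="statsmodels")
        try:
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
            warnings.filterwarnings("ignore", category=PerfectSeparationWarning)
        except ImportError:
            pass
        yield


def random_dive_trace(rng, n=400, dt=2.0):
    """Random-walk dive-like depth trace for property tests."""
    v = rng.normal(0.3, 0.8, n)
    depth = np.clip(np.cumsum(v) * dt, 0.0, None)
    # force a return to the surface
    k = n // 8
    depth[-k:] = np.maximum(depth[-k] - np.arange(k) * 2.0, 0.0)
    t = np.arange(n) * dt
    return t, depth
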