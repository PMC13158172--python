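"""Shared fixtures and the independent fixed-step integration oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from flashlpl import reference_parameters

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """Reference parameter set (quiescent-niche baseline)."""
    return reference_parameters()


def rk4(f, y0, t0, t1, h):
    """Classical fixed-step 4th-order Runge–Kutta — independent oracle.

    Integrates y' = f(t, y) from t0 to t1 with step at most ``h``; returns
    the terminal state.  Deliberately naive: no adaptivity, no implicit
    stages, so it shares nothing with the production Radau path.
    """
    n = int(np.ceil((t1 - t0) / h))
    h = (t1 - t0) / n
    t = t0
    y = np.asarray(y0, dtype=float)
    for _ in range(n):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y
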