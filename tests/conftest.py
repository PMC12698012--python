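"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from wacsaw.ingest import FirstDiffSeries

START = pd.Timestamp("2024-01-01T00:00:00", tz="UTC")


def lp_transport_cost(x, z, p: float = 1.0) -> float:
    """Optimal-transport cost between two equal-weight empirical samples,
    solved as an explicit linear program on the |xi - zj|^p cost matrix.

    Independent of the sorted-coupling implementation under test.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n, m = len(x), len(z)
    cost = np.abs(x[:, None] - z[None, :]) ** p
    # marginals: rows sum to 1/n, columns to 1/m
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun) ** (1.0 / p)


def make_fd(values, rate_hz: float = 10.0) -> FirstDiffSeries:
    """Wrap a raw dtheta array in a series starting at the reference epoch."""
    return FirstDiffSeries(
        start_time=START + pd.Timedelta(seconds=1.0 / rate_hz),
        rate_hz=rate_hz,
        dtheta=np.asarray(values, dtype=float),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
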