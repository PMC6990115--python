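import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from t3brain.connectivity import BinaryNetwork, ConnectivityMatrix, RoiTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_adjacency(rng, n, p=0.4):
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


def net_from_adj(adj, cost=0.1):
    return BinaryNetwork(np.asarray(adj, dtype=np.int8), cost)


def cm_from_values(z):
    z = np.asarray(z, dtype=float)
    z = (z + z.T) / 2
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z, [f"R{j + 1:03d}" for j in range(z.shape[0])])


def sinusoid_block(freqs_hz, T=120, tr=2.5, subject="sub001", condition="rest"):
    """One block whose regions are pure sinusoids at the given frequencies."""
    t = np.arange(T) * tr
    data = np.column_stack([np.sin(2 * np.pi * f * t + 0.3) for f in freqs_hz])
    return RoiTimeSeries(subject, condition, data, tr)
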