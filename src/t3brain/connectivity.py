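"""Functional connectivity matrices and cost-based binarization.

A connectivity matrix holds pairwise Fisher-z transformed Pearson
correlations between region-wise BOLD time courses.  Binarization keeps a
fixed fraction ("cost") of the strongest possible connections, which makes
networks comparable across subjects independent of overall correlation
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

CONDITIONS = ("rest", "meditation")

#: Pearson r is clamped to +/- this value before the Fisher transform,
#: since atanh diverges at |r| = 1.  Downstream thresholding only uses rank
#: order near the top, so the clamp value is immaterial beyond finiteness.
R_CLAMP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """One subject-condition block of region-averaged BOLD signals.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    condition : str
        Experimental condition, one of ``("rest", "meditation")``.
    data : ndarray, shape (T, J)
        Signal matrix, T time points by J regions.  Units are arbitrary.
    tr : float
        Sampling interval (repetition time) in seconds.
    region_names : list of str
        Unique region labels, length J.
    """

    subject_id: str
    condition: str
    data: np.ndarray
    tr: float
    region_names: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x J matrix")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.data.shape[0] < 8:
            raise ValueError(f"need at least 8 time points, got {self.data.shape[0]}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains missing or non-finite values")
        if not self.region_names:
            self.region_names = [f"R{j + 1:03d}" for j in range(self.data.shape[1])]
        if len(self.region_names) != self.data.shape[1]:
            raise ValueError("region_names length does not match number of columns")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region_names must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class ConnectivityMatrix:
    """Symmetric J x J matrix of Fisher-z correlations; diagonal excluded (NaN)."""

    z: np.ndarray
    region_names: list

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        J = self.z.shape[0]
        if self.z.shape != (J, J):
            raise ValueError("z must be square")
        off = ~np.eye(J, dtype=bool)
        if not np.allclose(self.z[off], self.z.T[off], equal_nan=True):
            raise ValueError("z must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.region_names, columns=self.region_names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="region")

    def to_edge_list(self, path) -> None:
        i, j = np.triu_indices(self.n_regions, k=1)
        pd.DataFrame(
            {
                "region_i": [self.region_names[a] for a in i],
                "region_j": [self.region_names[b] for b in j],
                "z": self.z[i, j],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class BinaryNetwork:
    """Cost-thresholded adjacency matrix (0/1, symmetric, no self-loops)."""

    adjacency: np.ndarray
    cost: float
    region_names: list = field(default_factory=list)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not self.region_names:
            self.region_names = [f"R{j + 1:03d}" for j in range(self.adjacency.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.adjacency, index=self.region_names, columns=self.region_names).to_csv(
            path, sep="\t", index_label="region"
        )


def bandpass(ts: RoiTimeSeries, low: float, high: float) -> RoiTimeSeries:
    """Band-pass filter each region's signal with a frequency-domain mask.

    The series is linearly detrended, Fourier transformed, components at
    frequencies outside ``[low, high]`` (and the DC component) are zeroed,
    and the signal is transformed back.  The output is therefore mean-free.

    Parameters
    ----------
    ts : RoiTimeSeries
    low, high : float
        Pass band in Hz; requires ``0 <= low < high <= 1/(2*tr)``.
    """
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    if high > ts.nyquist + 1e-12:
        raise ValueError(f"high={high} Hz exceeds Nyquist frequency {ts.nyquist} Hz")
    T = ts.n_timepoints
    x = signal.detrend(ts.data, axis=0, type="linear")
    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(T, d=ts.tr)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    keep[0] = False  # DC always removed
    spec[~keep, :] = 0.0
    y = np.fft.irfft(spec, n=T, axis=0)
    return RoiTimeSeries(ts.subject_id, ts.condition, y, ts.tr, list(ts.region_names))


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlations between all region pairs, Fisher-z transformed.

    r is clamped to ``+/-(1 - 1e-7)`` before ``atanh``; the diagonal is set
    to NaN and is excluded from all downstream thresholding and metrics.
    """
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.region_names[j] for j in dead]
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z, list(ts.region_names))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def binarize_by_cost(cm: ConnectivityMatrix, cost: float) -> BinaryNetwork:
    """Keep the ``round(cost * J(J-1)/2)`` strongest connections.

    Ties at the cutoff are broken by ascending lexicographic (i, j) order of
    the upper-triangle pair, so the output is deterministic and edge sets
    are nested across increasing costs.
    """
    if not (0 < cost <= 1):
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    J = cm.n_regions
    n_possible = J * (J - 1) // 2
    m = _round_half_away(cost * n_possible)
    iu, ju = np.triu_indices(J, k=1)
    zv = cm.z[iu, ju]
    # sort by z descending, then (i, j) ascending
    order = np.lexsort((ju, iu, -zv))
    keep = order[:m]
    adj = np.zeros((J, J), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, cost, list(cm.region_names))
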