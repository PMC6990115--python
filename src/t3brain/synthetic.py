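"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided.  The tensor generator inverts the Tucker3
model directly — it plants a known region support, metric carrier, and
class separation, then adds Gaussian noise — so the solver and the
permutation inference can be validated against exact ground truth.  The
time-series generator emulates the measured data: per subject, two 5-min
blocks (rest and meditation) of band-limited, covariance-structured
Gaussian signals at TR = 2.5 s over 116 regions, with a planted condition
effect that raises the pairwise correlation (and hence the thresholded
clustering coefficient) of a designated region subset during meditation.

Neither generator is calibrated to any real recording; both are stand-ins
whose purpose is known ground truth, as documented in docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import CONDITIONS, RoiTimeSeries
from .feature_tensor import METRIC_ORDER, FeatureTensor


def _default_region_names(J: int) -> list:
    return [f"R{j + 1:03d}" for j in range(J)]


def _subject_ids(n: int) -> list:
    return [f"sub{s + 1:03d}" for s in range(n)]


# ---------------------------------------------------------------------------
# tensor-level generator
# ---------------------------------------------------------------------------


@dataclass
class TensorSynthSpec:
    """Planted Tucker3 model: I = 2*n_subjects observations, J regions,
    K metrics, a region subset carrying the condition effect on one metric,
    class separation delta along the first component, and i.i.d. Gaussian
    noise with standard deviation sigma.  Indices are 0-based."""

    n_subjects: int = 29
    J: int = 116
    K: int = 4
    planted_region_set: tuple = tuple(range(8))
    planted_metric_index: int = METRIC_ORDER.index("clustering")
    delta: float = 1.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.J < 1 or self.K < 1:
            raise ValueError("n_subjects, J, K must be positive")
        rs = tuple(sorted(set(self.planted_region_set)))
        if not rs or min(rs) < 0 or max(rs) >= self.J:
            raise ValueError("planted_region_set must be a nonempty subset of 0..J-1")
        if len(rs) >= self.J:
            raise ValueError("planted_region_set must leave at least one region free")
        self.planted_region_set = rs
        if not (0 <= self.planted_metric_index < self.K):
            raise ValueError("planted_metric_index out of range")
        if self.delta < 0 or self.sigma < 0:
            raise ValueError("delta and sigma must be non-negative")


@dataclass
class TensorGroundTruth:
    """Planted loadings and labels used to build a synthetic tensor."""

    B: np.ndarray
    C: np.ndarray
    Y: np.ndarray
    labels: list
    planted_region_set: tuple
    planted_metric_index: int


def generate_feature_tensor(spec: TensorSynthSpec) -> tuple[FeatureTensor, TensorGroundTruth]:
    """Draw X = U Y (C kron B)^T + sigma*E from the planted model.

    B's first column is the unit-normalized indicator of the planted region
    set, its second the normalized indicator of the complement; C is the
    unit vector on the planted metric.  The class centroids are separated
    by ``delta`` along the first component only; the second component is a
    class-common baseline of magnitude delta/4, which makes the planted
    two-dimensional region subspace identifiable whenever delta > 0 while
    leaving the second component non-discriminative (and removable by
    column standardization).  With delta = 0 the centroid core is zero and
    the condition labels are fully exchangeable.
    """
    rng = np.random.default_rng(spec.seed)
    J, K = spec.J, spec.K
    planted = np.array(spec.planted_region_set)
    other = np.setdiff1d(np.arange(J), planted)

    B = np.zeros((J, 2))
    B[planted, 0] = 1.0 / np.sqrt(len(planted))
    B[other, 1] = 1.0 / np.sqrt(len(other))
    C = np.zeros((K, 1))
    C[spec.planted_metric_index, 0] = 1.0
    # rows = classes (rest, meditation); columns = components (q1, q2);
    # the Y columns are orthogonal with distinct norms, so the fitted
    # first component aligns with the planted region set
    d = spec.delta
    Y = np.array([[d / 2.0, d / 4.0], [-d / 2.0, d / 4.0]])

    subjects = _subject_ids(spec.n_subjects)
    obs_index = [(s, c) for s in subjects for c in CONDITIONS]
    labels = [c for _, c in obs_index]
    U = np.array([[1.0, 0.0] if c == "rest" else [0.0, 1.0] for c in labels])

    I = 2 * spec.n_subjects
    X_mat = U @ Y @ np.kron(C, B).T + spec.sigma * rng.standard_normal((I, J * K))
    X = X_mat.reshape(I, K, J).transpose(0, 2, 1)
    tensor = FeatureTensor(
        X, obs_index, _default_region_names(J), list(METRIC_ORDER[:K]) if K <= 4 else [f"M{k+1}" for k in range(K)]
    )
    truth = TensorGroundTruth(B, C, Y, labels, spec.planted_region_set, spec.planted_metric_index)
    return tensor, truth


# ---------------------------------------------------------------------------
# time-series-level generator
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesSynthSpec:
    """Covariance-structured, band-limited Gaussian BOLD surrogate.

    Regions are partitioned into contiguous blocks of ``block_size`` with
    within-block correlation ``rho0`` and a small between-block level
    ``eps``; during meditation the pairwise correlation among
    ``effect_region_set`` is raised to ``rho1``.  Each region's spectrum is
    shaped so that approximately ``band_power_fraction`` of its DFT
    amplitude falls inside ``band``.  Defaults mirror the study layout:
    29 subjects, 116 regions, 120 volumes at TR = 2.5 s, band
    0.008-0.09 Hz.
    """

    n_subjects: int = 29
    J: int = 116
    T: int = 120
    TR: float = 2.5
    rho0: float = 0.1
    rho1: float = 0.9
    effect_region_set: tuple = tuple(range(8))
    band: tuple = (0.008, 0.09)
    band_power_fraction: float = 0.85
    block_size: int = 8
    eps: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.J < 2 or self.T < 8:
            raise ValueError("need n_subjects >= 1, J >= 2, T >= 8")
        if not (0 <= self.rho0 < 1) or not (self.rho0 <= self.rho1 < 1):
            raise ValueError("need 0 <= rho0 <= rho1 < 1")
        es = tuple(sorted(set(self.effect_region_set)))
        if not es or min(es) < 0 or max(es) >= self.J:
            raise ValueError("effect_region_set must be a nonempty subset of 0..J-1")
        self.effect_region_set = es
        low, high = self.band
        if not (0 < low < high <= 1.0 / (2.0 * self.TR) + 1e-12):
            raise ValueError("band must lie within (0, Nyquist]")
        if not (0 < self.band_power_fraction <= 1):
            raise ValueError("band_power_fraction must be in (0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")


@dataclass
class TimeSeriesGroundTruth:
    """What was planted: effect regions, correlation levels, band target."""

    effect_region_set: tuple
    rho0: float
    rho1: float
    band: tuple
    band_power_fraction: float
    region_names: list


def _block_correlation(spec: TimeSeriesSynthSpec, condition: str) -> np.ndarray:
    J = spec.J
    R = np.full((J, J), spec.eps)
    for start in range(0, J, spec.block_size):
        stop = min(start + spec.block_size, J)
        R[start:stop, start:stop] = spec.rho0
    if condition == "meditation":
        idx = np.array(spec.effect_region_set)
        R[np.ix_(idx, idx)] = spec.rho1
    np.fill_diagonal(R, 1.0)
    return R


def _spectral_gain(spec: TimeSeriesSynthSpec) -> np.ndarray:
    """Per-rfft-bin gain putting ~band_power_fraction of amplitude in band."""
    freqs = np.fft.rfftfreq(spec.T, d=spec.TR)
    low, high = spec.band
    in_band = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    in_band[0] = False
    n_in = int(in_band[1:].sum())
    n_out = int((~in_band)[1:].sum())
    p = spec.band_power_fraction
    if n_out == 0 or p >= 1.0:
        s = 0.0
    else:
        # expected amplitude per bin is uniform for white noise, so the
        # in-band fraction is n_in / (n_in + s * n_out)
        s = n_in * (1.0 - p) / (p * n_out)
    gain = np.where(in_band, 1.0, s)
    gain[0] = 0.0
    return gain


def _shaped_noise(rng: np.random.Generator, T: int, J: int, gain: np.ndarray) -> np.ndarray:
    Z = rng.standard_normal((T, J))
    spec = np.fft.rfft(Z, axis=0) * gain[:, None]
    Y = np.fft.irfft(spec, n=T, axis=0)
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    return Y / sd


def generate_timeseries_dataset(
    spec: TimeSeriesSynthSpec,
) -> tuple[list[RoiTimeSeries], TimeSeriesGroundTruth]:
    """Generate 2*n_subjects blocks (rest, meditation per subject).

    Signals are white Gaussian noise shaped in the frequency domain (same
    filter for every region, which preserves the cross-region correlation
    structure) and then mixed by the Cholesky factor of the block
    correlation matrix.  Condition blocks are generated independently per
    subject.  Non-positive-semidefinite correlation matrices are rejected
    with an error naming the offending parameters.
    """
    rng = np.random.default_rng(spec.seed)
    region_names = _default_region_names(spec.J)
    gain = _spectral_gain(spec)

    chol = {}
    for cond in CONDITIONS:
        R = _block_correlation(spec, cond)
        w = np.linalg.eigvalsh(R)
        if w[0] < -1e-10:
            raise ValueError(
                f"correlation matrix for condition {cond!r} is not positive "
                f"semi-definite (min eigenvalue {w[0]:.3e}); check rho0={spec.rho0}, "
                f"rho1={spec.rho1}, eps={spec.eps}, block_size={spec.block_size}"
            )
        # tiny ridge so Cholesky succeeds at the PSD boundary
        chol[cond] = np.linalg.cholesky(R + 1e-10 * np.eye(spec.J))

    blocks = []
    for sid in _subject_ids(spec.n_subjects):
        for cond in CONDITIONS:
            Z = _shaped_noise(rng, spec.T, spec.J, gain)
            data = Z @ chol[cond].T
            blocks.append(RoiTimeSeries(sid, cond, data, spec.TR, list(region_names)))
    truth = TimeSeriesGroundTruth(
        spec.effect_region_set, spec.rho0, spec.rho1, spec.band, spec.band_power_fraction, region_names
    )
    return blocks, truth


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------


def write_dataset(blocks: list[RoiTimeSeries], truth, out_dir) -> Path:
    """Write per-block TSVs, a manifest TSV, and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for b in blocks:
        fname = f"{b.subject_id}_{b.condition}.tsv"
        pd.DataFrame(b.data, columns=b.region_names).to_csv(out / fname, sep="\t", index=False)
        manifest.append((fname, b.subject_id, b.condition, b.tr))
    pd.DataFrame(manifest, columns=["file", "subject_id", "condition", "tr"]).to_csv(
        out / "manifest.tsv", sep="\t", index=False
    )
    if truth is not None:
        payload = {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in vars(truth).items()
            if not isinstance(v, np.ndarray)
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    return out


def read_dataset(in_dir) -> list[RoiTimeSeries]:
    """Read a dataset written by :func:`write_dataset` (or hand-built to the
    same manifest layout)."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    blocks = []
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(in_dir / row.file, sep="\t")
        blocks.append(
            RoiTimeSeries(str(row.subject_id), row.condition, df.to_numpy(), float(row.tr), list(df.columns))
        )
    return blocks
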