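"""Three-way feature array (observations x regions x metrics).

Each observation is one subject-condition block; the metric axis has the
fixed order (degree, betweenness, clustering, falff) so that loadings are
comparable across runs.  Matricization unfolds the array into an
I x (J*K) matrix whose column for (region j, metric k) is k*J + j —
region fastest, metric slowest — matching the Kronecker layout C (x) B
used by the Tucker3 model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import CONDITIONS

METRIC_ORDER = ("degree", "betweenness", "clustering", "falff")

LONG_COLUMNS = ["subject_id", "condition", "region", "metric", "value"]


@dataclass
class FeatureTensor:
    """I x J x K array of per-observation region-by-metric features."""

    X: np.ndarray
    observation_index: list  # list of (subject_id, condition)
    region_names: list
    metric_names: list
    standardized: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        I, J, K = self.X.shape
        if len(self.observation_index) != I:
            raise ValueError("observation_index length must equal I")
        if len(self.region_names) != J or len(self.metric_names) != K:
            raise ValueError("axis name lengths inconsistent with X shape")
        subjects = {s for s, _ in self.observation_index}
        if I != 2 * len(subjects):
            raise ValueError("each subject must appear exactly once per condition")

    @property
    def shape(self):
        return self.X.shape

    @property
    def labels(self) -> list:
        """Condition label per observation row."""
        return [c for _, c in self.observation_index]

    def to_long(self) -> pd.DataFrame:
        I, J, K = self.X.shape
        rows = []
        for i, (sid, cond) in enumerate(self.observation_index):
            for k, metric in enumerate(self.metric_names):
                for j, region in enumerate(self.region_names):
                    rows.append((sid, cond, region, metric, self.X[i, j, k]))
        return pd.DataFrame(rows, columns=LONG_COLUMNS)


def assemble(table: pd.DataFrame, metric_names=METRIC_ORDER) -> FeatureTensor:
    """Build the tensor from a long-format table.

    ``table`` must have columns subject_id, condition, region, metric,
    value, with every (subject, condition, region, metric) cell present
    exactly once.  Observation rows are ordered by subject_id ascending
    with rest before meditation; regions keep their sorted-first-appearance
    order from the table.
    """
    missing_cols = set(LONG_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"table missing columns {sorted(missing_cols)}")
    subjects = sorted(table["subject_id"].unique())
    regions = sorted(table["region"].unique())
    conditions = [c for c in CONDITIONS if c in set(table["condition"])]
    if set(table["condition"]) - set(CONDITIONS):
        raise ValueError(f"unknown condition(s): {set(table['condition']) - set(CONDITIONS)}")

    obs_index = [(s, c) for s in subjects for c in CONDITIONS]
    I, J, K = len(obs_index), len(regions), len(metric_names)
    X = np.full((I, J, K), np.nan)
    obs_pos = {sc: i for i, sc in enumerate(obs_index)}
    reg_pos = {r: j for j, r in enumerate(regions)}
    met_pos = {m: k for k, m in enumerate(metric_names)}

    unknown_metrics = set(table["metric"]) - set(metric_names)
    if unknown_metrics:
        raise ValueError(f"unknown metric(s): {sorted(unknown_metrics)}")
    dup = table.duplicated(subset=["subject_id", "condition", "region", "metric"])
    if dup.any():
        cell = table.loc[dup.idxmax(), ["subject_id", "condition", "region", "metric"]]
        raise ValueError(f"duplicate cell: {tuple(cell)}")
    for sid, cond, region, metric, value in table[LONG_COLUMNS].itertuples(index=False):
        X[obs_pos[(sid, cond)], reg_pos[region], met_pos[metric]] = value
    if np.isnan(X).any():
        i, j, k = np.argwhere(np.isnan(X))[0]
        raise ValueError(
            f"missing cell: {obs_index[i] + (regions[j], metric_names[k])}"
        )
    return FeatureTensor(X, obs_index, regions, list(metric_names))


def standardize(t: FeatureTensor) -> FeatureTensor:
    """Z-score each (region, metric) column across observations.

    Columns with zero variance are set to all-zero with a warning.  The
    tensor must not already be standardized.
    """
    if t.standardized:
        raise ValueError("tensor is already standardized")
    mu = t.X.mean(axis=0)
    sd = t.X.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance (region, metric) column(s) set to 0")
    sd_safe = np.where(zero, 1.0, sd)
    Z = (t.X - mu) / sd_safe
    Z[:, zero] = 0.0
    return replace(t, X=Z, standardized=True)


def matricize(t: FeatureTensor) -> np.ndarray:
    """Unfold to I x (J*K); column of (region j, metric k) is k*J + j."""
    I, J, K = t.X.shape
    return t.X.transpose(0, 2, 1).reshape(I, J * K)


def refold(mat: np.ndarray, J: int, K: int) -> np.ndarray:
    """Inverse of :func:`matricize`: I x (J*K) back to I x J x K."""
    I = mat.shape[0]
    if mat.shape[1] != J * K:
        raise ValueError("column count does not equal J*K")
    return mat.reshape(I, K, J).transpose(0, 2, 1)
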