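"""Statistical inference on the fitted model and baseline comparisons.

The main tool is a permutation test on the absolute first-component
loadings: condition labels are permuted, the supervised Tucker3 model is
refitted for every permutation, and an element's p-value is the
(add-one-corrected) fraction of permuted |loadings| at least as large as
the observed one.  Region and metric loadings are tested separately, with
no multiple-testing correction by default (an optional BH mode exists).
A paired t-test with Benjamini-Hochberg correction over all
(region, metric) cells serves as the conventional mass-univariate
baseline, and overlap ratios quantify how stably regions are selected
across the cost grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import CONDITIONS
from .feature_tensor import FeatureTensor, matricize
from .t3clus import ScoreMatrix, TuckerConfig, _fit_arrays, build_indicator, fit

PERMUTATION_SCHEMES = ("within_subject", "free")


@dataclass
class PermutationResult:
    """Per-region and per-metric permutation p-values on |first-component
    loadings|, with the elements below alpha flagged significant."""

    region_pvalues: np.ndarray
    metric_pvalues: np.ndarray
    region_names: list
    metric_names: list
    observed_region_loadings: np.ndarray
    observed_metric_loadings: np.ndarray
    n_perm: int
    scheme: str
    seed: int
    alpha: float = 0.05

    @property
    def significant_regions(self) -> list:
        return [n for n, p in zip(self.region_names, self.region_pvalues) if p < self.alpha]

    @property
    def significant_metrics(self) -> list:
        return [n for n, p in zip(self.metric_names, self.metric_pvalues) if p < self.alpha]

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_names,
                "loading": self.observed_region_loadings,
                "p": self.region_pvalues,
            }
        )

    def metric_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric_names,
                "loading": self.observed_metric_loadings,
                "p": self.metric_pvalues,
            }
        )


def _permuted_labels(rng: np.random.Generator, labels: list, subjects: np.ndarray, scheme: str) -> list:
    labels = list(labels)
    if scheme == "within_subject":
        out = list(labels)
        for s in np.unique(subjects):
            idx = np.flatnonzero(subjects == s)
            if rng.random() < 0.5:
                for a in idx:
                    out[a] = CONDITIONS[1] if labels[a] == CONDITIONS[0] else CONDITIONS[0]
        return out
    # free: uniform relabeling preserving class sizes
    perm = rng.permutation(len(labels))
    return [labels[p] for p in perm]


def permutation_test(
    tensor: FeatureTensor,
    config: TuckerConfig | None = None,
    n_perm: int = 10000,
    scheme: str = "within_subject",
    seed: int = 0,
    alpha: float = 0.05,
    correct: str | None = None,
) -> PermutationResult:
    """Permutation test on absolute first-component loadings.

    For each of ``n_perm`` permutations the condition labels are permuted
    (``within_subject``: each subject's two labels are swapped with
    probability 1/2, respecting the paired design; ``free``: a uniform
    relabeling preserving class sizes), the supervised model is refitted,
    and |first-component| region and metric loadings are recorded.
    p = (1 + #{|perm| >= |obs|}) / (n_perm + 1), so the smallest attainable
    p-value is 1/(n_perm+1).  ``correct="bh"`` optionally applies a
    Benjamini-Hochberg adjustment within regions and within metrics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in PERMUTATION_SCHEMES:
        raise ValueError(f"scheme must be one of {PERMUTATION_SCHEMES}")
    if config is None:
        config = TuckerConfig()
    rng = np.random.default_rng(seed)

    X_mat = matricize(tensor)
    I, J, K = tensor.shape
    labels = tensor.labels
    subjects = np.array([s for s, _ in tensor.observation_index])

    observed = fit(tensor, build_indicator(labels, config.G), config)
    obs_b = np.abs(observed.B[:, 0])
    obs_c = np.abs(observed.C[:, 0])

    count_b = np.ones(J)
    count_c = np.ones(K)
    for _ in range(n_perm):
        plabels = _permuted_labels(rng, labels, subjects, scheme)
        U = build_indicator(plabels, config.G)
        res = _fit_arrays(X_mat, U, J, K, config)
        count_b += np.abs(res.B[:, 0]) >= obs_b
        count_c += np.abs(res.C[:, 0]) >= obs_c
    p_b = count_b / (n_perm + 1)
    p_c = count_c / (n_perm + 1)
    if correct == "bh":
        p_b = multipletests(p_b, method="fdr_bh")[1]
        p_c = multipletests(p_c, method="fdr_bh")[1]
    elif correct is not None:
        raise ValueError(f"unknown correction {correct!r}")
    return PermutationResult(
        p_b,
        p_c,
        list(tensor.region_names),
        list(tensor.metric_names),
        obs_b,
        obs_c,
        n_perm,
        scheme,
        seed,
        alpha,
    )


def score_condition_test(scores: ScoreMatrix, observation_index) -> pd.DataFrame:
    """Paired t-test on raw component scores between the two conditions.

    Differences are taken per subject (meditation minus rest) for each
    component column; returns a DataFrame with component, t, df, p.
    """
    raw = scores.raw_scores
    idx = {sc: i for i, sc in enumerate(observation_index)}
    subjects = sorted({s for s, _ in observation_index})
    rest = np.array([raw[idx[(s, "rest")]] for s in subjects])
    med = np.array([raw[idx[(s, "meditation")]] for s in subjects])
    diffs = med - rest
    rows = []
    for comp in range(raw.shape[1]):
        d = diffs[:, comp]
        if np.std(d, ddof=1) == 0:
            if np.allclose(d, 0):
                # identical scores in both conditions: no effect at all
                rows.append((comp + 1, 0.0, len(subjects) - 1, 1.0))
                continue
            raise ValueError(f"zero variance of paired differences for component {comp + 1}")
        t, p = stats.ttest_rel(med[:, comp], rest[:, comp])
        rows.append((comp + 1, float(t), len(subjects) - 1, float(p)))
    return pd.DataFrame(rows, columns=["component", "t", "df", "p"])


def paired_ttest_features(tensor: FeatureTensor, alpha: float = 0.05) -> pd.DataFrame:
    """Mass-univariate baseline: paired t-test per (region, metric) cell.

    Tests meditation vs rest across subjects for every cell of the
    (raw-scale) tensor, then applies Benjamini-Hochberg FDR correction
    across all J*K tests.  Cells with zero-variance differences get p = 1
    with a warning.  Returns region, metric, t, p, q, significant.
    """
    I, J, K = tensor.shape
    idx = {sc: i for i, sc in enumerate(tensor.observation_index)}
    subjects = sorted({s for s, _ in tensor.observation_index})
    rest = np.array([tensor.X[idx[(s, "rest")]] for s in subjects])
    med = np.array([tensor.X[idx[(s, "meditation")]] for s in subjects])
    diffs = med - rest  # n_subjects x J x K

    t_mat = np.zeros((J, K))
    p_mat = np.ones((J, K))
    degenerate = 0
    for j in range(J):
        for k in range(K):
            d = diffs[:, j, k]
            if np.std(d, ddof=1) == 0:
                degenerate += 1
                t_mat[j, k] = 0.0 if np.allclose(d, 0) else np.inf
                p_mat[j, k] = 1.0
                continue
            t, p = stats.ttest_rel(med[:, j, k], rest[:, j, k])
            t_mat[j, k] = t
            p_mat[j, k] = p
    if degenerate:
        warnings.warn(f"{degenerate} cell(s) had zero-variance differences; p set to 1")
    q = multipletests(p_mat.ravel(), method="fdr_bh")[1].reshape(J, K)
    rows = []
    for j, region in enumerate(tensor.region_names):
        for k, metric in enumerate(tensor.metric_names):
            rows.append((region, metric, t_mat[j, k], p_mat[j, k], q[j, k], q[j, k] < alpha))
    return pd.DataFrame(rows, columns=["region", "metric", "t", "p", "q", "significant"])


def overlap_ratio(
    selected_sets: dict,
    grid,
    lower_range: tuple = (0.050, 0.225),
) -> pd.DataFrame:
    """Fraction of cost settings at which each region was selected.

    ``selected_sets`` maps each grid cost to the set of regions selected at
    that cost.  Sub-range ratios split the grid at ``lower_range`` (the
    lower and higher ratios use their own sub-range sizes as denominators).
    Returns region, count, ratio, lower_ratio, higher_ratio.
    """
    costs = list(getattr(grid, "costs", grid))
    missing = [c for c in costs if c not in selected_sets]
    if missing:
        raise ValueError(f"no selection set for cost(s) {missing}")
    lo, hi = lower_range
    lower = [c for c in costs if lo - 1e-9 <= c <= hi + 1e-9]
    higher = [c for c in costs if c > hi + 1e-9]
    regions = sorted(set().union(*[set(selected_sets[c]) for c in costs]) or set())
    rows = []
    for r in regions:
        cnt = sum(r in selected_sets[c] for c in costs)
        cnt_lo = sum(r in selected_sets[c] for c in lower)
        cnt_hi = sum(r in selected_sets[c] for c in higher)
        rows.append(
            (
                r,
                cnt,
                cnt / len(costs),
                cnt_lo / len(lower) if lower else np.nan,
                cnt_hi / len(higher) if higher else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["region", "count", "ratio", "lower_ratio", "higher_ratio"])
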