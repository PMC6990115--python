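"""Cost-threshold selection over a grid of network densities.

A single cost is chosen by three criteria applied across all
subject-condition networks: (1) small-world feasibility — group-mean
global efficiency must lie strictly between that of an edge-matched ring
lattice and a degree-matched random graph; (2) similarity — the cost whose
degree distribution correlates best with each subject's cost-averaged
degree distribution; (3) stability — low standard deviation of the number
of detected communities across participants.  Criteria 2 and 3 are
combined by rank sum (ties resolved toward the smaller cost), a rule that
is configurable because no canonical combination exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import CONDITIONS, ConnectivityMatrix, binarize_by_cost
from .graph_metrics import degree_centrality, global_efficiency, newman_communities, reference_graph

DEFAULT_COSTS = tuple(np.round(0.050 + 0.025 * np.arange(19), 3))


@dataclass
class CostGrid:
    """Ordered cost settings; default 0.050 to 0.500 in steps of 0.025."""

    costs: tuple = DEFAULT_COSTS

    def __post_init__(self):
        c = np.asarray(self.costs, dtype=float)
        if c.size == 0 or np.any(np.diff(c) <= 0):
            raise ValueError("costs must be strictly increasing and nonempty")
        if np.any((c <= 0) | (c >= 1)):
            raise ValueError("costs must lie in (0, 1)")
        self.costs = tuple(float(x) for x in c)

    def __len__(self):
        return len(self.costs)


@dataclass
class CostSelectionReport:
    """Per-cost criteria values and the selected cost."""

    table: pd.DataFrame  # cost, feasible, similarity, stability_sd, rank_sum
    selected_cost: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


Dataset = dict  # (subject_id, condition) -> ConnectivityMatrix


def _check_dataset(dataset: Dataset) -> None:
    if not dataset:
        raise ValueError("dataset is empty")
    for key, cm in dataset.items():
        if not isinstance(cm, ConnectivityMatrix):
            raise TypeError(f"dataset[{key!r}] is not a ConnectivityMatrix")


def smallworld_feasible_costs(
    dataset: Dataset,
    grid: CostGrid,
    n_realizations: int = 20,
    seed: int | None = None,
) -> list[float]:
    """Costs where group-mean efficiency satisfies E_lattice < E_obs < E_random.

    For every cost, every subject-condition matrix is thresholded and its
    global efficiency compared with the mean efficiency of
    ``n_realizations`` degree-preserving random rewirings and an
    edge-matched deterministic ring lattice; the comparison uses group
    means over all subject-condition networks.
    """
    _check_dataset(dataset)
    rng = np.random.default_rng(seed)
    feasible = []
    for cost in grid.costs:
        e_obs, e_rand, e_latt = [], [], []
        for cm in dataset.values():
            net = binarize_by_cost(cm, cost)
            e_obs.append(global_efficiency(net))
            rands = reference_graph(net, "random", n_realizations, seed=int(rng.integers(0, 2**31 - 1)))
            e_rand.append(float(np.mean([global_efficiency(g) for g in rands])))
            e_latt.append(global_efficiency(reference_graph(net, "lattice", 1)[0]))
        if float(np.mean(e_latt)) < float(np.mean(e_obs)) < float(np.mean(e_rand)):
            feasible.append(cost)
    if not feasible:
        raise ValueError(
            "no cost satisfied the small-world criterion; widen the cost grid "
            "or check the input networks"
        )
    return feasible


def degree_similarity_score(dataset: Dataset, costs) -> dict[float, float]:
    """Mean correlation of each cost's degree vector with the cost-averaged one.

    Per subject-condition network the degree vector is computed at every
    cost, averaged across costs, and each per-cost vector is Pearson-
    correlated with that average; scores are means over subject-condition
    networks.  A grid of one cost scores 1 by convention.
    """
    _check_dataset(dataset)
    costs = list(costs)
    per_cost: dict[float, list] = {c: [] for c in costs}
    for cm in dataset.values():
        D = np.array([degree_centrality(binarize_by_cost(cm, c)).values for c in costs])
        avg = D.mean(axis=0)
        for c, vec in zip(costs, D):
            if len(costs) == 1:
                per_cost[c].append(1.0)
            elif np.std(vec) == 0 or np.std(avg) == 0:
                warnings.warn(f"constant degree vector at cost {c}; correlation set to 0")
                per_cost[c].append(0.0)
            else:
                per_cost[c].append(float(np.corrcoef(vec, avg)[0, 1]))
    return {c: float(np.mean(v)) for c, v in per_cost.items()}


def community_stability_score(dataset: Dataset, costs, gamma: float = 1.0) -> dict[float, float]:
    """Per-cost sample standard deviation (ddof=1) of the community count
    across participants, computed within each condition and then averaged
    over the two conditions (lower = more stable)."""
    _check_dataset(dataset)
    costs = list(costs)
    out = {}
    for c in costs:
        sds = []
        for cond in CONDITIONS:
            counts = [
                newman_communities(binarize_by_cost(cm, c), gamma).n_communities
                for (sid, cnd), cm in dataset.items()
                if cnd == cond
            ]
            if len(counts) >= 2:
                sds.append(float(np.std(counts, ddof=1)))
            elif counts:
                sds.append(0.0)
        out[c] = float(np.mean(sds)) if sds else 0.0
    return out


def _ordinal_ranks(values, descending: bool) -> np.ndarray:
    """Competition ('min') ranks, 1 = best."""
    v = np.asarray(values, dtype=float)
    key = -v if descending else v
    ranks = np.empty(len(v), dtype=int)
    for i, x in enumerate(key):
        ranks[i] = 1 + int(np.sum(key < x))
    return ranks


def combine_criteria(feasible, sim: dict, stab: dict, rule: str = "rank_sum"):
    """Pick one cost from per-cost similarity (higher better) and stability
    SD (lower better).  Returns (selected_cost, rank_sum array).

    "rank_sum" minimizes the sum of the two competition ranks;
    "similarity_first" / "stability_first" use a single criterion.  All
    ties resolve toward the smaller cost.
    """
    if rule not in ("rank_sum", "similarity_first", "stability_first"):
        raise ValueError(f"unknown rule {rule!r}")
    feasible = list(feasible)
    r_sim = _ordinal_ranks([sim[c] for c in feasible], descending=True)
    r_stab = _ordinal_ranks([stab[c] for c in feasible], descending=False)
    rank_sum = r_sim + r_stab
    key = {"rank_sum": rank_sum, "similarity_first": r_sim, "stability_first": r_stab}[rule]
    # argmin takes the first minimum; feasible is ascending, so ties
    # resolve toward the smaller cost
    return feasible[int(np.argmin(key))], rank_sum


def select_cost(
    dataset: Dataset,
    grid: CostGrid | None = None,
    gamma: float = 1.0,
    n_realizations: int = 20,
    seed: int | None = None,
    rule: str = "rank_sum",
) -> CostSelectionReport:
    """Apply the three criteria and pick one cost.

    Similarity and stability are evaluated within the small-world feasible
    range.  ``rule`` is "rank_sum" (default; minimal sum of the similarity
    and stability ranks), "similarity_first", or "stability_first"; all
    ties resolve toward the smaller cost.
    """
    if grid is None:
        grid = CostGrid()
    feasible = smallworld_feasible_costs(dataset, grid, n_realizations, seed)
    sim = degree_similarity_score(dataset, feasible)
    stab = community_stability_score(dataset, feasible, gamma)
    selected, rank_sum = combine_criteria(feasible, sim, stab, rule)

    rows = []
    for c in grid.costs:
        if c in feasible:
            i = feasible.index(c)
            rows.append((c, True, sim[c], stab[c], int(rank_sum[i])))
        else:
            rows.append((c, False, np.nan, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["cost", "feasible", "similarity", "stability_sd", "rank_sum"])
    return CostSelectionReport(table, float(selected))
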