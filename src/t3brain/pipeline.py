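"""End-to-end orchestration: data -> networks -> features -> model -> inference.

The pipeline composes the library stages in the order the analysis
prescribes: simulate or ingest ROI time series, build connectivity
matrices, choose (or accept) a cost threshold, compute the three nodal
graph metrics and fALFF, assemble and standardize the feature tensor, fit
the supervised Tucker3 model, and run the permutation test plus the
paired-t-test baseline.  Every run writes a machine-readable summary with
the configuration hash and all seeds, so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import RoiTimeSeries, bandpass, binarize_by_cost, correlation_matrix
from .falff import DEFAULT_BAND, compute_falff
from .feature_tensor import FeatureTensor, assemble, standardize
from .graph_metrics import betweenness_centrality, clustering_coefficient, degree_centrality
from .inference import paired_ttest_features, permutation_test, score_condition_test
from .synthetic import TimeSeriesSynthSpec, generate_timeseries_dataset, read_dataset, write_dataset
from .t3clus import TuckerConfig, build_indicator, component_scores, fit, loadings
from .threshold import CostGrid, select_cost


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Everything a run needs; scientific parameters have no hidden defaults
    beyond the documented study-condition values."""

    seed: int | None = None
    out_dir: str = "t3brain_run"
    input_dir: str | None = None  # manifest-based input; None => simulate
    synth: dict = field(default_factory=dict)  # TimeSeriesSynthSpec overrides
    cost: float | None = None  # fixed cost; None => select over the grid
    costs: tuple = CostGrid().costs
    gamma: float = 1.0
    n_realizations: int = 20
    band: tuple = DEFAULT_BAND
    apply_bandpass: bool = False
    tucker: dict = field(default_factory=dict)  # TuckerConfig overrides
    standardize: bool = True
    n_perm: int = 10000
    scheme: str = "within_subject"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed (required for stochastic stages)")
        if self.input_dir is None and self.synth is None:
            raise ValueError("either input_dir or synth must be given")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(f, sep="\t", index=False)


def compute_features(
    blocks: list[RoiTimeSeries],
    cost: float,
    band: tuple = DEFAULT_BAND,
    apply_bandpass: bool = False,
) -> pd.DataFrame:
    """Nodal graph metrics and fALFF for every subject-condition block.

    Returns a long-format table (subject_id, condition, cost, region,
    metric, value) with metrics degree, betweenness, clustering, falff.
    fALFF is computed on the (optionally band-passed) time course itself;
    the graph metrics on the cost-thresholded correlation network.
    """
    rows = []
    for ts in blocks:
        if apply_bandpass:
            ts = bandpass(ts, *band)
        net = binarize_by_cost(correlation_matrix(ts), cost)
        vectors = {
            "degree": degree_centrality(net).values,
            "betweenness": betweenness_centrality(net).values,
            "clustering": clustering_coefficient(net).values,
            "falff": compute_falff(ts, band).values,
        }
        for metric, values in vectors.items():
            for region, v in zip(ts.region_names, values):
                rows.append((ts.subject_id, ts.condition, cost, region, metric, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "cost", "region", "metric", "value"])


def analyze_dataset(
    blocks: list[RoiTimeSeries],
    cost: float,
    config: PipelineConfig | None = None,
) -> dict:
    """In-memory analysis of one dataset at one fixed cost.

    Runs features -> tensor -> supervised Tucker3 -> permutation test,
    score condition test, and the paired-t-test baseline.  Returns a dict
    of intermediate objects and result tables.
    """
    if config is None:
        config = PipelineConfig(seed=0)
    tcfg = TuckerConfig(**config.tucker)
    features = compute_features(blocks, cost, config.band, config.apply_bandpass)
    raw = assemble(features.drop(columns=["cost"]))
    tensor = standardize(raw) if config.standardize else raw
    U = build_indicator(tensor.labels, tcfg.G)
    result = fit(tensor, U, tcfg)
    scores = component_scores(result, tensor, U)
    perm = permutation_test(
        tensor,
        tcfg,
        n_perm=config.n_perm,
        scheme=config.scheme,
        seed=config.seed,
        alpha=config.alpha,
    )
    score_test = score_condition_test(scores, tensor.observation_index)
    ttest = paired_ttest_features(raw, alpha=config.alpha)
    return {
        "features": features,
        "tensor": tensor,
        "raw_tensor": raw,
        "result": result,
        "scores": scores,
        "permutation": perm,
        "score_test": score_test,
        "ttest": ttest,
    }


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write reports under ``config.out_dir``.

    Writes features.tsv, cost_selection.tsv (when a grid search runs),
    loading tables, permutation and t-test tables, component scores, and a
    run_summary.json carrying the config hash, selected cost, loss,
    significant regions/metrics, and the software version.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()

    @_stage("simulate/ingest")
    def get_blocks():
        if config.input_dir is not None:
            return read_dataset(config.input_dir), None
        spec = TimeSeriesSynthSpec(**{"seed": config.seed, **config.synth})
        blocks, truth = generate_timeseries_dataset(spec)
        write_dataset(blocks, truth, out / "simulated")
        return blocks, truth

    blocks, truth = get_blocks()

    @_stage("threshold_selection")
    def get_cost():
        if config.cost is not None:
            return float(config.cost), None
        cms = {(b.subject_id, b.condition): correlation_matrix(b) for b in blocks}
        report = select_cost(
            cms,
            CostGrid(tuple(config.costs)),
            gamma=config.gamma,
            n_realizations=config.n_realizations,
            seed=config.seed,
        )
        _write_tsv(report.table, out / "cost_selection.tsv", cfg_hash)
        (out / "cost_selection.json").write_text(
            json.dumps({"selected_cost": report.selected_cost, "config_hash": cfg_hash}, indent=2)
        )
        return report.selected_cost, report

    cost, cost_report = get_cost()

    results = _stage("analysis")(analyze_dataset)(blocks, cost, config)

    @_stage("reports")
    def write_reports():
        _write_tsv(results["features"], out / "features.tsv", cfg_hash)
        perm = results["permutation"]
        _write_tsv(perm.region_table(), out / "region_loadings.tsv", cfg_hash)
        _write_tsv(perm.metric_table(), out / "metric_loadings.tsv", cfg_hash)
        _write_tsv(results["ttest"], out / "paired_ttest.tsv", cfg_hash)
        _write_tsv(results["score_test"], out / "score_test.tsv", cfg_hash)
        scores = results["scores"]
        score_df = pd.DataFrame(
            scores.raw_scores,
            columns=[f"component_{q + 1}" for q in range(scores.raw_scores.shape[1])],
        ).assign(
            subject_id=[s for s, _ in results["tensor"].observation_index],
            condition=[c for _, c in results["tensor"].observation_index],
        )
        _write_tsv(score_df, out / "component_scores.tsv", cfg_hash)

        res = results["result"]
        summary = {
            "config_hash": cfg_hash,
            "version": __version__,
            "seed": config.seed,
            "selected_cost": cost,
            "loss": res.loss,
            "n_iter": res.n_iter,
            "converged": res.converged,
            "significant_regions": perm.significant_regions,
            "significant_metrics": perm.significant_metrics,
            "score_test": results["score_test"].to_dict(orient="records"),
            "n_significant_ttest_cells": int(results["ttest"]["significant"].sum()),
            "config": asdict(config),
        }
        if truth is not None:
            summary["ground_truth_effect_regions"] = [
                results["tensor"].region_names[j] for j in truth.effect_region_set
            ]
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        return summary

    write_reports()
    return out
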