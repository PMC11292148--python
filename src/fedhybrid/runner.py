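"""Config-driven experiment matrix: arms x strategies x repeats.

``run_experiment`` reproduces the canonical benchmark table layout on a
synthetic cohort: fully federated and hybrid arms for each requested
aggregation strategy, a centralized benchmark, and per-client local
baselines (including one pooled baseline for the plan's centralized group).
Each cell is repeated with independently derived seeds and reported as
mean (SD). Re-running with the same config and master seed reproduces
every output byte for byte.

``grid_search_centralized`` mirrors the common tuning protocol of grid
searching hyperparameters on a centralized run scored against a validation
split carved from the training data, then applying the winner elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import (
    METRICS_BY_TASK,
    ExperimentSummary,
    UndefinedMetricError,
    federated_evaluate,
)
from .federation import (
    FederationPlan,
    RunResult,
    assign_holdout_splits,
    run_centralized,
    run_federated,
    run_hybrid,
    run_local,
)
from .strategies import STRATEGY_NAMES, DivergenceError, StrategyConfig
from .synthdata import CohortSpec, SiteSpec, derive_seed, generate_sites, preset

__all__ = ["ExperimentConfig", "run_experiment", "grid_search_centralized"]

logger = logging.getLogger("fedhybrid")

ARMS = ("federated", "hybrid", "centralized", "local")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment matrix."""

    cohort: str | CohortSpec               # preset name or explicit spec
    plan: FederationPlan | None = None     # required for the hybrid arm
    arms: tuple = ARMS
    strategies: tuple = STRATEGY_NAMES
    repeats: int = 5
    metrics: tuple | None = None           # default: all metrics for the task
    master_seed: int = 0
    out_dir: str | None = None
    strategy_config: StrategyConfig = field(default_factory=StrategyConfig)
    standardize: bool = True
    holdout_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms {unknown}")
        unknown = set(self.strategies) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(f"unknown strategies {unknown}")

    def cohort_spec(self, seed: int) -> CohortSpec:
        if isinstance(self.cohort, str):
            return preset(self.cohort, seed=seed)
        return replace(self.cohort, seed=seed)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        raw = yaml.safe_load(text)
        if "plan" in raw and raw["plan"] is not None:
            raw["plan"] = FederationPlan(assignments=raw["plan"]["assignments"])
        if "strategy_config" in raw:
            raw["strategy_config"] = StrategyConfig(**raw["strategy_config"])
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            sites = [SiteSpec(**s) for s in raw["cohort"].pop("sites")]
            raw["cohort"] = CohortSpec(sites=sites, **raw["cohort"])
        for key in ("arms", "strategies", "metrics"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _evaluate(result: RunResult, metrics, values, arm, label):
    for metric in metrics:
        try:
            report = federated_evaluate(result.clients, result.params, metric)
        except UndefinedMetricError as exc:
            logger.warning("%s/%s: %s undefined (%s)", arm, label, metric, exc)
            continue
        values.setdefault((arm, label, metric), []).append(report)


def _write_artifacts(out_dir, arm, label, repeat, result: RunResult, reports):
    if out_dir is None:
        return
    stem = f"{arm}_{label}_{repeat}"
    result.history.to_csv(out_dir / f"history_{stem}.csv")
    result.history.params_to_json(out_dir / f"params_{stem}.json")
    for report in reports:
        report.to_json(out_dir / f"report_{stem}_{report.metric_name}.json")


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute the requested matrix; return (and optionally write) the summary.

    The summary has one row per arm x strategy/client x metric with columns
    ``arm, label, metric, mean, sd`` (sd empty when repeats == 1). A failing
    arm is logged and skipped; the other arms still run.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    values: dict[tuple, list] = {}
    task = None
    for r in range(config.repeats):
        seed_r = derive_seed(config.master_seed, "repeat", r)
        spec = config.cohort_spec(seed_r)
        task = spec.task
        metrics = config.metrics or METRICS_BY_TASK[task]
        clients = assign_holdout_splits(generate_sites(spec), seed_r, config.holdout_frac)

        for arm in config.arms:
            try:
                if arm == "federated":
                    for strat in config.strategies:
                        cfg = replace(config.strategy_config, name=strat)
                        res = run_federated(clients, cfg, seed_r, config.standardize)
                        _evaluate(res, metrics, values, arm, strat)
                        _write_artifacts(out_dir, arm, strat, r, res, [])
                elif arm == "hybrid":
                    if config.plan is None:
                        raise ValueError("hybrid arm requires a federation plan")
                    for strat in config.strategies:
                        cfg = replace(config.strategy_config, name=strat)
                        res = run_hybrid(clients, config.plan, cfg, seed_r, config.standardize)
                        _evaluate(res, metrics, values, arm, strat)
                        _write_artifacts(out_dir, arm, strat, r, res, [])
                elif arm == "centralized":
                    res = run_centralized(clients, config.strategy_config, seed_r,
                                          config.standardize)
                    _evaluate(res, metrics, values, arm, "all")
                    _write_artifacts(out_dir, arm, "all", r, res, [])
                elif arm == "local":
                    for client in clients:
                        res = run_local(client, config.strategy_config, seed_r,
                                        config.standardize)
                        _evaluate(res, metrics, values, arm, client.site_id)
                    if config.plan is not None:
                        group = [c for c in clients
                                 if config.plan.assignments[c.site_id] == "centralized"]
                        if group:
                            label = "+".join(c.site_id for c in group)
                            res = run_local(group, config.strategy_config, seed_r,
                                            config.standardize)
                            _evaluate(res, metrics, values, arm, label)
            except (DivergenceError, ValueError) as exc:
                logger.error("arm %r failed on repeat %d: %s", arm, r, exc)

    rows = []
    for (arm, label, metric), reports in sorted(values.items()):
        summary = ExperimentSummary(arm=arm, label=label, metric=metric,
                                    repeats=[rep.E for rep in reports])
        rows.append({"arm": arm, "label": label, "metric": metric,
                     "mean": summary.mean, "sd": summary.sd})
    summary_df = pd.DataFrame(rows, columns=["arm", "label", "metric", "mean", "sd"])
    if out_dir:
        summary_df.to_csv(out_dir / "summary.csv", index=False)
    return summary_df


def grid_search_centralized(
    config: ExperimentConfig,
    grid: dict,
    metric: str | None = None,
) -> tuple[StrategyConfig, pd.DataFrame]:
    """Tune (local_lr, batch_size, prox_mu) by centralized validation score.

    Each grid point trains centralized on a sub-training split and is scored
    on a validation split carved from the training data (the holdout is
    never touched). Ties break toward the earliest grid point in iteration
    order; a diverging point scores -inf instead of aborting the search.
    """
    points = [
        {"local_lr": lr, "batch_size": bs, "prox_mu": mu}
        for lr in grid.get("local_lr", [config.strategy_config.local_lr])
        for bs in grid.get("batch_size", [config.strategy_config.batch_size])
        for mu in grid.get("prox_mu", [config.strategy_config.prox_mu])
    ]
    if not points:
        raise ValueError("empty grid")

    seed = derive_seed(config.master_seed, "gridsearch")
    spec = config.cohort_spec(seed)
    metric = metric or (config.metrics or METRICS_BY_TASK[spec.task])[0]
    clients = assign_holdout_splits(generate_sites(spec), seed, config.holdout_frac)
    # carve a validation split out of each training split; holdout untouched
    train_only = [c.train_split() for c in clients]
    carved = assign_holdout_splits(train_only, derive_seed(seed, "val"), 0.25)

    rows = []
    best, best_score = None, -float("inf")
    for point in points:
        cfg = replace(config.strategy_config, **point)
        try:
            res = run_centralized(carved, cfg, seed, config.standardize)
            score = federated_evaluate(res.clients, res.params, metric).E
        except (DivergenceError, FloatingPointError, UndefinedMetricError) as exc:
            logger.warning("grid point %s diverged: %s", point, exc)
            score = -float("inf")
        rows.append({**point, "score": score})
        if score > best_score:
            best, best_score = cfg, score
    return best, pd.DataFrame(rows)
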