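"""Experiment arms across the degree-of-federation continuum.

The degree of federation is the fraction of the data universe that stays at
federated sites. It is realized here by a FederationPlan assigning each site
either role:

* ``federated`` sites keep their records and join training as themselves;
* ``centralized`` sites pool their records into ONE hub client that joins
  the federation as a single, usually large, participant.

With every site federated the plan reduces to conventional federated
learning (degree 1); with every site centralized it reduces to ordinary
pooled training (degree 0); anything in between is a hybrid run. The
centralized benchmark arm and per-client local baselines reuse the same
training loop, so all arms share one optimizer, one seed policy and one
split, and the boundary cases agree bit-for-bit.

Seed policy: a master seed drives (a) the per-site stratified 80/20
train/holdout split, keyed by site_id so every arm scores identical
holdouts, and (b) per-round batch shuffling, keyed by the client's position
in the effective-client list so a lone pooled hub and a lone raw site
shuffle identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .strategies import (
    StrategyConfig,
    init_server_state,
    local_update,
    server_update,
)
from .synthdata import derive_seed
from .tasks import ClientDataset, TaskError, n_params, task_loss_grad

__all__ = [
    "FederationPlan",
    "TrainingHistory",
    "RunResult",
    "assign_holdout_splits",
    "standardize_clients",
    "destandardize_params",
    "build_effective_clients",
    "run_federated",
    "run_hybrid",
    "run_centralized",
    "run_local",
]

HUB_ID = "hub"


@dataclass
class FederationPlan:
    """Site-to-role map; the degree of federation is derived, never set."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("a plan needs at least one site")
        bad = {r for r in self.assignments.values() if r not in ("federated", "centralized")}
        if bad:
            raise ValueError(f"unknown roles {bad}; expected 'federated' or 'centralized'")

    def degree(self, clients: list[ClientDataset]) -> float:
        """Fraction of all records held by federated sites."""
        self._check_cover(clients)
        total = sum(c.n for c in clients)
        fed = sum(c.n for c in clients if self.assignments[c.site_id] == "federated")
        return fed / total

    def _check_cover(self, clients: list[ClientDataset]) -> None:
        site_ids = {c.site_id for c in clients}
        plan_ids = set(self.assignments)
        if site_ids != plan_ids:
            raise ValueError(
                f"plan does not cover the sites exactly: plan-only {plan_ids - site_ids}, "
                f"site-only {site_ids - plan_ids}"
            )

    @classmethod
    def all_federated(cls, clients) -> "FederationPlan":
        return cls({c.site_id: "federated" for c in clients})

    @classmethod
    def all_centralized(cls, clients) -> "FederationPlan":
        return cls({c.site_id: "centralized" for c in clients})

    def to_yaml(self) -> str:
        return yaml.safe_dump({"assignments": dict(self.assignments)}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FederationPlan":
        return cls(**yaml.safe_load(text))


@dataclass
class TrainingHistory:
    """Per-round training losses and parameter snapshot hashes, plus the final model."""

    rounds: list[dict]          # {round, losses: {client -> loss}, param_hash}
    final_params: np.ndarray

    def hashes(self) -> list[str]:
        return [r["param_hash"] for r in self.rounds]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            {"round": r["round"], "client_id": cid, "loss": loss}
            for r in self.rounds
            for cid, loss in r["losses"].items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def params_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"params": self.final_params.tolist()}, indent=2))


@dataclass
class RunResult:
    """Final parameters, history, and the evaluation-ready effective clients."""

    params: np.ndarray
    history: TrainingHistory
    clients: list[ClientDataset]

    def __iter__(self):  # allows `params, history = run_*(...)`
        return iter((self.params, self.history))


def _param_hash(w: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(w).tobytes()).hexdigest()[:16]


def assign_holdout_splits(
    clients: list[ClientDataset], seed: int, holdout_frac: float = 0.2
) -> list[ClientDataset]:
    """Per-site stratified train/holdout split, fixed by (seed, site_id).

    Stratification is by label (classification) or event indicator
    (survival). Within each stratum the holdout count is round(frac * n),
    clipped to leave at least one record on each side when the stratum has
    two or more; a singleton stratum stays in the training split.
    """
    if not (0 < holdout_frac < 1):
        raise ValueError("holdout_frac must lie strictly in (0, 1)")
    out = []
    for client in clients:
        rng = np.random.default_rng(derive_seed(seed, "split", client.site_id))
        strata = client.y if client.task == "classification" else client.event
        mask = np.zeros(client.n, dtype=bool)
        for value in np.unique(strata):
            idx = np.flatnonzero(strata == value)
            if idx.size < 2:
                continue
            k = int(round(holdout_frac * idx.size))
            k = min(max(k, 1), idx.size - 1)
            chosen = rng.permutation(idx)[:k]
            mask[chosen] = True
        if not mask.any() or mask.all():
            raise TaskError(f"site {client.site_id!r}: degenerate holdout split (n={client.n})")
        out.append(replace(client, holdout_mask=mask))
    return out


def build_effective_clients(
    clients: list[ClientDataset], plan: FederationPlan
) -> list[ClientDataset]:
    """Pool centralized sites into one hub; federated sites pass through.

    Output order is federated sites in input order, hub last. Holdout masks
    are concatenated, so record-level split membership survives pooling.
    """
    plan._check_cover(clients)
    federated = [c for c in clients if plan.assignments[c.site_id] == "federated"]
    pooled = [c for c in clients if plan.assignments[c.site_id] == "centralized"]
    if not pooled:
        return list(clients)
    cat = lambda parts: None if parts[0] is None else np.concatenate(parts)
    hub = ClientDataset(
        site_id=HUB_ID,
        X=np.concatenate([c.X for c in pooled]),
        y=cat([c.y for c in pooled]),
        time=cat([c.time for c in pooled]),
        event=cat([c.event for c in pooled]),
        holdout_mask=cat([c.holdout_mask for c in pooled]),
    )
    return federated + [hub]


def standardize_clients(clients: list[ClientDataset]) -> list[ClientDataset]:
    """Per-client z-scoring using each client's own training-split statistics.

    No cross-client statistics are exchanged — consistent with a federation
    that shares only model updates. Zero-variance columns are left centered
    but unscaled.
    """
    out = []
    for client in clients:
        train = client.train_split()
        mean = train.X.mean(axis=0)
        std = train.X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        out.append(replace(client, X=(client.X - mean) / std))
    return out


def destandardize_params(
    params: np.ndarray, mean: np.ndarray, std: np.ndarray, task: str
) -> np.ndarray:
    """Map coefficients fitted on z-scored features back to the raw scale."""
    params = np.asarray(params, dtype=float)
    if task == "classification":
        beta = params[1:] / std
        intercept = params[0] - float(np.sum(params[1:] * mean / std))
        return np.concatenate([[intercept], beta])
    return params / std


def _train_loop(
    effective_clients: list[ClientDataset],
    cfg: StrategyConfig,
    seed: int,
) -> RunResult:
    """The single training loop behind every arm.

    Starts from w = 0; each round every client runs local_update from the
    current global parameters, then the strategy's server rule produces the
    next global model. Deterministic given (clients, cfg, seed).
    """
    if not effective_clients:
        raise ValueError("no clients to train on")
    tasks = {c.task for c in effective_clients}
    dims = {c.d for c in effective_clients}
    if len(tasks) != 1 or len(dims) != 1:
        raise ValueError("clients disagree on task or feature dimension")
    task, d = tasks.pop(), dims.pop()
    state = init_server_state(n_params(d, task), cfg)
    rounds = []
    for t in range(cfg.rounds):
        updates = []
        losses = {}
        for pos, client in enumerate(effective_clients):
            rng = np.random.default_rng(derive_seed(seed, "shuffle", pos, t))
            w_local, n = local_update(state.w, client, cfg, rng)
            updates.append((w_local, n))
        state = server_update(state, updates, cfg)
        for client in effective_clients:
            losses[client.site_id], _ = task_loss_grad(state.w, client.train_split())
        rounds.append({"round": t, "losses": losses, "param_hash": _param_hash(state.w)})
    history = TrainingHistory(rounds=rounds, final_params=state.w)
    return RunResult(params=state.w, history=history, clients=effective_clients)


def run_federated(
    effective_clients: list[ClientDataset],
    cfg: StrategyConfig,
    seed: int,
    standardize: bool = True,
) -> RunResult:
    """Conventional federated training over the given (effective) clients."""
    if standardize:
        effective_clients = standardize_clients(effective_clients)
    return _train_loop(effective_clients, cfg, seed)


def run_hybrid(
    clients: list[ClientDataset],
    plan: FederationPlan,
    cfg: StrategyConfig,
    seed: int,
    standardize: bool = True,
) -> RunResult:
    """Hybrid arm: pool the plan's centralized sites into a hub, then federate.

    The hub's aggregation weight is its pooled training-split size, exactly
    as any client's weight is its own size under FedAvg's data-weighted
    average.
    """
    return run_federated(build_effective_clients(clients, plan), cfg, seed, standardize)


def _as_plain_sgd(cfg: StrategyConfig) -> StrategyConfig:
    """Benchmark arms use plain FedAvg-style local SGD regardless of strategy."""
    return replace(cfg, name="fedavg", prox_mu=0.0)


def run_centralized(
    clients: list[ClientDataset],
    cfg: StrategyConfig,
    seed: int,
    standardize: bool = True,
) -> RunResult:
    """Benchmark arm: pool everything and train one model on the pooled split.

    Implemented as a single-hub run of the same loop — T rounds of
    local_epochs epochs equals T x local_epochs epochs of pooled mini-batch
    SGD (with reshuffling each round) — so the degree-0 boundary case of
    run_hybrid matches this arm exactly.
    """
    plan = FederationPlan.all_centralized(clients)
    return run_hybrid(clients, plan, _as_plain_sgd(cfg), seed, standardize)


def run_local(
    client: ClientDataset | list[ClientDataset],
    cfg: StrategyConfig,
    seed: int,
    standardize: bool = True,
) -> RunResult:
    """Per-client baseline: train on one site (or one pooled group) alone."""
    clients = [client] if isinstance(client, ClientDataset) else list(client)
    return run_centralized(clients, cfg, seed, standardize)
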