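"""Aggregation strategies: FedAvg, FedProx, and the adaptive FedOpt family.

A strategy is a pair of rules. The *local* rule takes the current global
parameters to a client and runs mini-batch gradient descent on the client's
training split (FedProx adds a proximal pull (mu/2)||w - w_global||^2 toward
the round's starting point). The *server* rule turns the size-weighted
average of the returned parameters into the next global model: FedAvg adopts
it directly, while FedAdagrad and FedYogi treat the average minus the
current global model as a pseudo-gradient and apply an Adagrad/Yogi-style
moment update to it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .tasks import ClientDataset, TaskError, task_loss_grad

__all__ = [
    "STRATEGY_NAMES",
    "StrategyConfig",
    "ServerState",
    "DivergenceError",
    "local_update",
    "aggregate_fedavg",
    "server_update_fedavg",
    "server_update_adaptive",
    "init_server_state",
]

STRATEGY_NAMES = ("fedavg", "fedprox", "fedadagrad", "fedyogi")


class DivergenceError(RuntimeError):
    """Non-finite loss during local training; carries the offending round/batch."""


@dataclass
class StrategyConfig:
    """Strategy hyperparameters.

    ``prox_mu`` is read only by fedprox; ``server_lr``, ``adaptivity``,
    ``momentum`` and ``second_moment`` only by the adaptive strategies.
    Defaults are common FedOpt-style desk-scale settings; every field is
    overridable and round-trips through YAML unchanged.
    """

    name: str = "fedavg"
    server_lr: float = 0.1       # eta, server step size (adaptive only)
    adaptivity: float = 1e-3     # tau, adaptive denominator floor
    momentum: float = 0.9        # beta_1, first-moment decay
    second_moment: float = 0.99  # beta_2, second-moment decay (fedyogi)
    prox_mu: float = 0.1         # mu, proximal weight (fedprox only)
    local_lr: float = 0.05       # eta_l, client step size
    local_epochs: int = 5
    batch_size: int = 32
    rounds: int = 50

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; expected one of {STRATEGY_NAMES}")
        if self.server_lr <= 0 or self.adaptivity <= 0 or self.local_lr <= 0:
            raise ValueError("server_lr, adaptivity and local_lr must be positive")
        if not (0 <= self.momentum < 1) or not (0 <= self.second_moment < 1):
            raise ValueError("momentum and second_moment must lie in [0, 1)")
        if self.prox_mu < 0:
            raise ValueError("prox_mu must be non-negative")
        if self.local_epochs < 1 or self.batch_size < 1 or self.rounds < 1:
            raise ValueError("local_epochs, batch_size and rounds must be positive integers")

    @property
    def is_adaptive(self) -> bool:
        return self.name in ("fedadagrad", "fedyogi")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StrategyConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class ServerState:
    """Global parameters plus first/second moment accumulators.

    ``v`` starts at adaptivity^2 for the adaptive strategies so the
    denominator sqrt(v) + tau is bounded away from zero at round 1.
    """

    round: int
    w: np.ndarray
    m: np.ndarray
    v: np.ndarray


def init_server_state(p: int, cfg: StrategyConfig) -> ServerState:
    v0 = cfg.adaptivity**2 if cfg.is_adaptive else 0.0
    return ServerState(round=0, w=np.zeros(p), m=np.zeros(p), v=np.full(p, v0))


def local_update(
    w_global: np.ndarray,
    client: ClientDataset,
    cfg: StrategyConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Run ``local_epochs`` of mini-batch SGD from ``w_global`` on the client.

    Batches are drawn by shuffling the training split with ``rng`` each
    epoch; the last short batch is kept. Returns the final local parameters
    and the training-split size (the FedAvg aggregation weight).
    """
    train = client.train_split()
    n = train.n
    if n == 0:
        raise TaskError(f"site {client.site_id!r}: empty training split")
    w = np.array(w_global, dtype=float)
    use_prox = cfg.name == "fedprox" and cfg.prox_mu != 0.0
    for epoch in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = train.subset(order[start : start + cfg.batch_size])
            if batch.event is not None and batch.event.sum() == 0:
                continue  # partial likelihood undefined on an event-free batch
            loss, grad = task_loss_grad(w, batch)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss on site {client.site_id!r}, "
                    f"epoch {epoch}, batch starting at {start}"
                )
            if use_prox:
                grad = grad + cfg.prox_mu * (w - w_global)
            w = w - cfg.local_lr * grad
    return w, n


def aggregate_fedavg(updates: list[tuple[np.ndarray, int]]) -> np.ndarray:
    """Size-weighted elementwise average sum_i (n_i / N) w_i.

    Terms are accumulated in a canonical order (sorted by size, then by
    parameter bytes) so the result is bit-identical under any permutation
    of the update list.
    """
    if not updates:
        raise ValueError("empty update list")
    shapes = {w.shape for w, _ in updates}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent update shapes {shapes}")
    first = updates[0][0]
    if all(np.array_equal(w, first) for w, _ in updates[1:]):
        return np.array(first, dtype=float)  # exact fixed point for unanimous clients
    total = sum(n for _, n in updates)
    ordered = sorted(updates, key=lambda u: (u[1], np.ascontiguousarray(u[0]).tobytes()))
    out = np.zeros_like(ordered[0][0], dtype=float)
    for w, n in ordered:
        out = out + (n / total) * w
    return out


def server_update_fedavg(state: ServerState, updates, cfg: StrategyConfig) -> ServerState:
    """FedAvg/FedProx server rule: adopt the weighted average as w^{t+1}."""
    return replace(state, round=state.round + 1, w=aggregate_fedavg(updates))


def server_update_adaptive(state: ServerState, updates, cfg: StrategyConfig) -> ServerState:
    """FedAdagrad / FedYogi server rule on the pseudo-gradient.

    delta = avg(updates) - w^t
    m <- beta1 m + (1 - beta1) delta
    v <- v + delta^2                                  (fedadagrad)
    v <- v - (1 - beta2) delta^2 sign(v - delta^2)    (fedyogi)
    w <- w^t + eta * m / (sqrt(v) + tau)
    """
    if cfg.name not in ("fedadagrad", "fedyogi"):
        raise ValueError(f"server_update_adaptive called with strategy {cfg.name!r}")
    delta = aggregate_fedavg(updates) - state.w
    if delta.shape != state.w.shape:
        raise ValueError("update shape does not match server state")
    m = cfg.momentum * state.m + (1 - cfg.momentum) * delta
    d2 = delta**2
    if cfg.name == "fedadagrad":
        v = state.v + d2
    else:
        v = state.v - (1 - cfg.second_moment) * d2 * np.sign(state.v - d2)
    denom = np.sqrt(v) + cfg.adaptivity
    assert np.all(denom > 0), "adaptive denominator lost positivity"
    w = state.w + cfg.server_lr * m / denom
    return ServerState(round=state.round + 1, w=w, m=m, v=v)


def server_update(state: ServerState, updates, cfg: StrategyConfig) -> ServerState:
    """Dispatch on the configured strategy."""
    if cfg.is_adaptive:
        return server_update_adaptive(state, updates, cfg)
    return server_update_fedavg(state, updates, cfg)
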