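"""Model heads shared by every training arm.

Two task heads cover the simulator's clinical use cases: logistic regression
for binary outcomes (e.g. presence of heart disease) and a Cox
proportional-hazards model for right-censored survival times (e.g. time to
death). Both are exposed as pure loss/gradient/prediction functions over a
flat parameter vector so the same code drives local client updates,
centralized training and federated aggregation.

Parameter layout
----------------
classification : ``(intercept, beta_1, ..., beta_d)`` — length ``d + 1``
survival       : ``(beta_1, ..., beta_d)`` — length ``d`` (the Cox partial
                 likelihood is invariant to an intercept, so none is fitted)

Losses are normalized — mean negative log-likelihood per record (logistic)
and Breslow negative log partial likelihood per event (Cox) — so a single
local learning rate transfers across sites of very different size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "ClientDataset",
    "TaskError",
    "logistic_predict",
    "logistic_loss_grad",
    "cox_loss_grad",
    "cox_risk_score",
    "task_loss_grad",
    "n_params",
]


class TaskError(ValueError):
    """Raised for contract violations: dimension mismatch, empty data, no events."""


@dataclass
class ClientDataset:
    """One site's data: features plus binary or survival outcomes.

    For classification ``y`` holds 0/1 labels and ``time``/``event`` are
    None; for survival ``y`` is None and ``time`` (positive) / ``event``
    (0/1) are set. ``holdout_mask`` marks the evaluation split; it is None
    until a split is assigned.
    """

    site_id: str
    X: np.ndarray
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    holdout_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise TaskError(f"site {self.site_id!r}: X must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.X)):
            raise TaskError(f"site {self.site_id!r}: non-finite feature values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.n,):
                raise TaskError(f"site {self.site_id!r}: label length mismatch")
            if not np.isin(self.y, (0.0, 1.0)).all():
                raise TaskError(f"site {self.site_id!r}: labels must be 0/1")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=float)
            if self.time.shape != (self.n,) or self.event.shape != (self.n,):
                raise TaskError(f"site {self.site_id!r}: survival column length mismatch")
            if np.any(self.time <= 0):
                raise TaskError(f"site {self.site_id!r}: observed times must be positive")
            if not np.isin(self.event, (0.0, 1.0)).all():
                raise TaskError(f"site {self.site_id!r}: event indicators must be 0/1")
        if self.holdout_mask is not None:
            self.holdout_mask = np.asarray(self.holdout_mask, dtype=bool)
            if self.holdout_mask.shape != (self.n,):
                raise TaskError(f"site {self.site_id!r}: holdout mask length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def task(self) -> str:
        return "classification" if self.y is not None else "survival"

    def subset(self, mask: np.ndarray, site_id: str | None = None) -> "ClientDataset":
        """Row-subset preserving outcome columns; the mask is consumed, not kept."""
        return ClientDataset(
            site_id=site_id if site_id is not None else self.site_id,
            X=self.X[mask],
            y=None if self.y is None else self.y[mask],
            time=None if self.time is None else self.time[mask],
            event=None if self.event is None else self.event[mask],
        )

    def train_split(self) -> "ClientDataset":
        if self.holdout_mask is None:
            return self
        return self.subset(~self.holdout_mask)

    def holdout_split(self) -> "ClientDataset":
        if self.holdout_mask is None:
            raise TaskError(f"site {self.site_id!r}: no holdout split assigned")
        return self.subset(self.holdout_mask)


def n_params(d: int, task: str) -> int:
    """Length of the parameter vector for feature dimension ``d``."""
    if task == "classification":
        return d + 1
    if task == "survival":
        return d
    raise TaskError(f"unknown task {task!r}")


def _check_dim(params: np.ndarray, X: np.ndarray, task: str) -> None:
    expected = n_params(X.shape[1], task)
    if params.shape != (expected,):
        raise TaskError(
            f"parameter vector of length {params.shape} does not match "
            f"{task} head for d={X.shape[1]} (expected {expected})"
        )


def logistic_predict(params: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-record event probability 1 / (1 + exp(-(b0 + x·beta)))."""
    params = np.asarray(params, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_dim(params, X, "classification")
    return expit(params[0] + X @ params[1:])


def logistic_loss_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Mean negative log-likelihood and its exact gradient.

    loss = -(1/n) sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)] with
    p_i = sigmoid(b0 + x_i·beta); gradient has the intercept component first.
    """
    params = np.asarray(params, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise TaskError("empty dataset")
    _check_dim(params, X, "classification")
    z = params[0] + X @ params[1:]
    # log(1 + e^z) - y z, computed stably via logaddexp
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    resid = expit(z) - y
    grad = np.empty_like(params)
    grad[0] = resid.mean()
    grad[1:] = X.T @ resid / n
    return loss, grad


def cox_loss_grad(params: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Breslow negative log partial likelihood per event, with exact gradient.

    The risk set at an event time t is {j : time_j >= t}; tied event times
    share one denominator evaluated over their common risk set (Breslow).
    Normalization is by the number of events.
    """
    params = np.asarray(params, dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if X.shape[0] == 0:
        raise TaskError("empty dataset")
    _check_dim(params, X, "survival")
    n_events = float(event.sum())
    if n_events == 0:
        raise TaskError("partial likelihood undefined: no events")

    order = np.argsort(-time, kind="stable")  # descending time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ params
    m = eta.max()
    w = np.exp(eta - m)  # shifted for stability
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    # ties: every subject with the same time belongs to the risk set, so each
    # event uses the cumulative sum up to the END of its tie group
    _, inv, counts = np.unique(-ts, return_inverse=True, return_counts=True)
    group_end = np.cumsum(counts) - 1  # index of last row of each tie group
    idx = group_end[inv]
    denom_w = cum_w[idx]
    loss = float(np.sum(es * (np.log(denom_w) + m - eta)) / n_events)
    grad = (es[:, None] * (cum_wx[idx] / denom_w[:, None] - Xs)).sum(axis=0) / n_events
    return loss, grad


def cox_risk_score(params: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Linear predictor x·beta; higher score means higher predicted hazard."""
    params = np.asarray(params, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_dim(params, X, "survival")
    return X @ params


def task_loss_grad(params: np.ndarray, data: ClientDataset):
    """Dispatch to the dataset's task head."""
    if data.task == "classification":
        return logistic_loss_grad(params, data.X, data.y)
    return cox_loss_grad(params, data.X, data.time, data.event)
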