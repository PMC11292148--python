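"""Metrics and the size-weighted federated evaluation protocol.

In a federation without a shared server-side test set, the global model is
scored on each client's own holdout and the per-client metrics E_i are
combined into E = sum_i (n_i / N) E_i, weighting each client by its holdout
size n_i (N = sum n_i). The per-client values are retained alongside the
aggregate, since the dispersion across clients is often the finding.

Metrics: accuracy and ROC-AUC (Mann-Whitney form, half credit for score
ties) for classification; Harrell's concordance index for survival.
A client whose holdout cannot support a metric (single-class labels, no
comparable survival pairs) is reported as undefined and excluded from the
weighted sum, with N reduced accordingly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .tasks import ClientDataset, cox_risk_score, logistic_predict

__all__ = [
    "UndefinedMetricError",
    "EvaluationReport",
    "ExperimentSummary",
    "accuracy",
    "roc_auc",
    "concordance_index",
    "federated_evaluate",
    "summarize_repeats",
    "METRICS_BY_TASK",
]

METRICS_BY_TASK = {"classification": ("roc_auc", "accuracy"), "survival": ("c_index",)}


class UndefinedMetricError(ValueError):
    """The metric has no value on this sample (single class, no comparable pairs)."""


def accuracy(y_true, probabilities, threshold: float = 0.5) -> float:
    """Fraction of records where (p >= threshold) equals the label."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise UndefinedMetricError("accuracy of an empty sample")
    return float(np.mean((p >= threshold) == (y == 1)))


def roc_auc(y_true, scores) -> float:
    """Mann-Whitney ROC-AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed from mid-ranks, which is exactly the pairwise definition with
    half credit for tied scores.
    """
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC needs at least one positive and one negative")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def concordance_index(time, event, risk_scores) -> float:
    """Harrell's C for right-censored data.

    A pair is comparable when the shorter observed time ends in an event
    (ties in time with both events are not comparable). A comparable pair is
    concordant when the earlier-failing subject has the higher risk score;
    risk ties earn half credit.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    r = np.asarray(risk_scores, dtype=float)
    n = t.size
    comparable = 0
    score = 0.0
    for i in range(n):
        if e[i] != 1:
            continue
        # j with longer time, or equal time but censored, is comparable to i
        later = (t > t[i]) | ((t == t[i]) & (e == 0))
        m = int(later.sum())
        if m == 0:
            continue
        comparable += m
        score += float((r[later] < r[i]).sum()) + 0.5 * float((r[later] == r[i]).sum())
    if comparable == 0:
        raise UndefinedMetricError("no comparable pairs")
    return score / comparable


@dataclass
class EvaluationReport:
    """Per-client metrics with sizes and the size-weighted aggregate."""

    metric_name: str
    per_client: list[dict]  # {site_id, n, value} with value None when undefined
    N: int
    E: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = list(self.per_client)
        rows.append({"site_id": "WEIGHTED", "n": self.N, "value": self.E})
        pd.DataFrame(rows).to_csv(path, index=False)


def _client_metric(client: ClientDataset, params: np.ndarray, metric_name: str) -> float:
    holdout = client.holdout_split()
    if metric_name in ("roc_auc", "accuracy"):
        p = logistic_predict(params, holdout.X)
        if metric_name == "accuracy":
            return accuracy(holdout.y, p)
        return roc_auc(holdout.y, p)
    if metric_name == "c_index":
        return concordance_index(holdout.time, holdout.event, cox_risk_score(params, holdout.X))
    raise ValueError(f"unknown metric {metric_name!r}")


def federated_evaluate(
    clients: list[ClientDataset],
    params: np.ndarray,
    metric_name: str,
) -> EvaluationReport:
    """Score the global parameters on every client's holdout and weight by size.

    Clients on which the metric is undefined are kept in the per-client list
    with a null value but contribute neither E_i nor n_i to the aggregate.
    """
    per_client = []
    num = 0.0
    N = 0
    for client in clients:
        holdout_n = int(client.holdout_split().n)
        try:
            value = _client_metric(client, params, metric_name)
        except UndefinedMetricError as exc:
            warnings.warn(
                f"site {client.site_id!r}: {metric_name} undefined on its holdout "
                f"({exc}); excluded from the weighted aggregate"
            )
            per_client.append({"site_id": client.site_id, "n": holdout_n, "value": None})
            continue
        per_client.append({"site_id": client.site_id, "n": holdout_n, "value": value})
        num += holdout_n * value
        N += holdout_n
    if N == 0:
        raise UndefinedMetricError(f"{metric_name} undefined on every client")
    return EvaluationReport(metric_name=metric_name, per_client=per_client, N=N, E=num / N)


def summarize_repeats(values) -> tuple[float, float | None]:
    """Mean and sample (n-1) standard deviation; sd is None for a single repeat."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    return mean, sd


@dataclass
class ExperimentSummary:
    """One Table-style row: arm x strategy/client x metric, mean (SD) over repeats."""

    arm: str
    label: str       # strategy name, or client id for local rows
    metric: str
    repeats: list[float]
    mean: float = field(init=False)
    sd: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.mean, self.sd = summarize_repeats(self.repeats)
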