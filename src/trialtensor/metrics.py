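"""Ranking metrics for sparse binary outcome prediction.

AUROC is the Mann-Whitney probability that a random positive outranks a
random negative (ties counted 1/2); AUPRC is average precision (step
integration of the precision-recall curve, no interpolation).  Both
delegate to scikit-learn, whose definitions match exactly; independent
brute-force oracles live in the test suite.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "UndefinedMetricError",
    "auroc",
    "auprc",
    "topk_metrics",
    "bootstrap_ci",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. a single-class fold)."""


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=np.int64).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores have different lengths")
    if len(labels) == 0:
        raise UndefinedMetricError("no examples")
    return labels, scores


def auroc(labels, scores) -> float:
    labels, scores = _validate(labels, scores)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    labels, scores = _validate(labels, scores)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined without positives")
    return float(average_precision_score(labels, scores))


def topk_metrics(labels, scores, k: int = 30) -> tuple[float, float, float]:
    """(precision@k, recall@k, F-score at the 0.5 score threshold).

    Top-k ties are broken by stable input order so runs are reproducible.
    ``k > n`` is clipped to n with a warning.
    """
    labels, scores = _validate(labels, scores)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(labels)
    if k > n:
        warnings.warn(f"k={k} > n={n}; clipping to n", stacklevel=2)
        k = n
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("top-k metrics undefined without positives")
    order = np.argsort(-scores, kind="stable")
    tp_at_k = int(labels[order[:k]].sum())
    precision_at_k = tp_at_k / k
    recall_at_k = tp_at_k / n_pos
    pred_pos = scores >= 0.5
    tp = int((labels[pred_pos] == 1).sum())
    prec = tp / pred_pos.sum() if pred_pos.any() else 0.0
    rec = tp / n_pos
    f_score = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    return precision_at_k, recall_at_k, f_score


def bootstrap_ci(
    labels,
    scores,
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 1000,
    seed: int = 0,
    retry_cap: int = 100,
) -> tuple[float, float]:
    """Percentile 95% CI over ``n_boot`` pair resamples (with replacement).

    Resamples on which the metric is undefined (single class) are redrawn up
    to ``retry_cap`` times each; exhaustion raises UndefinedMetricError.
    """
    labels, scores = _validate(labels, scores)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(labels)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(retry_cap + 1):
            idx = rng.integers(0, n, size=n)
            try:
                stats[b] = metric(labels[idx], scores[idx])
                break
            except UndefinedMetricError:
                if attempt == retry_cap:
                    raise UndefinedMetricError(
                        "bootstrap retry cap exhausted; CI undefined"
                    )
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))
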