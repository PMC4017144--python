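"""Edge-detection quality metrics: undirected ROC/AUC, d-Accuracy, normalized MSE.

The connectivity matrix convention throughout is C[i, j] = strength of the
influence j -> i; truth edges are ordered (source, target) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["EvaluationReport", "roc_auc", "d_accuracy", "mse", "evaluate"]


@dataclass(frozen=True, eq=False)
class EvaluationReport:
    auc: float
    d_accuracy: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _undirected(C: np.ndarray, truth) -> tuple[np.ndarray, np.ndarray]:
    """Scores and labels over distinct unordered pairs (diagonal excluded).

    The undirected score of a pair is the larger of the two directed scores,
    con(i, j) = max(c_ij, c_ji).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError("connectivity matrix must be square")
    truth_und = {frozenset(e) for e in truth}
    scores, labels = [], []
    for i in range(n):
        for j in range(i + 1, n):
            scores.append(max(C[i, j], C[j, i]))
            labels.append(1 if frozenset((i, j)) in truth_und else 0)
    return np.array(scores), np.array(labels)


def roc_auc(C: np.ndarray, truth) -> float:
    """Area under the undirected ROC curve, sweeping all score thresholds.

    Midrank tie handling (equivalent to the normalized Mann-Whitney U
    statistic).  ``truth`` is a set of pairs; orientation is ignored.
    """
    scores, labels = _undirected(C, truth)
    pos = labels.sum()
    if pos == 0 or pos == labels.size:
        raise ValueError("truth has no negatives or no positives; AUC undefined")
    return float(roc_auc_score(labels, scores))


def d_accuracy(C: np.ndarray, truth_directed) -> float:
    """Fraction of true connections whose larger score lies on the true direction.

    For a true edge (j, i) (influence j -> i) the direction counts as
    correct when c_ij > c_ji; exact ties earn half credit.
    """
    C = np.asarray(C, dtype=float)
    edges = list(truth_directed)
    if not edges:
        raise ValueError("empty truth; d-Accuracy undefined")
    score = 0.0
    for src, tgt in edges:
        fwd, rev = C[tgt, src], C[src, tgt]
        if fwd > rev:
            score += 1.0
        elif fwd == rev:
            score += 0.5
    return score / len(edges)


def mse(s_true: np.ndarray, s_est: np.ndarray) -> float:
    """Energy-normalized squared error sum ||s - s_est||^2 / sum ||s||^2."""
    s_true = np.asarray(s_true, dtype=float)
    s_est = np.asarray(s_est, dtype=float)
    if s_true.shape != s_est.shape:
        raise ValueError("shapes must match")
    energy = float(np.sum(s_true**2))
    if energy == 0.0:
        raise ValueError("zero-energy reference signal")
    return float(np.sum((s_true - s_est) ** 2) / energy)


def evaluate(C: np.ndarray, truth_directed) -> EvaluationReport:
    """Full report: undirected AUC with ROC counts, plus d-Accuracy."""
    scores, labels = _undirected(C, truth_directed)
    pos = labels.sum()
    if pos == 0 or pos == labels.size:
        raise ValueError("truth has no negatives or no positives; AUC undefined")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return EvaluationReport(
        auc=float(roc_auc_score(labels, scores)),
        d_accuracy=d_accuracy(C, truth_directed),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
    )
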