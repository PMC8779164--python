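"""Multi-class evaluation metrics: prediction accuracy, Rand index, and
the Hand–Till multi-class AUC (MAUC) obtained by averaging symmetrized
pairwise AUCs over all class pairs.

Ties in the pairwise AUC count 1/2 (standard rank-statistic convention).
The Rand index is the plain (unadjusted) pair-agreement fraction; an
adjusted variant is provided for completeness but is not part of the
headline report.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "prediction_accuracy",
    "rand_index",
    "adjusted_rand_index",
    "pairwise_auc",
    "multiclass_auc",
    "EvaluationReport",
    "evaluate_probabilities",
]


def _pair(x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"label vectors must be 1-D of equal length, got {x.shape} and {y.shape}")
    return x, y


def prediction_accuracy(true_labels, predicted) -> float:
    """Fraction of correct classifications, (#matches)/n."""
    t, p = _pair(true_labels, predicted)
    if len(t) < 1:
        raise ValueError("need at least one subject")
    return float(np.mean(t == p))


def _contingency(a, b) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def rand_index(partition_a, partition_b) -> float:
    """Plain Rand index: the fraction of subject pairs on which the two
    partitions agree (together in both, or apart in both)."""
    a, b = _pair(partition_a, partition_b)
    n = len(a)
    if n < 2:
        raise ValueError("Rand index needs n >= 2 subjects")
    table = _contingency(a, b)

    def pairs(x):
        x = np.asarray(x, dtype=float)
        return float(np.sum(x * (x - 1) / 2))

    total = n * (n - 1) / 2
    same_both = pairs(table)                      # together in both
    same_a = pairs(table.sum(axis=1))
    same_b = pairs(table.sum(axis=0))
    # apart in both = total - (same in a) - (same in b) + (same in both)
    return float((same_both + total - same_a - same_b + same_both) / total)


def adjusted_rand_index(partition_a, partition_b) -> float:
    """Chance-corrected Rand index (not used in the headline report)."""
    from sklearn.metrics import adjusted_rand_score

    a, b = _pair(partition_a, partition_b)
    return float(adjusted_rand_score(a, b))


def pairwise_auc(scores_i, scores_j) -> float:
    """One-directional AUC  A(i|j) = P(score_i > score_j) + 1/2 P(tie).

    ``scores_i`` are the scores of class-i subjects and ``scores_j`` those
    of class-j subjects under a common scoring direction (higher = more
    class i).  Computed via the rank-sum statistic with midranks, which
    realizes the half-credit tie convention exactly.
    """
    si = np.asarray(scores_i, dtype=float)
    sj = np.asarray(scores_j, dtype=float)
    if si.size == 0 or sj.size == 0:
        raise ValueError("both score groups must be non-empty")
    ranks = rankdata(np.concatenate([si, sj]))
    rank_sum_i = ranks[: si.size].sum()
    return float((rank_sum_i - si.size * (si.size + 1) / 2) / (si.size * sj.size))


def multiclass_auc(prob, true_labels, return_pairs: bool = False):
    """Hand–Till M: mean over unordered class pairs {i, j} of
    ``[A(i|j) + A(j|i)] / 2``, where A(i|j) ranks class-i against class-j
    subjects by the class-i probability column and A(j|i) by the class-j
    column.  Reduces to the standard two-class AUC for K=2.
    """
    prob = np.atleast_2d(np.asarray(prob, dtype=float))
    y = np.asarray(true_labels)
    if prob.shape[0] != y.shape[0]:
        raise ValueError("probability rows must match number of labels")
    K = prob.shape[1]
    if K < 2:
        raise ValueError("need K >= 2 classes")
    present = set(np.unique(y).tolist())
    missing = [k for k in range(K) if k not in present]
    if missing:
        raise ValueError(f"classes absent from true_labels: {missing}")
    pair_values = {}
    for i, j in combinations(range(K), 2):
        mask_i, mask_j = y == i, y == j
        a_ij = pairwise_auc(prob[mask_i, i], prob[mask_j, i])
        a_ji = pairwise_auc(prob[mask_j, j], prob[mask_i, j])
        pair_values[(i, j)] = (a_ij + a_ji) / 2
    m = float(np.mean(list(pair_values.values())))
    return (m, pair_values) if return_pairs else m


@dataclass
class EvaluationReport:
    """PA / RI / MAUC bundle with the per-pair AUC table."""

    pa: float
    ri: float
    mauc: float
    pair_auc: dict  # (i, j) -> symmetrized pairwise AUC

    def to_frame(self):
        import pandas as pd

        rows = [("PA", self.pa), ("RI", self.ri), ("MAUC", self.mauc)]
        rows += [(f"AUC({i},{j})", v) for (i, j), v in sorted(self.pair_auc.items())]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False)


def evaluate_probabilities(prob, true_labels) -> EvaluationReport:
    """Full evaluation from a probability matrix: predictions are the
    per-row argmax (ties toward the lowest class index)."""
    prob = np.atleast_2d(np.asarray(prob, dtype=float))
    y = np.asarray(true_labels)
    pred = prob.argmax(axis=1)
    mauc, pairs = multiclass_auc(prob, y, return_pairs=True)
    return EvaluationReport(
        pa=prediction_accuracy(y, pred),
        ri=rand_index(y, pred),
        mauc=mauc,
        pair_auc=pairs,
    )
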