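"""Ranking metrics for binary classifiers.

AUROC is computed from rank statistics (Mann-Whitney U with average ranks),
which equals the probability that a randomly chosen positive outranks a
randomly chosen negative, counting ties as one half.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["compute_auroc", "compute_auroc_batch", "sensitivity_at_specificity"]


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present in `labels`")
    if n_pos + n_neg != labels.size:
        raise ValueError("labels must be binary (0/1)")
    return n_pos, n_neg


def compute_auroc(scores, labels) -> float:
    """Area under the ROC curve for continuous scores and 0/1 labels.

    Ties in `scores` contribute 1/2, so a constant score vector yields 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_labels(labels)
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_auroc_batch(score_matrix, labels) -> np.ndarray:
    """AUROC for each row of `score_matrix` against one label vector.

    Used to score many permutation repetitions at once.
    """
    s = np.asarray(score_matrix, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_labels(labels)
    ranks = rankdata(s, axis=1)
    u = ranks[:, labels == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def sensitivity_at_specificity(scores, labels, specificity: float = 0.80) -> float:
    """Sensitivity at the smallest score threshold whose specificity >= target.

    Subjects with score >= threshold are called positive. Sweeping the
    threshold from low to high trades sensitivity for specificity; the
    smallest threshold reaching the requested specificity maximizes
    sensitivity subject to that constraint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_labels(labels)
    if not 0.0 <= specificity <= 1.0:
        raise ValueError("specificity must be in [0, 1]")
    # candidate thresholds: every distinct score, plus one above the maximum
    # (predict-none), so specificity 1 is always reachable.
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    neg = scores[labels == 0]
    pos = scores[labels == 1]
    for thr in thresholds:
        spec = np.mean(neg < thr)
        if spec >= specificity:
            return float(np.mean(pos >= thr))
    raise RuntimeError("unreachable: specificity 1 attainable at +inf threshold")
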