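"""Shared fixtures and oracle helpers for the test suite."""

import numpy as np
import pytest

import connsearch as cs


def random_spd(rng: np.random.Generator, n: int, cond: float = 10.0) -> np.ndarray:
    """A random SPD matrix with eigenvalues spread up to `cond`."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    eigs = rng.uniform(1.0, cond, size=n)
    return Q @ np.diag(eigs) @ Q.T


def pair_count_auroc(scores, labels) -> float:
    """Exhaustive pair-counting AUROC oracle (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_by(pvals, alpha=0.05):
    """Benjamini-Yekutieli step-up from the definition.

    Returns (reject array, adjusted q-values), with
    q_(i) = min_{j >= i} min(1, m * c(m) * p_(j) / j) and c(m) = sum 1/i.
    """
    p = np.asarray(pvals, float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = m * c_m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q <= alpha, q


def labels_and_sex(cohort):
    y = np.array([s.diagnosis for s in cohort], int)
    sex = np.array([s.sex for s in cohort], int)
    return y, sex


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject no-signal cohort, small ROIs: cheap shared input."""
    spec = cs.CohortSpec(n_subjects=60, n_rois=8, n_timepoints=80,
                         n_anat=5, seed=42)
    subjects, truth = cs.generate_cohort(spec)
    return spec, subjects, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with strong planted edge and anatomical signal."""
    spec = cs.CohortSpec(n_subjects=120, n_rois=8, n_timepoints=150, n_anat=5,
                         planted_edges=((0, 1, 0.3), (2, 5, 0.3)),
                         planted_anat=((0, 1.0), (3, 1.0)), seed=7)
    subjects, truth = cs.generate_cohort(spec)
    return spec, subjects, truth
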