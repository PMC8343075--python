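"""Classifier evaluation: accuracy/AUC, chance threshold, screening,
permutation significance.

The chance threshold is the analytic accuracy bound a coin-flip classifier
exceeds with probability at most alpha: with N subjects and correctness a
Binomial(N, 1/2) draw, the smallest two-decimal accuracy t such that
P(X/N > t) <= alpha. For N = 87 at alpha = 0.05 this is 0.59. Note the
binomial chance model deliberately ignores class imbalance (a constant
majority-class guesser on a 53/34 split scores 0.609); this is a property
of the screening convention, not corrected here.

The permutation test re-runs the *entire* nested LOOCV pipeline
(normalization, RFE, SVM) under label permutations that preserve the class
counts. Two p-values are reported: the one-sample t-test of the observed
accuracy against the null accuracies, and the empirical permutation p
``(1 + #{null >= observed}) / (n_perm + 1)``. The empirical p is the
preferred one — the t-test treats the null draws as a sample and is
anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import ClassifierResult, loocv_matrix

__all__ = [
    "accuracy",
    "auc",
    "chance_threshold",
    "screen_predictive",
    "permutation_test",
    "PermutationResult",
]


def accuracy(result: ClassifierResult) -> float:
    """Proportion of correctly classified subjects (TP + TN over N)."""
    return result.accuracy


def auc(result: ClassifierResult) -> float:
    """Rank-based area under the ROC of pooled LOOCV decision scores."""
    return result.auc


def chance_threshold(n: int, alpha: float = 0.05) -> float:
    """Smallest two-decimal accuracy t with P(X/n > t) <= alpha, X ~ Bin(n, 1/2).

    Returns 1.00 when no achievable accuracy level is that improbable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for k in range(101):
        t = k / 100.0
        # P(X > t*n) = P(X >= floor(t*n) + 1) = sf(floor(t*n))
        tail = stats.binom.sf(int(np.floor(t * n + 1e-9)), n, 0.5)
        if tail <= alpha:
            return t
    return 1.0


def screen_predictive(
    results: list[ClassifierResult],
    acc_threshold: float,
    auc_floor: float = 0.6,
) -> list[ClassifierResult]:
    """Keep results with accuracy strictly above the chance threshold AND
    AUC strictly above the floor — both conditions strict ("greater than")."""
    return [r for r in results if r.accuracy > acc_threshold and r.auc > auc_floor]


@dataclass
class PermutationResult:
    """Null accuracy distribution and significance of one observed accuracy."""

    tract_id: str | None
    property: str | None
    observed_accuracy: float
    null_accuracies: np.ndarray
    t_test_p: float
    empirical_p: float
    n_perm: int
    seed: int | None


def permutation_test(
    cohort,
    tract_id: str,
    property: str,
    n_perm: int = 1000,
    seed: int | None = None,
    observed: ClassifierResult | None = None,
    **loocv_kwargs,
) -> PermutationResult:
    """Label-permutation significance of one tract/property classifier.

    Each permutation shuffles the C/NC labels (preserving the group counts
    by construction) and re-runs the full LOOCV pipeline — normalization,
    RFE and SVM are all refit on the permuted labels. One RNG seeded once
    governs all shuffles, so identical seeds give identical nulls.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, _, names = cohort.feature_matrix(tract_id, property)
    if observed is None:
        observed = loocv_matrix(
            X, cohort.groups, cohort.subjects, names,
            tract_id=tract_id, property=property, **loocv_kwargs,
        )
    obs_acc = observed.accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_groups = rng.permutation(cohort.groups)
        res = loocv_matrix(
            X, perm_groups, cohort.subjects, names,
            tract_id=tract_id, property=property, **loocv_kwargs,
        )
        null[b] = res.accuracy
    if np.ptp(null) == 0:
        t_p = 0.0 if obs_acc != null[0] else 1.0
    else:
        t_p = float(stats.ttest_1samp(null, popmean=obs_acc).pvalue)
    emp_p = float((1 + np.sum(null >= obs_acc)) / (n_perm + 1))
    return PermutationResult(
        tract_id=tract_id,
        property=property,
        observed_accuracy=obs_acc,
        null_accuracies=null,
        t_test_p=t_p,
        empirical_p=emp_p,
        n_perm=n_perm,
        seed=seed,
    )
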