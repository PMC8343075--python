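"""Nested leave-one-out SVM classification with SVM-RFE feature selection.

The engine mirrors the along-tract classification procedure: within every
leave-one-out fold the N-1 training profiles are z-scored per node (training
statistics only — the held-out subject never touches any fitted quantity),
recursive feature elimination with correlation-bias reduction (CBR) prunes
the nodes down to the 10 most discriminative, and an RBF-kernel SVM trained
on those nodes classifies the held-out subject as converter (C) or
non-converter (NC).

RFE ranking criterion (nonlinear SVM-RFE): with dual coefficients ``a``
(labels folded in) and kernel matrix ``K`` of the current feature set, the
cost of removing feature ``i`` is

    dJ(i) = 1/2 a' K a  -  1/2 a' K^(-i) a

where ``K^(-i)`` is the kernel recomputed without feature ``i`` and ``a``
is held fixed. For the RBF kernel ``K^(-i) = K * exp(gamma * D_i)``
elementwise, with ``D_i`` the squared-difference matrix of feature ``i`` —
which makes the criterion cheap to evaluate for every candidate feature.

Correlation-bias reduction: plain RFE underestimates features that carry
the same signal as correlated neighbours (removing one leaves the kernel
almost unchanged). Features forming a correlated group (pairwise |r| above
a threshold on the training data, closed transitively) are therefore scored
by removing the *whole group*, and the group score is assigned to every
member; the lowest-scored feature is then eliminated, one per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

__all__ = [
    "NormalizationParams",
    "FoldRecord",
    "ClassifierResult",
    "RfeResult",
    "normalize_fit",
    "normalize_apply",
    "train_svm",
    "rfe_cbr",
    "loocv_matrix",
    "loocv_classify",
]

POSITIVE_LABEL = "C"
NEGATIVE_LABEL = "NC"

# the ClassifierResult dataclass has a field named "property" (the diffusion
# property it classifies), which shadows the builtin inside the class body
_builtin_property = property


# ---------------------------------------------------------------------------
# fold-wise normalization

@dataclass
class NormalizationParams:
    """Per-feature mean and SD estimated on training rows only (SD with n-1)."""

    means: np.ndarray
    sds: np.ndarray
    feature_names: list | None = None

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return X * self.sds + self.means


def normalize_fit(X: np.ndarray, feature_names: list | None = None) -> NormalizationParams:
    """Fit z-scoring parameters on training rows.

    Raises on a constant feature (zero SD), naming it.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("normalization needs at least 2 training rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.nonzero(sds == 0)[0]
    if bad.size:
        name = feature_names[bad[0]] if feature_names is not None else int(bad[0])
        raise ValueError(f"constant feature in training data: {name!r}")
    return NormalizationParams(means=means, sds=sds, feature_names=feature_names)


def normalize_apply(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Apply the affine training transform; no statistics are recomputed."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != params.means.shape[0]:
        raise ValueError(
            f"feature mismatch: data has {X.shape[-1]} features, params expect "
            f"{params.means.shape[0]}"
        )
    return (X - params.means) / params.sds


# ---------------------------------------------------------------------------
# SVM

def default_gamma(X: np.ndarray) -> float:
    """RBF width 1/(n_features * pooled feature variance) of the given matrix."""
    X = np.asarray(X, dtype=float)
    pooled = float(X.var(axis=0, ddof=1).mean())
    if pooled <= 0:
        raise ValueError("pooled feature variance is zero")
    return 1.0 / (X.shape[1] * pooled)


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0, gamma: float | None = None) -> SVC:
    """RBF-kernel SVM; ``y`` codes converters as 1. Positive decision score => C."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if gamma is None:
        gamma = default_gamma(X)
    model = SVC(C=C, kernel="rbf", gamma=gamma)
    model.fit(X, y)
    return model


try:  # low-level libsvm trainer: skips estimator validation in the hot RFE loop
    from sklearn.svm import _libsvm as _llsvm

    _llsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - depends on sklearn internals
    _llsvm = None


def _fit_dual(K: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Dual coefficients a_i = y_i alpha_i (full-length vector) of an SVM fit
    on a precomputed kernel.

    Only quadratic forms a'Ma of the result are consumed, which are invariant
    to the overall sign, so the libsvm fast path needs no label-order sign
    fix-up (a unit test pins its agreement with :class:`sklearn.svm.SVC`).
    """
    a = np.zeros(len(y))
    if _llsvm is not None:
        out = _llsvm.fit(
            np.ascontiguousarray(K, dtype=np.float64),
            np.asarray(y, dtype=np.float64),
            svm_type=0,
            kernel="precomputed",
            C=C,
            tol=1e-3,
            cache_size=200.0,
        )
        support, sv_coef = out[0], out[3]
        a[support] = sv_coef[0]
        return a
    model = SVC(C=C, kernel="precomputed")
    model.fit(K, y)
    a[model.support_] = model.dual_coef_[0]
    return a


# ---------------------------------------------------------------------------
# RFE with correlation-bias reduction

@dataclass
class RfeResult:
    """Outcome of one RFE run.

    ``selected`` — surviving feature columns (sorted); ``elimination_order``
    — columns in the order they were removed (least informative first). The
    concatenation ``elimination_order + selected`` is a full ranking from
    least to most retained.
    """

    selected: list[int]
    elimination_order: list[int]


def _correlation_groups(
    eu: np.ndarray, ev: np.ndarray, active: list[int], n_features: int
) -> list[list[int]]:
    """Connected components of the correlation graph restricted to ``active``.

    ``eu``/``ev`` are the edge endpoints of the full-feature correlation
    graph; components are taken over the active features only (removing a
    feature can split a transitively chained group)."""
    mask = np.zeros(n_features, dtype=bool)
    mask[active] = True
    sel = mask[eu] & mask[ev]
    parent = list(range(n_features))
    for u, v in zip(eu[sel].tolist(), ev[sel].tolist()):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        if u != v:
            parent[u] = v
    groups: dict[int, list[int]] = {}
    for i in active:
        r = i
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        groups.setdefault(r, []).append(i)
    return list(groups.values())


def rfe_cbr(
    X: np.ndarray,
    y: np.ndarray,
    target_k: int = 10,
    C: float = 1.0,
    gamma: float | None = None,
    corr_threshold: float = 0.9,
    use_cbr: bool = True,
) -> RfeResult:
    """SVM-RFE with correlation-bias reduction, one feature per iteration.

    ``X`` is the (already normalized) training matrix, ``y`` the binary
    labels (C = 1). Eliminates the lowest-scored feature per iteration until
    ``min(target_k, n_features)`` remain; ties are broken by eliminating the
    higher column index (the lower node index is kept). ``use_cbr=False``
    gives plain single-feature SVM-RFE.

    Kernels are kept in packed upper-triangle form: for the RBF kernel,
    removing feature i maps K -> K * exp(gamma * D_i) elementwise with D_i
    the squared-difference matrix of feature i, so one precomputed
    per-feature factor serves both the dJ ranking and the kernel update.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, f = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if gamma is None:
        gamma = default_gamma(X)
    keep = min(target_k, f)
    active = list(range(f))
    order: list[int] = []
    if f <= keep:
        return RfeResult(selected=active, elimination_order=order)

    iu0, iu1 = np.triu_indices(n)
    Dtri = (X[iu0] - X[iu1]) ** 2  # (m, f) squared feature differences per pair
    Emat = np.exp(gamma * Dtri).T.copy()  # (f, m)
    Ktri = np.exp(-gamma * Dtri.sum(axis=1))
    # off-diagonal pairs count twice in quadratic forms over the full matrix
    wtri = np.where(iu0 == iu1, 1.0, 2.0)
    Kfull = np.empty((n, n))

    if use_cbr:
        corr = np.corrcoef(X.T)
        adj = np.triu(np.abs(corr) >= corr_threshold, k=1)
        eu, ev = np.nonzero(adj)
    else:
        eu = ev = np.empty(0, dtype=int)

    while len(active) > keep:
        Kfull[iu0, iu1] = Ktri
        Kfull[iu1, iu0] = Ktri
        a = _fit_dual(Kfull, y, C)
        btri = a[iu0] * a[iu1] * Ktri * wtri
        full = btri.sum()  # a' K a
        quad_wo = Emat @ btri  # a' K^(-i) a for every feature
        scores = 0.5 * (full - quad_wo)
        if use_cbr:
            for group in _correlation_groups(eu, ev, active, f):
                if len(group) > 1:
                    e_g = Emat[group].prod(axis=0)
                    scores[group] = 0.5 * (full - e_g @ btri)
        active_scores = scores[active]
        min_score = active_scores.min()
        ties = [active[i] for i in np.nonzero(active_scores == min_score)[0]]
        drop = max(ties)  # keep the lower node index on ties
        Ktri = Ktri * Emat[drop]
        active.remove(drop)
        order.append(drop)
    return RfeResult(selected=active, elimination_order=order)


def rfe_delta_j_oracle(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, gamma: float | None = None
) -> np.ndarray:
    """Independent single-step dJ scores via explicit kernel recomputation.

    For each feature, refits nothing: trains one SVM on the full kernel and
    recomputes the kernel from scratch on the data with that feature deleted
    (``sklearn`` pairwise RBF), returning ``1/2 a'Ka - 1/2 a'K^(-i)a``. Used
    as a brute-force cross-check of the fast elimination path.
    """
    from sklearn.metrics.pairwise import rbf_kernel

    X = np.asarray(X, dtype=float)
    if gamma is None:
        gamma = default_gamma(X)
    K = rbf_kernel(X, gamma=gamma)
    a = _fit_dual(K, y, C)
    full = a @ K @ a
    scores = np.empty(X.shape[1])
    for i in range(X.shape[1]):
        Xi = np.delete(X, i, axis=1)
        Ki = rbf_kernel(Xi, gamma=gamma)
        scores[i] = 0.5 * full - 0.5 * (a @ Ki @ a)
    return scores


# ---------------------------------------------------------------------------
# leave-one-out cross-validation

@dataclass
class FoldRecord:
    """One LOOCV fold: held-out subject, prediction, score, selected features."""

    left_out_subject: str
    true_label: str
    predicted_label: str
    decision_score: float
    selected_nodes: tuple

    @_builtin_property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


@dataclass
class ClassifierResult:
    """All LOOCV folds for one feature set, with pooled performance.

    Accuracy is the proportion of correctly classified subjects (true
    positives + true negatives over N, converters positive); AUC is the
    rank-based area under the ROC of the pooled fold decision scores, ties
    counting one half.
    """

    fold_records: list[FoldRecord]
    tract_id: str | None = None
    property: str | None = None

    @_builtin_property
    def n(self) -> int:
        return len(self.fold_records)

    @_builtin_property
    def accuracy(self) -> float:
        if not self.fold_records:
            raise ValueError("no fold records")
        return float(np.mean([fr.correct for fr in self.fold_records]))

    @_builtin_property
    def auc(self) -> float:
        truths = np.array([fr.true_label == POSITIVE_LABEL for fr in self.fold_records])
        if truths.all() or not truths.any():
            raise ValueError("AUC undefined: only one class present in truth")
        scores = np.array([fr.decision_score for fr in self.fold_records])
        ranks = rankdata(scores)  # midranks: ties contribute 1/2
        n_pos = int(truths.sum())
        n_neg = len(truths) - n_pos
        u = ranks[truths].sum() - n_pos * (n_pos + 1) / 2.0
        return float(u / (n_pos * n_neg))

    def selected_union(self) -> list:
        seen: dict = {}
        for fr in self.fold_records:
            for name in fr.selected_nodes:
                seen[name] = True
        return sorted(seen)


def loocv_matrix(
    X: np.ndarray,
    groups: np.ndarray,
    subjects: list[str],
    feature_names: list,
    target_k: int = 10,
    C: float = 1.0,
    corr_threshold: float = 0.9,
    use_cbr: bool = True,
    tract_id: str | None = None,
    property: str | None = None,
) -> ClassifierResult:
    """Run the full nested LOOCV pipeline on one feature matrix.

    Per fold: z-score on the N-1 training rows, transform both sides with
    the training statistics, RFE-CBR on training data only, train the RBF
    SVM on the selected features, predict the held-out subject. The RBF
    width is fixed per fold at 1/(d0 * pooled variance) of the full
    normalized training matrix (d0 the initial feature count) and reused by
    the RFE criterion and the final fold model.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups, dtype=object)
    n = X.shape[0]
    if n != len(subjects) or n != len(groups):
        raise ValueError("rows, subjects and groups must align")
    y = (groups == POSITIVE_LABEL).astype(int)
    if y.sum() < 2 or (n - y.sum()) < 2:
        raise ValueError("need at least 2 subjects per class for LOOCV")
    records = []
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        Xtr, ytr = X[mask], y[mask]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"class absent from training fold leaving out {subjects[j]}")
        params = normalize_fit(Xtr, feature_names)
        Xtr_n = normalize_apply(params, Xtr)
        Xte_n = normalize_apply(params, X[j : j + 1])
        gamma = default_gamma(Xtr_n)
        rfe = rfe_cbr(
            Xtr_n,
            ytr,
            target_k=target_k,
            C=C,
            gamma=gamma,
            corr_threshold=corr_threshold,
            use_cbr=use_cbr,
        )
        sel = sorted(rfe.selected)
        model = SVC(C=C, kernel="rbf", gamma=gamma)
        model.fit(Xtr_n[:, sel], ytr)
        score = float(model.decision_function(Xte_n[:, sel])[0])
        pred = POSITIVE_LABEL if score > 0 else NEGATIVE_LABEL
        records.append(
            FoldRecord(
                left_out_subject=subjects[j],
                true_label=str(groups[j]),
                predicted_label=pred,
                decision_score=score,
                selected_nodes=tuple(feature_names[i] for i in sel),
            )
        )
    return ClassifierResult(fold_records=records, tract_id=tract_id, property=property)


def loocv_classify(
    cohort,
    tract_id: str,
    property: str,
    target_k: int = 10,
    C: float = 1.0,
    corr_threshold: float = 0.9,
    use_cbr: bool = True,
) -> ClassifierResult:
    """Nested LOOCV classification of one tract's diffusion property.

    ``property`` may be ``"ALL"`` to concatenate the four property profiles
    into one 4 x n_nodes feature vector per subject.
    """
    X, _, names = cohort.feature_matrix(tract_id, property)
    return loocv_matrix(
        X,
        cohort.groups,
        cohort.subjects,
        names,
        target_k=target_k,
        C=C,
        corr_threshold=corr_threshold,
        use_cbr=use_cbr,
        tract_id=tract_id,
        property=property,
    )
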