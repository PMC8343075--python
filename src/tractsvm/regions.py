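"""Predictive-region analysis: node-selection stability, FDR-tested group
differences, region definition, and the final region-restricted classifier.

Because RFE picks 10 nodes inside every LOOCV fold, the per-node selection
frequency across folds measures how stably a node carries discriminative
signal. Nodes selected in at least half the folds (default) are candidates;
candidates that also show FDR-significant group differences (pointwise
pooled-variance t-tests, Benjamini-Hochberg at q = 0.05) — grouped into
maximal runs of consecutive node indices — are the reported predictive
regions. A final SVM classifier restricted to the region nodes (pooled
across tracts and properties) quantifies their joint predictive value with
the identical nested LOOCV pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import ClassifierResult, loocv_matrix

__all__ = [
    "SelectionHistogram",
    "NodeTestResult",
    "Region",
    "RegionReport",
    "selection_histogram",
    "select_candidate_nodes",
    "node_group_tests",
    "define_regions",
    "final_region_classifier",
]


@dataclass
class SelectionHistogram:
    """Per-node RFE selection frequency over LOOCV folds, for all nodes."""

    tract_id: str | None
    property: str | None
    frequencies: np.ndarray  # length n_nodes; node 1 first
    n_folds: int

    def top_nodes(self, k: int) -> list[int]:
        """The k most-selected nodes (1-based), most frequent first; ties by
        lower node index."""
        order = np.lexsort((np.arange(len(self.frequencies)), -self.frequencies))
        return [int(i) + 1 for i in order[:k]]


@dataclass
class NodeTestResult:
    """Pointwise two-sample t-test at one node with its FDR flag."""

    node: int
    t: float
    p: float
    significant: bool


@dataclass
class Region:
    """A maximal run of consecutive predictive nodes in one tract/property."""

    tract_id: str
    property: str
    nodes: list[int]


@dataclass
class RegionReport:
    """Predictive regions plus the final region-restricted classifier output."""

    regions: list[Region]
    final_accuracy: float | None = None
    final_auc: float | None = None
    final_selected_nodes: list = field(default_factory=list)
    final_result: ClassifierResult | None = None


def selection_histogram(result: ClassifierResult, n_nodes: int = 100) -> SelectionHistogram:
    """Fraction of folds in which RFE selected each node.

    Assumes a single-tract, single-property result whose selected feature
    names are ``(tract, property, node)`` triples.
    """
    if not result.fold_records:
        raise ValueError("no fold records")
    counts = np.zeros(n_nodes)
    for fr in result.fold_records:
        for name in fr.selected_nodes:
            node = name[2] if isinstance(name, tuple) else int(name)
            counts[node - 1] += 1
    return SelectionHistogram(
        tract_id=result.tract_id,
        property=result.property,
        frequencies=counts / result.n,
        n_folds=result.n,
    )


def select_candidate_nodes(hist: SelectionHistogram, freq_threshold: float = 0.5) -> list[int]:
    """Nodes (1-based) selected in at least ``freq_threshold`` of folds.

    Never-selected nodes are excluded even at threshold 0, so threshold 0
    means "every node RFE ever picked" and 1.0 "picked in every fold".
    """
    keep = (hist.frequencies >= freq_threshold) & (hist.frequencies > 0)
    return [int(i) + 1 for i in np.nonzero(keep)[0]]


def node_group_tests(
    cohort,
    tract_id: str,
    property: str,
    nodes: list[int],
    q: float = 0.05,
) -> list[NodeTestResult]:
    """Pointwise pooled-variance t-tests (C minus NC) with BH-FDR at ``q``.

    The FDR family is exactly the ``nodes`` tested (df = N - 2, matching the
    cohort-table convention t(85) for N = 87).
    """
    if not nodes:
        return []
    arr = cohort.data[(tract_id, property)]
    is_c = cohort.groups == "C"
    if is_c.sum() < 2 or (~is_c).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    ts, ps = [], []
    for node in nodes:
        a = arr[is_c, node - 1]
        b = arr[~is_c, node - 1]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError(f"zero variance in both groups at node {node}")
        res = stats.ttest_ind(a, b, equal_var=True)
        ts.append(float(res.statistic))
        ps.append(float(res.pvalue))
    flags = multipletests(ps, alpha=q, method="fdr_bh")[0]
    return [
        NodeTestResult(node=n, t=t, p=p, significant=bool(f))
        for n, t, p, f in zip(nodes, ts, ps, flags)
    ]


def _consecutive_runs(nodes: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for n in sorted(nodes):
        if runs and n == runs[-1][-1] + 1:
            runs[-1].append(n)
        else:
            runs.append([n])
    return runs


def define_regions(
    candidates: dict[tuple[str, str], list[int]],
    tests: dict[tuple[str, str], list[NodeTestResult]],
) -> list[Region]:
    """Intersect candidate and FDR-significant nodes; group consecutive runs.

    ``candidates`` maps (tract, property) to candidate node lists and
    ``tests`` to the corresponding pointwise test results. Pairs whose
    intersection is empty simply contribute no region.
    """
    regions: list[Region] = []
    for key in sorted(candidates):
        cand = set(candidates[key])
        sig = {t.node for t in tests.get(key, []) if t.significant}
        for run in _consecutive_runs(sorted(cand & sig)):
            regions.append(Region(tract_id=key[0], property=key[1], nodes=run))
    return regions


def final_region_classifier(
    cohort,
    regions: list[Region],
    target_k: int = 10,
    C: float = 1.0,
    corr_threshold: float = 0.9,
    use_cbr: bool = True,
) -> RegionReport:
    """Nested LOOCV on the region-restricted features pooled across tracts.

    Runs the identical pipeline (fold-wise normalization, RFE to
    ``min(target_k, n_features)``, RBF SVM); reports accuracy, AUC and the
    union of per-fold selected nodes (which can exceed ``target_k`` — each
    fold selects at most ``target_k`` but folds may disagree).
    """
    if not regions:
        raise ValueError("empty region set: no predictive regions to classify")
    spec = [(r.tract_id, r.property, r.nodes) for r in regions]
    X, _, names = cohort.region_feature_matrix(spec)
    result = loocv_matrix(
        X,
        cohort.groups,
        cohort.subjects,
        names,
        target_k=target_k,
        C=C,
        corr_threshold=corr_threshold,
        use_cbr=use_cbr,
    )
    return RegionReport(
        regions=regions,
        final_accuracy=result.accuracy,
        final_auc=result.auc,
        final_selected_nodes=result.selected_union(),
        final_result=result,
    )
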