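"""The end-to-end procedure: per-tract screens, chance/AUC filter,
permutation tests, selection histograms with FDR node tests, region
definition, and the final region-restricted classifier.

Stage order (one cohort in, one report bundle out):

1. nested LOOCV classification of every (tract, property) pair in the
   cohort, plus the concatenated "ALL" feature set per tract when all four
   properties are present;
2. screen: accuracy strictly above the binomial chance threshold for the
   cohort size AND AUC strictly above the floor (0.6);
3. label-permutation significance tests on the surviving pairs;
4. per-survivor node-selection histograms, candidate nodes, pointwise
   t-tests with BH-FDR;
5. predictive regions (candidate AND significant, consecutive runs) and the
   final region-restricted LOOCV classifier.

Every artifact embeds the run configuration and package version; reruns
with identical cohort and configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierResult, loocv_classify
from .cohort import ALL_PROPERTIES, Cohort
from .evaluate import chance_threshold, permutation_test, screen_predictive
from .io import RunConfig
from .regions import (
    RegionReport,
    define_regions,
    final_region_classifier,
    node_group_tests,
    select_candidate_nodes,
    selection_histogram,
)

logger = logging.getLogger("tractsvm")

__all__ = ["run_full_pipeline", "PipelineReport"]


@dataclasses.dataclass
class PipelineReport:
    """Everything the pipeline computed, with provenance."""

    config: RunConfig
    version: str
    n_subjects: int
    acc_threshold: float
    results: dict  # (tract, property) -> ClassifierResult
    survivors: list  # (tract, property) keys surviving the screen
    permutations: dict  # (tract, property) -> PermutationResult
    histograms: dict  # (tract, property) -> SelectionHistogram
    candidates: dict  # (tract, property) -> [nodes]
    node_tests: dict  # (tract, property) -> [NodeTestResult]
    region_report: RegionReport | None
    timings: dict
    error: str | None = None

    def accuracy_table(self) -> pd.DataFrame:
        return self._metric_table("accuracy")

    def auc_table(self) -> pd.DataFrame:
        return self._metric_table("auc")

    def _metric_table(self, metric: str) -> pd.DataFrame:
        tracts = sorted({t for t, _ in self.results})
        props = ["FA", "MD", "RD", "AxD", ALL_PROPERTIES]
        table = pd.DataFrame(index=tracts, columns=props, dtype=float)
        table.index.name = "tract_id"
        for (tract, prop), res in self.results.items():
            table.loc[tract, prop] = getattr(res, metric)
        return table.dropna(axis=1, how="all")


def run_full_pipeline(
    cohort: Cohort, config: RunConfig | None = None, outdir: str | Path | None = None
) -> PipelineReport:
    """Execute the complete screening-to-regions procedure on one cohort.

    Stages after the screen are guarded: on failure the partial report is
    still returned (and written, when ``outdir`` is given) with the error
    recorded.
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    pairs = list(cohort.pairs())
    if config.include_all_properties:
        for tract in cohort.tracts:
            if all((tract, p) in cohort.data for p in ("FA", "MD", "RD", "AxD")):
                pairs.append((tract, ALL_PROPERTIES))
    results: dict = {}
    for tract, prop in pairs:
        results[(tract, prop)] = loocv_classify(
            cohort, tract, prop,
            target_k=config.target_k, C=config.svm_c,
            corr_threshold=config.corr_threshold, use_cbr=config.use_cbr,
        )
        logger.info(
            "screen %s/%s: accuracy %.3f auc %.3f", tract, prop,
            results[(tract, prop)].accuracy, results[(tract, prop)].auc,
        )
    timings["screens"] = time.perf_counter() - t0

    acc_threshold = chance_threshold(cohort.n_subjects, config.alpha)
    surviving = screen_predictive(list(results.values()), acc_threshold, config.auc_floor)
    survivors = [(r.tract_id, r.property) for r in surviving]

    permutations: dict = {}
    histograms: dict = {}
    candidates: dict = {}
    node_tests: dict = {}
    region_report = None
    error = None
    try:
        t1 = time.perf_counter()
        seed_seq = np.random.SeedSequence(config.seed)
        perm_seeds = seed_seq.generate_state(max(len(survivors), 1)) % (2**31)
        for (tract, prop), pseed in zip(survivors, perm_seeds):
            permutations[(tract, prop)] = permutation_test(
                cohort, tract, prop,
                n_perm=config.n_perm, seed=int(pseed),
                observed=results[(tract, prop)],
                target_k=config.target_k, C=config.svm_c,
                corr_threshold=config.corr_threshold, use_cbr=config.use_cbr,
            )
        timings["permutations"] = time.perf_counter() - t1

        t2 = time.perf_counter()
        for tract, prop in survivors:
            if prop == ALL_PROPERTIES:
                continue  # node regions are defined per single property
            hist = selection_histogram(results[(tract, prop)], cohort.n_nodes)
            histograms[(tract, prop)] = hist
            cand = select_candidate_nodes(hist, config.freq_threshold)
            candidates[(tract, prop)] = cand
            tested = list(range(1, cohort.n_nodes + 1)) if config.test_all_nodes else cand
            node_tests[(tract, prop)] = node_group_tests(
                cohort, tract, prop, tested, q=config.fdr_q
            )
        regions = define_regions(candidates, node_tests)
        if regions:
            region_report = final_region_classifier(
                cohort, regions,
                target_k=config.target_k, C=config.svm_c,
                corr_threshold=config.corr_threshold, use_cbr=config.use_cbr,
            )
        else:
            region_report = RegionReport(regions=[])
        timings["regions"] = time.perf_counter() - t2
    except Exception as exc:  # partial results are still reported
        logger.exception("pipeline stage failed; returning partial report")
        error = f"{type(exc).__name__}: {exc}"

    timings["total"] = time.perf_counter() - t0
    report = PipelineReport(
        config=config,
        version=__version__,
        n_subjects=cohort.n_subjects,
        acc_threshold=acc_threshold,
        results=results,
        survivors=survivors,
        permutations=permutations,
        histograms=histograms,
        candidates=candidates,
        node_tests=node_tests,
        region_report=region_report,
        timings=timings,
        error=error,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def _result_to_dict(res: ClassifierResult) -> dict:
    return {
        "tract_id": res.tract_id,
        "property": res.property,
        "accuracy": res.accuracy,
        "auc": res.auc,
        "folds": [
            {
                "left_out_subject": fr.left_out_subject,
                "true_label": fr.true_label,
                "predicted_label": fr.predicted_label,
                "decision_score": fr.decision_score,
                "selected_nodes": [list(n) for n in fr.selected_nodes],
            }
            for fr in res.fold_records
        ],
    }


def write_report(report: PipelineReport, outdir: str | Path) -> None:
    """Write the report bundle: accuracy/AUC CSVs, permutation and region
    JSON, histogram CSVs, and a human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config": report.config.to_dict(), "version": report.version}

    report.accuracy_table().round(4).to_csv(outdir / "accuracy_table.csv")
    report.auc_table().round(4).to_csv(outdir / "auc_table.csv")

    perm = {
        f"{t}/{p}": {
            "observed_accuracy": r.observed_accuracy,
            "t_test_p": r.t_test_p,
            "empirical_p": r.empirical_p,
            "n_perm": r.n_perm,
            "seed": r.seed,
            "null_accuracies": list(np.round(r.null_accuracies, 6)),
        }
        for (t, p), r in report.permutations.items()
    }
    (outdir / "permutations.json").write_text(
        json.dumps({**provenance, "tests": perm}, indent=1)
    )

    hist_rows = []
    for (tract, prop), hist in report.histograms.items():
        sig = {t.node for t in report.node_tests.get((tract, prop), []) if t.significant}
        for node, freq in enumerate(hist.frequencies, start=1):
            hist_rows.append(
                {
                    "tract_id": tract,
                    "property": prop,
                    "node": node,
                    "frequency": freq,
                    "significant": node in sig,
                }
            )
    pd.DataFrame(
        hist_rows,
        columns=["tract_id", "property", "node", "frequency", "significant"],
    ).to_csv(outdir / "selection_histograms.csv", index=False)

    rr = report.region_report
    region_doc = {
        **provenance,
        "acc_threshold": report.acc_threshold,
        "survivors": [f"{t}/{p}" for t, p in report.survivors],
        "regions": [
            {"tract_id": r.tract_id, "property": r.property, "nodes": r.nodes}
            for r in (rr.regions if rr else [])
        ],
        "final_accuracy": rr.final_accuracy if rr else None,
        "final_auc": rr.final_auc if rr else None,
        "final_selected_nodes": [list(n) for n in (rr.final_selected_nodes if rr else [])],
        "error": report.error,
    }
    (outdir / "region_report.json").write_text(json.dumps(region_doc, indent=1))

    lines = [
        f"tractsvm {report.version} pipeline report",
        f"subjects: {report.n_subjects}; chance accuracy threshold: {report.acc_threshold:.2f}",
        f"screens run: {len(report.results)}; survivors: {len(report.survivors)}",
    ]
    for t, p in report.survivors:
        res = report.results[(t, p)]
        line = f"  {t}/{p}: accuracy {res.accuracy:.2f}, AUC {res.auc:.2f}"
        if (t, p) in report.permutations:
            line += f", permutation p {report.permutations[(t, p)].empirical_p:.4g}"
        lines.append(line)
    if rr and rr.regions:
        lines.append("predictive regions:")
        for r in rr.regions:
            lines.append(f"  {r.tract_id}/{r.property}: nodes {r.nodes[0]}-{r.nodes[-1]}")
        lines.append(
            f"final region classifier: accuracy {rr.final_accuracy:.2f}, AUC {rr.final_auc:.2f}"
        )
    else:
        lines.append("no predictive regions identified")
    if report.error:
        lines.append(f"ERROR (partial results): {report.error}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
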