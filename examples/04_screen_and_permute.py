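"""Screen tract/property pairs and test a survivor by label permutation.

Uses a small, fast cohort (15 subjects, 12 nodes) so the full-pipeline
permutation re-runs finish in seconds; the logic is identical at study
scale (87 subjects, 100 nodes, 1,000 permutations).
"""

from tractsvm import (
    EffectSpec,
    SimConfig,
    chance_threshold,
    generate_cohort,
    loocv_classify,
    permutation_test,
    screen_predictive,
)

cfg = SimConfig(
    n_C=7, n_NC=8, tracts=("left_ilf", "right_ifof"), properties=("MD",),
    n_nodes=12, correlation_length=2.0,
    effects=(EffectSpec("left_ilf", "MD", (4, 8), 3.0),), seed=3,
)
cohort = generate_cohort(cfg)
thr = chance_threshold(cohort.n_subjects, 0.05)
results = [loocv_classify(cohort, t, p, target_k=4) for t, p in cohort.pairs()]
for r in results:
    print(f"{r.tract_id}/{r.property}: accuracy {r.accuracy:.2f}, AUC {r.auc:.2f}")

survivors = screen_predictive(results, thr, auc_floor=0.6)
print(f"survivors of the chance (> {thr:.2f}) + AUC (> 0.6) screen: "
      f"{[(r.tract_id, r.property) for r in survivors]}")

for r in survivors:
    perm = permutation_test(
        cohort, r.tract_id, r.property, n_perm=99, seed=0, target_k=4
    )
    print(f"{r.tract_id}: observed {perm.observed_accuracy:.2f}, "
          f"null mean {perm.null_accuracies.mean():.2f}, "
          f"empirical p {perm.empirical_p:.3f}")
# Only the tract carrying the implanted effect survives; its observed
# accuracy sits far above the label-permutation null distribution.
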