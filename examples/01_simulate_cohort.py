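"""Generate a synthetic MCI-conversion cohort with implanted tract effects.

Builds the benchmark cohort (34 converters / 53 non-converters, 100-node
axial-diffusivity profiles along three tracts, localized d = 1.5 group
effects) and writes it to the long-format profile CSV.
"""

import numpy as np

from tractsvm import benchmark_config, generate_cohort, write_profiles

cfg = benchmark_config(seed=0)
cohort = generate_cohort(cfg)
write_profiles(cohort, "benchmark_profiles.csv")

print(f"subjects: {cohort.n_subjects} ({cohort.n_converters} C, "
      f"{cohort.n_subjects - cohort.n_converters} NC)")
print(f"tract/property pairs: {cohort.pairs()}")
for eff in cfg.effects:
    arr = cohort.data[(eff.tract_id, eff.property)]
    is_c = cohort.groups == "C"
    lo, hi = eff.node_range
    shift = arr[is_c, lo - 1:hi].mean() - arr[~is_c, lo - 1:hi].mean()
    print(f"implanted {eff.tract_id} nodes {lo}-{hi}: "
          f"C-NC mean shift {shift:.4f} (x10^-3 mm^2/s)")
print("wrote benchmark_profiles.csv")
# The shifts approximate d * baseline SD = 1.5 * 0.08 = 0.12: converters show
# elevated axial diffusivity exactly where the effects were implanted.
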