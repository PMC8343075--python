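"""Clean a streamline bundle and quantify it into a 100-node tract profile.

Builds a synthetic bundle of 100 fibers around a curved centerline with a
known scalar field along the arc, injects 3 over-length and 2 far-displaced
outlier fibers, applies the 4-SD length / 5-SD core-deviation cleaning
rules, and summarizes the survivors into a distance-weighted profile.
"""

import numpy as np

from tractsvm import clean_bundle, generate_bundle, profile_bundle

t = np.linspace(0.0, 120.0, 60)
centerline = np.column_stack([t, 10 * np.sin(t / 40.0), np.zeros_like(t)])

bundle = generate_bundle(
    100, centerline, dispersion_sd=1.0, length_jitter=0.03,
    outlier_spec={"n_long": 3, "n_far": 2},
    field=lambda s: 0.40 + 0.15 * np.sin(np.pi * s),  # FA bump mid-tract
    seed=42, tract_id="left_arcuate",
)
print(f"fibers before cleaning: {bundle.n_fibers}")
cleaned = clean_bundle(bundle)
print(f"fibers after cleaning:  {cleaned.n_fibers} "
      f"({bundle.n_fibers - cleaned.n_fibers} outliers removed)")

profile = profile_bundle(cleaned, subject_id="s001", property="FA")
print(f"profile nodes 1/50/100: {profile.values[0]:.3f} "
      f"{profile.values[49]:.3f} {profile.values[99]:.3f}")
# The 5 injected outliers are removed exactly; the profile tracks the
# generating field (0.40 at the tract ends, ~0.55 at mid-tract).
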