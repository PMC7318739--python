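"""Perivascular AQP4 profiling on a synthetic cortex micrograph.

Classifies vessels by the shortest-axis/myosin rule, casts the 50 µm x
8.5 µm lumen-anchored profile for five random vessels per class, normalizes
to background and scores the per-animal mean profiles by AUC.
"""

import numpy as np

from brainfluid.perivascular import (
    background_stats,
    extract_profile,
    mean_profile_per_animal,
    normalize_profile,
    sample_vessels,
)
from brainfluid.synthetic import PhantomSpec, make_fluorescence_phantom

spec = PhantomSpec(seed=1)
img, vessels = make_fluorescence_phantom(spec, "WKY", "Cx", "WKY01")
bg_mean, bg_sd = background_stats(img, vessels)
threshold = bg_mean + 2.0 * bg_sd
print(f"background {bg_mean:.1f} ± {bg_sd:.1f} -> anchor threshold {threshold:.1f}")

for cls, chosen in sample_vessels(vessels, n_per_class=5, seed=7).items():
    profiles = [
        normalize_profile(
            extract_profile(img, v, threshold=threshold, neighbours=vessels), bg_mean
        )
        for v in chosen
    ]
    summary = mean_profile_per_animal(profiles)
    peak_um = summary.mean_profile.distances_um[np.argmax(summary.mean_profile.intensity)]
    print(f"{cls:9s}: peak at {peak_um:.2f} µm from the lumen, AUC {summary.auc:6.2f} "
          f"(n={summary.n_vessels})")
print("AUC ordering arteriole > venule > capillary reflects the wider "
      "astrocytic-endfoot AQP4 domain around arterioles")
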