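"""AQP4/beta-actin quantification from electropherogram traces.

Integrates the baseline-subtracted ~34 kDa (AQP4) and ~48 kDa (actin) peaks
of four replicate runs and averages the per-run ratio, as one would for each
animal of a cohort.
"""

from brainfluid.protein import ACTIN_WINDOW, AQP4_WINDOW, aqp4_actin_ratio, integrate_peak
from brainfluid.synthetic import PhantomSpec, make_electropherograms, wes_truth

spec = PhantomSpec(seed=1)
traces = make_electropherograms(spec)["WKY01"]

areas = []
for trace in traces:
    a34 = integrate_peak(trace, AQP4_WINDOW)
    a48 = integrate_peak(trace, ACTIN_WINDOW)
    areas.append((a34, a48))
    print(f"{trace.run_id}: AQP4 area {a34:8.1f}, actin area {a48:8.1f}, "
          f"ratio {a34 / a48:.3f}")

ratio = aqp4_actin_ratio(areas)
truth = wes_truth(spec)["WKY01"]
print(f"mean AQP4/actin ratio over {len(areas)} runs: {ratio:.3f} "
      f"(construction truth {truth:.3f})")
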