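# brainfluid

Quantification pipeline for rodent brain fluid-homeostasis studies — the kind
of study that compares spontaneously hypertensive rats (SHR) with their
normotensive Wistar Kyoto (WKY) controls across MRI, gravimetry,
immunofluorescence and protein assays. The package implements every
quantitative stage of such a study as a tested, reusable library, together
with a synthetic-data generator that emulates all of its inputs with known
ground truth, so the whole pipeline is verifiable end to end without any
acquisition.

## What it computes

* **ADC mapping** (`brainfluid.adc`). Per voxel and gradient direction the
  apparent diffusion coefficient is the least-squares slope of ln *S* against
  *b* under the mono-exponential model *S(b) = S₀ e^(−b·ADC)*; with the
  two-point protocol (b = 0/800 s/mm²) this is exactly ln(S₀/S_b)/b, averaged
  over the three orthogonal directions. ROI summaries exclude CSF-containing
  voxels, whose ~3× faster diffusion would inflate parenchymal means.
* **Volumetry** (`brainfluid.volumetry`). Region volume = voxel count ×
  voxel volume, straight off a label mask; parenchymal volume = intracranial
  − (lateral + third ventricle).
* **Perivascular AQP4 profiling** (`brainfluid.perivascular`). Vessels are
  classified by the shortest-axis diameter (>20 µm with myosin → arteriole,
  without → venule, otherwise capillary); a 50 µm × 8.5 µm band is cast
  perpendicular to the vessel's longest axis starting at the first
  AQP4-immunoreactive pixel seen from the lumen; profiles are normalized to
  background (raw/background − 1), averaged per animal, and scored by the
  trapezoidal area under the curve (AUC) over 0–50 µm.
* **Gravimetry** (`brainfluid.gravimetry`). Brain water as
  100·(wet−dry)/wet percent and as (wet−dry)/dry g water/g dry weight, with
  exact conversions between the two.
* **Protein quantification** (`brainfluid.protein`). Baseline-subtracted
  trapezoidal areas of the ~34 kDa (AQP4) and ~48 kDa (β-actin)
  electropherogram peaks; expression as the AQP4/actin ratio averaged over
  replicate runs.
* **Group statistics** (`brainfluid.stats`). Shapiro–Wilk-gated two-group
  tests (Student's t / Mann–Whitney U), an iterative two-sided Grubbs outlier
  screen (α = 0.05), and two-way ANOVA (strain × region, Type-II sums of
  squares) with Bonferroni-corrected strain-within-region comparisons.
* **Synthetic studies** (`brainfluid.synthetic`, `brainfluid.pipeline`).
  `PhantomSpec` describes a full two-strain cohort (11 WKY vs 10 SHR by
  default, with group effects on ventricular volume, parenchymal ADC, water
  content and the corpus-callosum capillary AQP4 halo); `make_study` emits
  every input with known truth and `run_study` runs all stages and the
  statistics layer over it.

## Worked example

```sh
python examples/perivascular_profiles.py
```

```
background 100.0 ± 1.0 -> anchor threshold 102.0
arteriole: peak at 1.50 µm from the lumen, AUC  22.48 (n=5)
capillary: peak at 1.50 µm from the lumen, AUC   6.13 (n=5)
venule   : peak at 1.50 µm from the lumen, AUC  12.19 (n=5)
```

The AQP4 intensity around each vessel peaks ~1.5 µm outside the lumen — the
astrocytic endfoot sheath — with the same peak height in all three vessel
classes but a wider spatial domain around arterioles, hence the AUC ordering
arteriole > venule > capillary. The other scripts in `examples/` cover water
content (77.1% ↔ 3.37 g/g dry, a 4.7% dry-normalized increase), volumetry,
ADC mapping, electropherogram ratios, and a reduced end-to-end study.

A thin CLI mirrors the library for file-based use:
`brainfluid simulate|volumes|adc|water|aqp4|wes|stats|run --help`.

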