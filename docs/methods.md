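# Methods

This note documents the models and conventions behind each stage, the
synthetic-data generator that stands in for acquisition, the numerical
choices, and the known limitations.

## ADC mapping

The signal model is mono-exponential, *S(b) = S₀ e^(−b·ADC)*. The fit is
ordinary least squares on ln *S* against *b*, per gradient direction, with
the voxel ADC the mean over directions. With the default two-point protocol
(b = 0 and 800 s/mm²) the OLS slope coincides with the closed form
ln(S₀/S_b)/b, so no nonlinear fitting is warranted. Conventions:

* Voxels with any non-positive signal cannot be log-fitted; they are flagged
  invalid rather than imputed.
* Negative fitted ADCs (noise can push *S_b* above *S₀*) are retained and
  flagged valid. Clamping them at zero would bias ROI means upward; the
  reporting layer decides what to do with them.
* CSF exclusion is mask-driven: ROI summaries drop voxels carrying a
  ventricle label. Intensity-based CSF detection is deliberately not
  attempted — on real data the exclusion happens during manual ROI drawing,
  and the masks are the record of it.
* Inputs must be pre-registered to a common grid (the loader checks shapes);
  registration itself is outside the package's scope.

## Volumetry

Volume is exactly voxel count × voxel volume from the mask's spacing — no
smoothing, no partial-volume correction, no interpolation across the 1 mm
slices despite the ~0.14–0.27 mm in-plane pitch. That is how volumes are read
off a manual segmentation, and anything fancier would not be comparable.
Because a single-integer label image cannot represent "total intracranial"
and its contained ventricles simultaneously, `SegmentationMask` supports
composite regions (named unions of base labels); "IC" is the union of all
intracranial labels, mirroring the practice of keeping the intracranial
segmentation separate from the sub-structure segmentation. Parenchymal
volume is IC − (LV + 3V); a negative result raises, since it can only mean
inconsistent masks.

## Perivascular AQP4

* **Classification** is rule-based on the annotation: shortest-axis diameter
  > 20 µm with myosin immunoreactivity → arteriole, the same size without →
  venule, everything else → capillary. The shortest axis is used because
  sections cut vessels obliquely; the short axis approximates the true
  diameter. The rule is total — exactly one class per vessel.
* **Profile geometry.** The ray runs perpendicular to the lumen's longest
  axis (estimated from the polygon's second moments), outward from the
  centroid, on whichever side offers the full 50 µm of clearance; when both
  sides qualify the positive image axis is chosen, so re-analysis is
  deterministic. The 8.5 µm width is implemented as the mean over parallel
  sub-rays at pixel pitch, bilinearly interpolated.
* **Anchoring.** The profile starts at the first pixel along the ray —
  searching outward from the lumen boundary, within a 10 µm budget — whose
  AQP4 intensity exceeds background mean + 2 SD, with background measured at
  least 25 µm away from any annotated vessel. The "+2 SD" detection
  criterion is a convention (the anchoring rule itself does not define
  a threshold) and is configurable.
* **Normalization** maps background to zero: intensity ← raw/background − 1.
  It is scale-invariant (rescaling raw and background together changes
  nothing) and idempotent on background-level signal.
* **Scoring.** Profiles are normalized per image, then averaged per animal
  (per vessel class in the cortex, per region for capillaries), then scored
  by the trapezoidal AUC over 0–50 µm; negative excursions are retained.
  Averaging before vs after background correction is equivalent here because
  the normalization is affine per image.
* A profile that would exit the image or cross a neighbouring lumen raises
  and asks for reselection rather than silently truncating.

## Gravimetry

Both normalizations are kept because percent water compresses oedema: at
~77% water a 0.8 percentage-point group difference corresponds to a ~4.7%
change in g water/g dry weight. The conversion is exact:
g/g = f/(1−f) with f the water mass fraction. Reporting follows convention —
percent at 1 dp, g/g at 2 dp — and the quoted percent increase is computed
from the 2-dp values (3.37 vs 3.22 → 4.7%); full precision is retained
internally. (Computed from unrounded group values the same increase reads
closer to 5%, which is why loosely-quoted versions of this number vary.)

## Protein quantification

Peak areas are trapezoidal integrals of the baseline-subtracted trace over a
window of centre ± 4 kDa; the baseline is the chord joining the trace values
at the window edges, so constant offsets contribute exactly zero. Windows
default to 34 kDa (AQP4) and 48 kDa (β-actin) and are wide enough to also
cover the 33/46 kDa apparent weights seen in some calibrations; they are
configurable. No deconvolution is attempted — one dominant peak per window is
assumed, as in the instrument software. Expression is the per-run AQP4/actin
area ratio averaged over the (default four) replicate runs per animal.

## Statistics layer

* **Gate.** Each group is Shapiro–Wilk-tested at α = 0.05; both pass →
  unpaired Student's t (pooled variance), otherwise Mann–Whitney U,
  two-sided. Constant samples fail the gate by convention. Measured over
  2000 Gaussian nulls at the study's group sizes (11 vs 10) the gated
  procedure rejects at ~0.05, within [0.03, 0.07].
* **Grubbs screen.** Two-sided, iterative (one removal per pass), critical
  value G = ((n−1)/√n)·√(t²/(n−2+t²)) with t the 1−α/(2n) Student quantile
  on n−2 df. Applied per (region × strain) cell of the capillary-AUC table —
  the cell over which screening is applied is a package convention, chosen
  so that regional and strain structure cannot masquerade as outliers.
  Like any single-outlier test applied iteratively it can be masked by
  multiple adjacent outliers in small samples.
* **Two-way ANOVA.** `statsmodels` OLS with strain × region factors and
  Type-II sums of squares (no interaction-driven hypotheses; groups nearly
  balanced at 11 vs 10). Post hoc strain-within-region comparisons are
  unpaired t tests *within each cell*, Bonferroni-corrected by the number of
  regions. The within-cell variance is used instead of the model's pooled
  residual deliberately: perivascular AUC spread scales with the cell mean
  (multiplicative biology), and a pooled residual would undersize the
  comparisons in high-mean cells. With a single region the model reduces to
  a one-way ANOVA whose F equals the squared two-sample t.

## The synthetic-data generator

`PhantomSpec` defaults encode the study conditions: 11 WKY vs 10 SHR; b =
0/800 s/mm², 3 orthogonal directions, 35 mm FOV, 1 mm slices; group effects
on lateral/third-ventricle volume (63.6 vs 35.6 mm³ LV), intracranial and
corpus-callosum volume, parenchymal ADC (0.86 vs 0.96 ×10⁻³ mm²/s, the
reduction localized to cc/thalamus/hypothalamus), water content (77.1 vs
76.3%), and the SHR corpus-callosum capillary halo (height × 0.6); no strain
effect on hippocampal volume, cortical AQP4, GFAP, or the AQP4/actin ratio.
Intracranial volumes (2300 vs 2173 mm³) are set so the derived parenchymal
volume is ~7% lower in SHR, consistent with the reported atrophy.

What it emulates, and how:

* **Imaging.** Regions are connected quasi-spherical voxel sets of exactly
  round(target/voxel-volume) voxels, placed on two rings inside the
  intracranial ball with clearance margins that hold at the jitter extremes.
  Anatomy is deliberately schematic: exact countability and connectedness
  are what volumetry needs, not shape realism. T2w and DWI are emitted on
  one common grid (default 128², 26 slices) — i.e. pre-registered, since
  registration is out of scope. DWI noise is Gaussian on the magnitude with
  relative SD `noise_sd_fraction` (default 0.02); at this SNR the Rician
  bias is negligible, which is why the full Rician model is not used. The
  true SNR of such acquisitions is not knowable from reported values alone;
  the default is a free parameter, not a claim.
* **Microscopy.** Vessels are elliptical lumina (elongated, as oblique
  sections produce) in a clearance-respecting grid layout; the AQP4 channel
  is background × (1 + Gaussian bump in signed distance from the lumen
  boundary: height h, peak 1.5 µm outside the lumen, decay σ of 8/4/1.5 µm
  for arteriole/venule/capillary). The signed-distance rendering keeps the
  profile smooth across the lumen edge, as a point-spread function would.
  The Gaussian form is chosen for its analytic AUC,
  h·σ·√(π/2)·[erf((50−off)/(σ√2)) + erf(off/(σ√2))], which serves as the
  oracle for the extraction pipeline (rendered vs analytic agrees within 2%
  at the default 0.25 µm/px, which gives six samples across the 1.5 µm
  offset). Myosin marks arteriole walls; nuclei and GFAP channels carry
  strain-null levels.
* **Gravimetry** draws the water mass fraction around the strain target
  (Gaussian, SD 0.25 percentage points), fixes the dry weight, and computes
  wet = dry/(1−fraction), so zero jitter reproduces the target exactly.
* **Electropherograms** are Gaussian peaks (σ 0.8/1.0 kDa at 34/48 kDa) on a
  small baseline with trace noise, with per-run amplitudes constructed so
  the analytic area ratio equals the per-run target ratio.
* **Randomness.** Everything derives from one root seed through per-animal,
  per-component seed sequences: identical seeds are bit-identical, and any
  animal or component regenerates in isolation.

Between-animal variability is a generator choice, not a reported quantity.
The defaults — ADC factor CV 2%, region-volume CV 3%, water jitter SD
0.25 pp, AQP4 expression factor uniform on [0.85, 1.15] — are deliberately
modest: the phantom's purpose is recovery-from-construction (does the
pipeline get back what was built in?), not an emulation of cohort power.
Two of these deserve emphasis:

* The AQP4 expression factor is **bounded uniform** rather than Gaussian, so
  that injected gross outliers (4 cells scaled ×6, placed in strain-null
  regions) are the *only* values outside the Grubbs envelope and
  "the screen removes exactly what was injected" is a well-posed check;
  Gaussian inliers would trip a 5%-level Grubbs test at its nominal rate
  somewhere in the 12 cells about half the time. Real expression data are
  not bounded.
* Because spreads are small, the pipeline detects the constructed effects
  with high power. Passing tests therefore show correctness of the
  quantification chain, not that a real 11-vs-10 cohort would reach the same
  significances.

Not emulated: realistic anatomy, pulse-sequence physics, scanner artefacts
(bias fields, ghosting), vessel-orientation diversity (lumina are drawn with
horizontal long axes so every profile ray has guaranteed clearance),
staining variability beyond global expression factors, and molecular-weight
calibration drift.

## Numerical choices and degenerate inputs

* Log-space OLS for ADC (exact for two b-values); tolerance-free closed-form
  identities are asserted at machine precision in the tests.
* Point-to-ellipse distances in the renderer use a vectorized Newton
  iteration (10 steps), exact to rendering precision except deep inside the
  lumen where the halo is zero anyway.
* Bilinear interpolation for all sub-pixel sampling; profile grids run 0 to
  50 µm at pixel pitch inclusive.
* Ties/degenerates: identical groups compare at p = 1; zero-variance
  parametric input raises; Grubbs requires n ≥ 3 and non-constant data;
  empty ROIs after CSF exclusion raise; masks that would make parenchymal
  volume negative raise.
* Problem sizes used by the test-suite and the acceptance script: the full
  default cohort (21 animals, 128²×26 imaging grid, six micrographs per
  animal at 0.25 µm/px) for the end-to-end checks; 2000 replicates for the
  type-I calibration; 400 replicates for the family-wise-error check, tested
  against a binomial-consistency bound rather than the raw 0.05 (a Monte
  Carlo estimate of a quantity that is ≤ 0.05 in expectation fluctuates
  above it).

## Limitations

* The spatial layouts (region slots, vessel grids) guarantee feasibility of
  every measurement; they do not stress occlusion, crowding, or
  border-of-image cases beyond the explicit error paths.
* The Grubbs screen's per-cell convention and the anchor threshold's +2 SD
  are package conventions where the underlying procedures are commonly left
  unstated; both are configurable and recorded here.
* Statistical routes are chosen per dataset by the gate; on another
  cohort the same measurement may legitimately switch between t and
  Mann–Whitney. The report records the route taken.
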