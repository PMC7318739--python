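"""ADC mapping from DWI with CSF exclusion.

Fits the mono-exponential decay S(b) = S0 exp(-b ADC) per voxel and
direction on a two-strain pair of phantoms and summarizes the whole-brain
parenchymal ADC — ventricular (CSF) voxels excluded, since free water at
~3x the tissue diffusivity would inflate the mean.
"""

from brainfluid import fit_adc, roi_adc
from brainfluid.synthetic import PhantomSpec, make_imaging_phantom

spec = PhantomSpec(seed=1)
for strain, animal in (("WKY", "WKY01"), ("SHR", "SHR01")):
    _, dwi, mask, true_map = make_imaging_phantom(spec, strain, animal)
    adc_map = fit_adc(dwi)
    whole = roi_adc(adc_map, mask, "IC", csf_labels=("LV", "3V"))
    naive = roi_adc(adc_map, mask, "IC")  # CSF left in, for comparison
    cc = roi_adc(adc_map, mask, "cc", csf_labels=("LV", "3V"))
    print(f"{strain}: whole-brain ADC {whole.mean_adc * 1e3:.3f} x10^-3 mm²/s "
          f"({whole.n_voxels} voxels); with CSF included it would read "
          f"{naive.mean_adc * 1e3:.3f}; corpus callosum {cc.mean_adc * 1e3:.3f}")
print("the hypertensive phantom carries the lower parenchymal diffusivity "
      "(cytotoxic-oedema-like construction)")
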