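"""Brain water content: converting between the two reported normalizations.

Percent water content compresses oedema changes (a <1 percentage-point
difference), while normalizing to dry matter reveals the same change as a
several-percent shift in g water / g dry weight.
"""

from brainfluid import percent_water_content, water_per_dry, wet_to_dry_normalization

# one hypertensive-like hemisphere: 1.000 g wet, 0.229 g after desiccation
wet, dry = 1.000, 0.229
pct = percent_water_content(wet, dry)
gg = water_per_dry(wet, dry)
print(f"wet {wet:.3f} g, dry {dry:.3f} g -> {pct:.1f}% water, {gg:.2f} g/g dry")

# the group-level conversion: 77.1% vs 76.3% water content
shr = wet_to_dry_normalization(77.1)
wky = wet_to_dry_normalization(76.3)
increase = 100.0 * (round(shr, 2) - round(wky, 2)) / round(wky, 2)
print(f"77.1% -> {shr:.2f} g/g   76.3% -> {wky:.2f} g/g")
print(f"dry-normalized increase: {increase:.1f}%  "
      "(a <1 percentage-point difference in % water)")
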