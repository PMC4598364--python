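"""Project flower spectra into bee and hummingbird colour spaces.

Computes von Kries-adapted receptor excitations of a pink and a green
flower against an average-leaf background under D65 sunlight, then maps
them to the bee colour hexagon (2-D) and the hummingbird opponent space
(3-D). The leaf background itself sits at the hexagon origin: to an
adapted bee it is achromatic.
"""

import floravision as fv

leaf = fv.smooth(fv.make_leaf_background())
bee = fv.bee_visual_system(leaf)
bird = fv.hummingbird_visual_system(leaf)

flowers = []
for name in ("pink", "green"):
    s, _ = fv.simulate_flower_spectrum(fv.DEFAULT_CLASS_PROFILES[name], seed=0)
    flowers.append(fv.smooth(s))

print("bee colour hexagon (x, y; purity = distance from achromatic origin):")
table = fv.project_library([leaf] + flowers, bee)
print(table[["accession", "x", "y", "purity", "hue_angle"]].round(3).to_string(index=False))

print("\nhummingbird colour space (x, y, z):")
table3 = fv.project_library(flowers, bird)
print(table3[["accession", "x", "y", "z", "purity"]].round(3).to_string(index=False))
# z contrasts UV against the red-extending receptor: flowers reflecting UV
# but little red sit at positive z, and stimuli with equal UV and red
# excitation lie exactly in the z = 0 plane.
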