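"""Convert a stained-specimen colour to chromaticity and compute ΔC.

Walks the core colour path by hand: an encoded RGB triple is gamma-decoded,
multiplied by the D65 linear-sRGB matrix to get XYZ tristimulus values,
projected to CIE 1931 (x, y) chromaticity, and compared against a second
point with the ΔC Euclidean distance.
"""

import numpy as np

from cvchroma import decode_channel, delta_c, rgb_to_xyz, xyz_to_lab, xyz_to_xy

# a violet-tinged pixel colour, 8-bit → [0, 1]
encoded = np.array([162, 120, 158]) / 255.0
linear = decode_channel(encoded)
xyz = rgb_to_xyz(linear)
xy = xyz_to_xy(xyz)
lab = xyz_to_lab(xyz)

print(f"encoded RGB : {encoded.round(4)}")
print(f"linear RGB  : {np.round(linear, 4)}")
print(f"XYZ         : {xyz.round(4)}")
print(f"(x, y)      : ({xy[0]:.5f}, {xy[1]:.5f})")
print(f"L*a*b*      : ({lab[0]:.2f}, {lab[1]:.2f}, {lab[2]:.2f})")

# group-mean chromaticities: bare titanium vs 3 days of E. coli immersion
ti_only = (0.3237, 0.3425)
ti_3day = (0.3171, 0.3335)
dc = delta_c(ti_only, ti_3day)
print(f"\nΔC between group means {ti_only} and {ti_3day}: {dc:.5g}")
print("ΔC is the length of the colour shift on the xy plane; larger shifts")
print("mean more crystal-violet stain, i.e. more biofilm.")
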