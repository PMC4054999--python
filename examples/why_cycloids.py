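"""Show why vertical-design length estimation needs cycloid probes.

Vessels in granulation tissue are not isotropic — here they are concentrated
along the vertical (surface-to-cartilage) axis.  The sine-weighted tangents of
a 90°-rotated cycloid keep Lv = 2I/(L_T·T_s) unbiased for any such
azimuthally symmetric tissue; straight horizontal test lines of the same total
length overcount the vertical traces badly.
"""

from woundstereo.validation import anisotropy_comparison

result = anisotropy_comparison(seed=2024, anisotropy=4.0)

print(f"true Lv:                {result['true_Lv']:8.0f} mm⁻²")
print(f"cycloid estimate:       {result['cycloid_Lv']:8.0f} mm⁻²  "
      f"(bias {result['cycloid_bias']:+.1%})")
print(f"straight-line estimate: {result['straight_Lv']:8.0f} mm⁻²  "
      f"(bias {result['straight_bias']:+.1%})")
print()
print("The deliberately wrong probe (straight horizontal lines) roughly")
print("doubles the length density of axially aligned vessels; the cycloid")
print("stays within sampling noise of the truth.")
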