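"""Walk one wound's raw measurements through every estimator.

Numbers are chosen to match the untreated arm of the reference study, so the
printed densities, diffusion distance and diameter can be compared against
the published group means.
"""

from woundstereo import (
    length_density,
    radial_diffusion,
    surface_density,
    totals,
    vessel_diameter,
    volume_fraction,
    wound_closure,
    wound_volume,
)

# wound tracings: a 6-mm punch wound measured at day 0 and day 7
A0, A7 = 28.27, 18.26  # mm²
closure = wound_closure(A0, A7)
print(f"wound closure: {closure:.1f} %  (diabetic wounds close ~35% in a week)")

# six thickness readings from the cartilage to the wound surface
thicknesses = [0.60, 0.70, 0.70, 0.70, 0.70, 0.75]  # mm
volume = wound_volume(thicknesses, 17.4)
print(f"wound volume: {volume:.2f} mm³")

# mean intersection counts per field with the two cycloid systems
Sv = surface_density(I=13.32, L_T=2.4)          # test line 2,400 μm = 2.4 mm
Lv = length_density(I=23.05, L_T=2.24, T_s=0.005)  # 2,240 μm line, 5 μm section
print(f"surface density Sv: {Sv:.1f} mm⁻¹   length density Lv: {Lv:.0f} mm⁻²")

Rdiff = radial_diffusion(Lv)
d = vessel_diameter(Sv, Lv, shrinkage=1.6)
print(f"radial diffusion distance: {Rdiff:.2f} μm  (smaller = denser capillary bed)")
print(f"vessel diameter (×1.6 shrinkage): {d:.2f} μm")

Vv = volume_fraction(P_p=134, P_T=1152)  # pooled over 6 fields of 192 points
print(f"inflammatory volume fraction: {Vv:.3f}")
print(f"total vessel length in wound: {totals(Lv, volume):,.0f} mm")
print(f"total vessel surface in wound: {totals(Sv, volume):.0f} mm²")
print(f"total inflammatory cell volume: {totals(Vv, volume):.2f} mm³")
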