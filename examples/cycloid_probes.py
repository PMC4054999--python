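"""Build the two standard cycloid test systems and export them for audit.

The surface-density probe has its minor axis parallel to the vertical axis
(2,400 μm of test line); the length-density probe is the same cycloid rotated
90 degrees (2,240 μm).  A 192-point grid rides along for volume-fraction
point counting.
"""

from pathlib import Path

from woundstereo import build_test_system, system_to_json, system_to_svg

frame = (700.0, 500.0)  # a 20x field of view, μm

surface = build_test_system("surface", target_L_T=2400.0, frame=frame, r=30.0)
length = build_test_system("length", target_L_T=2240.0, frame=frame, r=28.0)

for name, system in (("surface", surface), ("length", length)):
    print(
        f"{name:8s} probe: {len(system.arcs)} arcs of 4r = {4 * system.arcs[0].r:.0f} μm, "
        f"L_T = {system.L_T:.0f} μm, {system.n_points} grid points"
    )

out = Path("scratch_probes")
out.mkdir(exist_ok=True)
(out / "surface.svg").write_text(system_to_svg(surface))
(out / "surface.json").write_text(system_to_json(surface))
print(f"wrote SVG overlay and JSON description to {out}/")
print("The summed arc length is the exact L_T entering Sv = 2I/L_T;")
print("the SVG can be overlaid on a micrograph to reproduce manual counting.")
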