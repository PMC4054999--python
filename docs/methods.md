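# Methods

## The measurement model

The package implements the vertical-sections stereological design for
quantifying angiogenesis in healing wounds.  Tissue is sectioned on planes
containing a fixed *vertical* axis (the skin-surface-to-cartilage direction;
image rows by convention).  On such sections, unbiased estimation of surface
and length density for arbitrarily anisotropic structures requires test
curves whose tangent directions, weighted by arc length, are distributed
proportionally to sin(angle to the vertical axis) — the defining property of
the cycloid.  Two probe configurations are used:

* **surface mode** — minor axis parallel to the vertical axis; boundary
  crossings `I` with vessel-profile walls on the section plane give
  `S_V = 2I / L_T`;
* **length mode** — the same cycloid rotated 90°; crossings with vessel
  traces projected through the section thickness give
  `L_V = 2I / (L_T · T_s)` (the projected thick-slab design).

A regular 192-point grid overlays each field for volume-fraction point
counting (`V_v = P_p / P_T`), and the morphometric quantities (percentage
closure, six-point wound volume, percentage epithelialization) are plain
arithmetic on wound tracings.  Derived quantities: the Krogh radius
`R_diff = 1/√(π·L_V)` (mean tissue radius served by one capillary) and the
mean vessel diameter `d = S_V/(π·L_V)`, exact for cylinders since
`S_V = π·d·L_V`.  The histological shrinkage factor (default 1.6) multiplies
the diameter only; densities and `R_diff` are reported uncorrected.  Totals
are densities × wound volume, where wound volume uses the necropsy-day traced
area.

Counting semantics differ deliberately between the two designs.  A test line
passing through a vessel profile crosses the vessel *wall* twice, so the
surface count is the number of membership transitions.  The length design
counts intersections with the projected *linear feature* (the vessel axis), so
one transversal pass is one intersection; using wall transitions there would
double `L_V`.

## Field sampling

Fields of view (default five per section) are placed across the wound bed by
systematic uniform random sampling: period = span / n_fields, one uniformly
random start per section, centers at start + k·period.  Counts are pooled
across all fields and sections of a wound as a ratio of sums (pool counts,
then apply the formulas), the standard design-based choice; a
`per_field_mean` switch reproduces mean-of-ratios for sensitivity analysis.
Per-wound values, not per-field values, are the statistical unit.

## Counting on rasters

Masks are binary rasters with physical pixel size.  Membership along a test
curve is sampled at sub-pixel steps (min(pixel/4, 0.05 μm)) against the
0.5-level set of the mask after Gaussian pre-smoothing (σ = 0.6 px) and
bilinear interpolation.  Two raster artefacts motivated this:

* Raw nearest-pixel membership makes the effective boundary the pixel
  *staircase*, whose edges are only horizontal/vertical; crossing counts are
  then inflated by the Manhattan factor E[|sin φ|+|cos φ|] of the probe's
  tangent distribution (≈ +28% for cycloids), independent of resolution.
  The smoothed level set restores a boundary whose crossings match the exact
  disc-crossing expectation within ~1–2% for both straight and cycloid
  probes.
* σ = 0.6 px balances the residual level-set wiggle (overcount) against
  curvature erosion of profiles only a few pixels across (undercount);
  capillary profiles of ~2 px radius are near this floor, and surface
  densities of sub-micron vessels should be counted at ≤ 0.25 μm/px.

Point-grid hits use plain nearest-pixel lookup (floor of coordinate/pixel), a
deterministic tie-break.

For the length design on *synthetic* sections, counting uses the exact
projected-centerline overlay (`SectionImage.trace_segments`) by
segment–polyline intersection.  In a 5-μm slab the projected traces are
themselves only ~5 μm long, so any rasterized trace of ≥ 1 px effective width
biases run counts by O(pixel / trace length) — tens of percent at practical
resolutions — while the vector overlay is the zero-width linear-feature image
the estimator's theory assumes.  Mask-based run counting remains available
for real raster data; note that counting runs on full tube *silhouettes*
(2-μm vessels projected through 5 μm) overestimates `L_V` by roughly 2× — the
classical overprojection problem, which applies equally to manual counting on
thick-section micrographs.

## Synthetic microanatomy

Vessels are straight cylinders: midpoints uniform in the box dilated by half
a segment length (a stationary Boolean segment process restricted to the box,
hence uniform density inside), directions isotropic or concentrated toward
the vertical axis (azimuthally symmetric, the symmetry the vertical design
assumes), clipped to the box.  Ground truth is exact bookkeeping:
`true_Lv` = clipped centerline length / volume, `true_Sv` = lateral cylinder
surface / volume, so `Sv/Lv = π·d` holds exactly at zero diameter spread.
Generation stops once the clipped density reaches the target and refuses
configurations whose vessel volume fraction exceeds 5% (keeping tube-overlap
surface below ~1%).  Curvature and branching are not modelled — they do not
enter the density identities used as truth.  Default segment length is
50–100 μm, the order of intercapillary branch distances.

Inflammatory cells are non-overlapping spheres (default radius 4 μm, ~8-μm
lymphocytes) placed by random sequential addition fully inside the box, so
`true_Vv` is exactly n·(4/3 πR³)/V.

Sections are rasterized as exact finite-cylinder geometry (a pixel is
foreground iff its center is covered): `thin` mode is the mid-plane
intersection (elliptical profiles — the geometry the surface and
volume-fraction estimators assume), `projected` mode the silhouette of
cylinder ∩ slab (validated against a voxel oracle), `trace` mode the
rasterized projected centerlines.  `cut_section_pair` bundles the thin mask,
the trace raster and the vector overlay into one section object.

What the generator does **not** emulate: staining variability and
segmentation error (inputs here are perfect masks), vessel curvature,
branching and diameter taper, section compression/tearing, and the spatial
heterogeneity of a real wound bed (density gradients from edge to center).
Passing recovery tests therefore demonstrate correctness of the probes,
counting and formulas under known geometry — not robustness to imaging or
segmentation artefacts.

## Synthetic studies

`generate_study` draws per-wound true parameters (closure, L_V, S_V, V_v,
volume) from truncated normals (at 0, and 100 for closure) with per-arm
means/SDs.  The default parameterization reproduces a published four-arm
diabetic rabbit ear ulcer study (untreated, collagen, CAC+collagen,
CAC(OPN)+collagen; n = 8 wounds/arm).  Closure means per arm were not
published and are reconstructed from the three pairwise Fisher-LSD interval
midpoints plus the pooled diabetic mean (24.2 / 32.1 / 38.0 / 47.4%, common
SD 8.9).  Per-wound cylinder diameter follows from the drawn S_V/(π·L_V), so
each wound's tissue is internally consistent.  Rendered studies use a
300×300×180 μm block per wound, four section pairs, 0.25 μm/px and 48-μm
fields with 288 μm of cycloid per field — sized so the per-wound estimation
CV stays well below the published between-wound CV.

## Statistics

Classical equal-variance analyses, as appropriate for n = 8 arms: pooled
two-sample t (Welch optional), one-way ANOVA, and *unprotected* Fisher-LSD
95% mean-difference intervals always reported together with the omnibus p
(a `protected` switch gates them on omnibus significance).  Per-group Pearson
matrices cover {closure, V_v, S_V, L_V, R_diff, d}; variables whose spread is
at rounding level are reported as undefined (NaN), never silently zero.
ANOVA type-I error is calibrated at 5% ± 2% on null studies in the test
suite.  The strong negative R_diff–L_V correlation seen in group analyses is
structural (R_diff is a decreasing function of L_V) and serves as an internal
consistency check.

## Numerical and design choices

* Canonical internal unit is μm; reported units are mm⁻¹, mm⁻², μm, mm³.
  Test-line lengths are interpreted in micrometers (2,400/2,240 μm);
  nanometer-scale test lines would be physically meaningless at 20×.
* Cycloid radii default to values making L_T an integer number of 4r arcs
  (r = 30 μm for 2,400; r = 28 μm for 2,240); arcs are sampled at equal
  arc-length steps via s(t) = 4r(1 − cos(t/2)), so polyline length matches
  4r to < 0.01%.
* Validation experiment sizes (tissue 800×560×300 μm, 30 sections, five
  80-μm fields with L_T = 640 μm, 0.5 μm/px) were chosen so single-run
  sampling error stays at the few-percent level; the field band is cycled
  systematically through the tissue depth across sections to decorrelate
  individual segments' contributions.
* Degenerate inputs fail loudly (typed exceptions) rather than returning
  sentinel values; zero-variance statistical inputs use the conventional
  (0, 1) t-test result only in the exactly-degenerate equal-means case.

## Known limitations

* Real single-mask data (one micrograph serving both counts) inherits
  overprojection bias in L_V and finite-thickness bias in S_V; the package
  quantifies these on synthetic tissue but cannot remove them from real
  thick-section counts.
* Sub-micron vessel profiles at ≥ 0.5 μm/px sit at the raster resolution
  floor; surface densities there carry raster bias of order 10%.
* Wounds are treated as independent (no ear/animal random effects), matching
  the reference analysis; a mixed-effects extension is out of scope.
* Epithelialization is computed from supplied lengths only; no detection of
  epithelium in images.
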