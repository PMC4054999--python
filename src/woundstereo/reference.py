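"""Published group-level summary statistics used as default study conditions.

These are the printed mean ± SD values (n = 8 wounds per arm) from a four-arm
diabetic rabbit ear ulcer experiment comparing collagen scaffolds seeded with
circulating angiogenic cells (CACs), with or without ex-vivo osteopontin (OPN)
exposure, against collagen alone and untreated wounds.  They serve two roles:

* default parameterization of the synthetic study generator, so simulated
  studies reproduce realistic effect sizes and between-wound variability;
* inputs to internal-consistency checks — the diffusion distance and vessel
  diameter columns are recomputable from the density columns by closed form.

Closure means per arm were not published; they are reconstructed from the
pairwise Fisher-LSD 95% confidence intervals (midpoints 23.18, 15.25 and
13.81 for CAC(OPN)−untreated, CAC(OPN)−collagen and CAC−untreated) together
with the pooled diabetic closure mean of 35.4%, and the common SD of 8.9 is
back-solved from the CI half-width 9.07 at 28 within-group degrees of freedom.
"""

from __future__ import annotations

import math

__all__ = [
    "GROUPS",
    "REFERENCE_GROUPS",
    "SHRINKAGE_FACTOR",
    "SECTION_THICKNESS_UM",
    "PUNCH_AREA_MM2",
]

SHRINKAGE_FACTOR = 1.6
SECTION_THICKNESS_UM = 5.0
#: Day-0 area of a 6-mm punch biopsy wound.
PUNCH_AREA_MM2 = math.pi * 3.0**2

GROUPS = ("CAC_OPN_collagen", "CAC_collagen", "collagen", "untreated")

#: Printed group summaries: mean and SD per parameter.
#: volume mm^3; inflam_total mm^3; Sv mm^-1; surface_total mm^2; Lv mm^-2;
#: length_total mm; Rdiff μm; diameter μm (shrinkage-corrected);
#: closure % (reconstructed, see module docstring); Vv = inflam_total/volume.
REFERENCE_GROUPS: dict[str, dict[str, tuple[float, float]]] = {
    "CAC_OPN_collagen": {
        "volume": (13.2, 5.1),
        "inflam_total": (2.37, 0.97),
        "Sv": (22.4, 9.3),
        "surface_total": (306.3, 178.0),
        "Lv": (6212.0, 1424.0),
        "length_total": (81678.0, 35117.0),
        "Rdiff": (7.29, 0.9),
        "diameter": (1.8, 0.47),
        "closure": (47.4, 8.9),
    },
    "CAC_collagen": {
        "volume": (14.1, 3.5),
        "inflam_total": (3.01, 1.16),
        "Sv": (21.6, 4.34),
        "surface_total": (330.5, 20.0),
        "Lv": (6534.0, 1589.0),
        "length_total": (90490.0, 26997.0),
        "Rdiff": (7.16, 0.1),
        "diameter": (1.76, 0.46),
        "closure": (38.0, 8.9),
    },
    "collagen": {
        "volume": (17.4, 3.6),
        "inflam_total": (3.21, 0.91),
        "Sv": (25.6, 5.8),
        "surface_total": (442.0, 112.0),
        "Lv": (7575.0, 1610.0),
        "length_total": (131220.0, 34187.0),
        "Rdiff": (6.56, 0.6),
        "diameter": (1.74, 0.3),
        "closure": (32.1, 8.9),
    },
    "untreated": {
        "volume": (12.03, 3.69),
        "inflam_total": (1.39, 0.5),
        "Sv": (11.1, 5.0),
        "surface_total": (146.0, 116.0),
        "Lv": (4116.0, 1093.0),
        "length_total": (49337.0, 51595.0),
        "Rdiff": (9.05, 0.15),
        "diameter": (1.35, 0.38),
        "closure": (24.2, 8.9),
    },
}


def group_vv(group: str) -> tuple[float, float]:
    """Inflammatory-cell volume fraction implied by printed totals and volumes.

    Vv mean = inflam_total / volume; the SD is propagated proportionally from
    the inflam_total SD (a first-order approximation adequate for simulation).
    """
    g = REFERENCE_GROUPS[group]
    mean = g["inflam_total"][0] / g["volume"][0]
    sd = mean * g["inflam_total"][1] / g["inflam_total"][0]
    return mean, sd
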