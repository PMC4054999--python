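"""Cycloid test systems, point grids and systematic uniform random field placement.

Vertical-sections stereology estimates surface and length densities of
anisotropic structures (here: capillaries in granulation tissue) from 2D
sections cut parallel to a fixed *vertical* axis.  The probes that make those
estimators unbiased are cycloid arcs: the tangent directions of a cycloid,
weighted by arc length, are distributed proportionally to sin(angle from the
minor axis).  With the minor axis parallel to the vertical axis the cycloid is
the correct probe for surface density; rotated by 90 degrees it is the correct
probe for length density on projected thick sections (the Gokhale design).

Coordinates are 2D (x, y) in micrometers with ``y`` the vertical
(skin-surface-to-cartilage) axis, which maps to image rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidParameterError, SamplingError

__all__ = [
    "CycloidArc",
    "StraightLineProbe",
    "TestSystem",
    "SamplingPlan",
    "ProbeConfig",
    "make_cycloid_arc",
    "build_test_system",
    "build_line_system",
    "build_point_grid",
    "plan_fields",
    "sample_polyline",
    "system_to_json",
    "system_to_svg",
]

#: Probe modes. ``surface`` = minor axis parallel to the vertical axis
#: (Formula-B counting); ``length`` = minor axis rotated 90 degrees
#: (Formula-C counting on projected sections).
MODE_SURFACE = "surface"
MODE_LENGTH = "length"


@dataclass(frozen=True)
class CycloidArc:
    """One half-arch of a cycloid, sampled as a polyline.

    The canonical arch is x(t) = r(t - sin t), y(t) = r(1 - cos t) for
    t in [0, pi]; its analytic length is 4r and its extent along the local
    minor axis (canonical y) is 2r.  ``orientation`` is the angle of the minor
    axis with respect to the vertical axis, in radians.
    """

    r: float
    orientation: float
    anchor: tuple[float, float]
    vertices: np.ndarray  # (n, 2) float array, μm

    @property
    def length(self) -> float:
        """Declared (analytic) arc length, 4r."""
        return 4.0 * self.r

    @property
    def minor_axis(self) -> float:
        return 2.0 * self.r

    def polyline_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def translated(self, dx: float, dy: float) -> "CycloidArc":
        return CycloidArc(
            r=self.r,
            orientation=self.orientation,
            anchor=(self.anchor[0] + dx, self.anchor[1] + dy),
            vertices=self.vertices + np.array([dx, dy]),
        )


@dataclass(frozen=True)
class StraightLineProbe:
    """A straight test segment.

    Not part of the vertical design: straight lines of fixed orientation are a
    deliberately orientation-biased probe, kept only as a control to
    demonstrate why cycloids are required on anisotropic tissue.
    """

    vertices: np.ndarray  # (2, 2)

    @property
    def length(self) -> float:
        return float(np.hypot(*(self.vertices[1] - self.vertices[0])))

    def translated(self, dx: float, dy: float) -> "StraightLineProbe":
        return StraightLineProbe(self.vertices + np.array([dx, dy]))


@dataclass(frozen=True)
class TestSystem:
    """A set of test curves plus a point grid laid out in a rectangular frame.

    ``L_T`` is the total declared test-line length (μm); for volume-fraction
    point counting ``point_grid`` holds ``n_points`` regularly spaced points.
    ``frame`` is (width, height) in μm with the origin at (0, 0).
    """

    arcs: tuple
    L_T: float
    mode: str
    point_grid: np.ndarray  # (n, 2)
    frame: tuple[float, float]

    @property
    def n_points(self) -> int:
        return len(self.point_grid)

    def summed_arc_length(self) -> float:
        return float(sum(a.length for a in self.arcs))

    def translated(self, dx: float, dy: float) -> "TestSystem":
        return TestSystem(
            arcs=tuple(a.translated(dx, dy) for a in self.arcs),
            L_T=self.L_T,
            mode=self.mode,
            point_grid=self.point_grid + np.array([dx, dy]),
            frame=self.frame,
        )


@dataclass(frozen=True)
class SamplingPlan:
    """Systematic uniform random placement of fields across a wound span.

    Fields are placed at a fixed ``period`` with a single uniformly random
    start, so every position along the wound bed has equal sampling
    probability.  ``wound_span`` is the (lo, hi) interval (μm) from one wound
    edge to the other; field centers run ordered from one edge to the other.
    """

    n_fields: int
    field_size: tuple[float, float]
    wound_span: tuple[float, float]
    period: float
    random_start: float
    seed: int

    @property
    def centers(self) -> np.ndarray:
        lo = self.wound_span[0]
        return lo + self.random_start + self.period * np.arange(self.n_fields)


@dataclass
class ProbeConfig:
    """Default probe configuration mirroring the study protocol.

    Test-line lengths are in micrometers; the generator radii default so each
    target length is an integer number of 4r arcs.
    """

    L_T_surface_um: float = 2400.0
    L_T_length_um: float = 2240.0
    cycloid_r_surface_um: float = 30.0
    cycloid_r_length_um: float = 28.0
    n_grid_points: int = 192
    n_fields: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# cycloid construction


def make_cycloid_arc(
    r: float,
    orientation: float = 0.0,
    anchor: Sequence[float] = (0.0, 0.0),
    vertex_spacing: float | None = None,
) -> CycloidArc:
    """Build a half-arch cycloid polyline of analytic length 4r.

    Vertices are placed at equal arc-length steps (``vertex_spacing``, default
    r/50, must be <= r/10) using the closed-form arc-length parameterization
    s(t) = 4r(1 - cos(t/2)), so the chord-summed polyline length matches 4r to
    well under 0.1%.  ``orientation`` rotates the minor axis away from the
    vertical (+y) axis; ``anchor`` translates the canonical origin.
    """
    if r <= 0:
        raise InvalidParameterError(f"cycloid generator radius must be > 0, got {r}")
    if vertex_spacing is None:
        vertex_spacing = r / 50.0
    if vertex_spacing <= 0:
        raise InvalidParameterError("vertex_spacing must be > 0")
    if vertex_spacing > r / 10.0 + 1e-12:
        raise InvalidParameterError(
            f"vertex_spacing {vertex_spacing} too coarse; must be <= r/10 = {r / 10}"
        )
    total = 4.0 * r
    n_seg = max(int(math.ceil(total / vertex_spacing)), 4)
    s = np.linspace(0.0, total, n_seg + 1)
    # s(t) = 4r (1 - cos(t/2))  =>  t = 2 arccos(1 - s / 4r)
    t = 2.0 * np.arccos(np.clip(1.0 - s / total, -1.0, 1.0))
    lx = r * (t - np.sin(t))
    ly = r * (1.0 - np.cos(t))
    c, sn = math.cos(orientation), math.sin(orientation)
    gx = c * lx + sn * ly
    gy = -sn * lx + c * ly
    verts = np.column_stack([gx + anchor[0], gy + anchor[1]])
    return CycloidArc(r=r, orientation=orientation, anchor=(float(anchor[0]), float(anchor[1])), vertices=verts)


def _arc_footprint(r: float, orientation: float) -> tuple[float, float]:
    """Bounding-box (width, height) of one arch at the given orientation."""
    probe = make_cycloid_arc(r, orientation, (0.0, 0.0), vertex_spacing=r / 50.0)
    lo = probe.vertices.min(axis=0)
    hi = probe.vertices.max(axis=0)
    return float(hi[0] - lo[0]), float(hi[1] - lo[1])


def build_test_system(
    mode: str,
    target_L_T: float,
    frame: tuple[float, float],
    r: float,
    n_grid_points: int = 192,
    vertex_spacing: float | None = None,
) -> TestSystem:
    """Lay ceil(target_L_T / 4r) cycloid arcs on a regular lattice in ``frame``.

    The recorded ``L_T`` is the exact summed declared arc length, which is
    within one arc (4r) above ``target_L_T``.  ``mode='surface'`` uses
    orientation 0 (minor axis vertical); ``mode='length'`` uses pi/2.
    A point grid of ``n_grid_points`` is overlaid for volume-fraction counting.
    """
    if target_L_T <= 0:
        raise InvalidParameterError("target_L_T must be > 0")
    if mode not in (MODE_SURFACE, MODE_LENGTH):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    orientation = 0.0 if mode == MODE_SURFACE else math.pi / 2.0
    n_arcs = int(math.ceil(target_L_T / (4.0 * r) - 1e-9))
    fw, fh = frame
    cw, ch = _arc_footprint(r, orientation)
    layout = None
    best_score = None
    for cols in range(1, n_arcs + 1):
        rows = int(math.ceil(n_arcs / cols))
        if cols * cw <= fw + 1e-9 and rows * ch <= fh + 1e-9:
            # prefer the most balanced feasible lattice
            score = abs(math.log((cols * cw) / (rows * ch)))
            if best_score is None or score < best_score:
                best_score = score
                layout = (cols, rows)
    if layout is None:
        raise ConfigurationError(
            f"frame {frame} cannot hold {n_arcs} arcs of footprint ({cw:.1f}, {ch:.1f}) μm"
        )
    cols, rows = layout
    sx, sy = fw / cols, fh / rows
    arcs = []
    k = 0
    for j in range(rows):
        for i in range(cols):
            if k >= n_arcs:
                break
            arc = make_cycloid_arc(r, orientation, (0.0, 0.0), vertex_spacing)
            lo = arc.vertices.min(axis=0)
            hi = arc.vertices.max(axis=0)
            bbox_center = (lo + hi) / 2.0
            cell_center = np.array([(i + 0.5) * sx, (j + 0.5) * sy])
            shift = cell_center - bbox_center
            arcs.append(arc.translated(shift[0], shift[1]))
            k += 1
    grid = build_point_grid(n_grid_points, frame)
    L_T = float(sum(a.length for a in arcs))
    return TestSystem(arcs=tuple(arcs), L_T=L_T, mode=mode, point_grid=grid, frame=frame)


def build_line_system(
    target_L_T: float,
    frame: tuple[float, float],
    n_lines: int,
    n_grid_points: int = 192,
) -> TestSystem:
    """Control probe: horizontal straight lines of total length ``target_L_T``.

    Straight lines of a fixed orientation violate the sine-weighting required
    by the vertical design; this system exists to demonstrate the bias cycloids
    avoid on anisotropic tissue.  Lines are stacked evenly through the frame.
    """
    if target_L_T <= 0 or n_lines < 1:
        raise InvalidParameterError("need target_L_T > 0 and n_lines >= 1")
    fw, fh = frame
    line_len = target_L_T / n_lines
    if line_len > fw + 1e-9:
        raise ConfigurationError(f"line length {line_len} exceeds frame width {fw}")
    x0 = (fw - line_len) / 2.0
    probes = []
    for j in range(n_lines):
        y = (j + 0.5) * fh / n_lines
        probes.append(StraightLineProbe(np.array([[x0, y], [x0 + line_len, y]])))
    grid = build_point_grid(n_grid_points, frame)
    return TestSystem(arcs=tuple(probes), L_T=float(target_L_T), mode="line", point_grid=grid, frame=frame)


def build_point_grid(n_points: int, frame: tuple[float, float]) -> np.ndarray:
    """Regular a×b lattice of exactly ``n_points`` points with half-spacing margins.

    The factorization a×b = n_points is chosen to best match the frame aspect
    ratio; a mismatch worse than a factor of 2 raises ``ConfigurationError``.
    """
    if n_points < 1:
        raise InvalidParameterError("n_points must be >= 1")
    fw, fh = frame
    aspect = fw / fh
    best = None
    for a in range(1, n_points + 1):
        if n_points % a:
            continue
        b = n_points // a
        score = abs(math.log((a / b) / aspect))
        if best is None or score < best[0]:
            best = (score, a, b)
    score, a, b = best
    if score > math.log(2.0) + 1e-9:
        raise ConfigurationError(
            f"{n_points} points cannot be factored into a lattice matching aspect {aspect:.2f}"
        )
    xs = (np.arange(a) + 0.5) * fw / a
    ys = (np.arange(b) + 0.5) * fh / b
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def plan_fields(
    wound_span: tuple[float, float],
    field_size: tuple[float, float],
    n_fields: int,
    seed: int,
) -> SamplingPlan:
    """Systematic uniform random (SUR) field placement across the wound bed.

    period = span / n_fields; a single random start is drawn uniformly on
    [0, period) from a seeded generator and field centers sit at
    ``start + k * period``, ordered from one wound edge to the other.
    """
    lo, hi = wound_span
    span = hi - lo
    if n_fields < 1:
        raise InvalidParameterError("n_fields must be >= 1")
    fw = field_size[0]
    if span < n_fields * fw - 1e-9:
        raise SamplingError(
            f"wound span {span} μm too short for {n_fields} fields of width {fw} μm"
        )
    period = span / n_fields
    rng = np.random.default_rng(seed)
    start = float(rng.uniform(0.0, period))
    return SamplingPlan(
        n_fields=n_fields,
        field_size=(float(field_size[0]), float(field_size[1])),
        wound_span=(float(lo), float(hi)),
        period=float(period),
        random_start=start,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# geometry helpers and export


def sample_polyline(vertices: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at equal arc-length steps (endpoint included)."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = max(int(math.ceil(total / step)), 1)
    s = np.linspace(0.0, total, n + 1)
    x = np.interp(s, cum, vertices[:, 0])
    y = np.interp(s, cum, vertices[:, 1])
    return np.column_stack([x, y])


def system_to_json(system: TestSystem) -> str:
    """Audit export: arc anchors, r, orientation, L_T and grid points as JSON."""
    arcs = []
    for a in system.arcs:
        if isinstance(a, CycloidArc):
            arcs.append(
                {"kind": "cycloid", "r": a.r, "orientation": a.orientation, "anchor": list(a.anchor)}
            )
        else:
            arcs.append({"kind": "line", "vertices": a.vertices.tolist()})
    return json.dumps(
        {
            "mode": system.mode,
            "L_T_um": system.L_T,
            "frame_um": list(system.frame),
            "arcs": arcs,
            "point_grid_um": system.point_grid.tolist(),
        },
        indent=2,
    )


def system_to_svg(system: TestSystem) -> str:
    """Render the test system as an SVG overlay (1 unit = 1 μm)."""
    fw, fh = system.frame
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {fw:.3f} {fh:.3f}" '
        f'width="{fw:.0f}" height="{fh:.0f}">',
        f'<rect x="0" y="0" width="{fw:.3f}" height="{fh:.3f}" fill="none" '
        'stroke="black" stroke-width="0.2"/>',
    ]
    for a in system.arcs:
        pts = " ".join(f"{x:.3f},{y:.3f}" for x, y in a.vertices)
        parts.append(
            f'<polyline points="{pts}" fill="none" stroke="blue" stroke-width="0.3"/>'
        )
    for x, y in system.point_grid:
        parts.append(f'<circle cx="{x:.3f}" cy="{y:.3f}" r="0.5" fill="red"/>')
    parts.append("</svg>")
    return "\n".join(parts)
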