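"""Synthetic 3D microanatomy with exactly known Lv, Sv and Vv.

The study this pipeline models deposited no raw images, so every estimator is
validated against simulated granulation tissue instead: straight cylindrical
vessel segments (random or axially concentrated orientations) and
non-overlapping inflammatory-cell spheres inside a 3D box, with bookkept
ground truth,

* true_Lv = total clipped centerline length / box volume   (mm⁻²)
* true_Sv = total lateral cylinder surface / box volume    (mm⁻¹)
* true_Vv = total sphere volume / box volume               (fraction)

Vertical sections are cut on planes containing the vertical (z) axis and
rasterized into calibrated binary masks: ``thin`` mode intersects each
cylinder with the mid-plane (elliptical profiles, the geometry the surface and
volume-fraction estimators assume), ``projected`` mode renders the exact
silhouette of each cylinder within a slab of the section thickness (the
geometry the Gokhale length estimator assumes).  Straight segments keep the
bookkeeping exact; curvature would not change the density identities used as
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .counting import TRACE_HALF_WIDTH_UM, SectionImage
from .errors import GenerationError, InvalidParameterError, SectioningError
from .estimators import radial_diffusion, totals, vessel_diameter
from .reference import GROUPS, PUNCH_AREA_MM2, REFERENCE_GROUPS, group_vv

__all__ = [
    "VesselSegment",
    "SyntheticTissue",
    "SyntheticWound",
    "SyntheticStudy",
    "RenderConfig",
    "generate_network",
    "generate_cell_field",
    "cut_vertical_section",
    "cut_section_pair",
    "generate_study",
    "reference_group_params",
]

_MAX_VESSEL_VOLUME_FRACTION = 0.05  # keeps tube overlaps < ~1% of surface


@dataclass(frozen=True)
class VesselSegment:
    """A straight cylindrical vessel segment (endpoints and radius in μm)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise InvalidParameterError("degenerate segment: p0 == p1")
        if self.radius <= 0:
            raise InvalidParameterError("segment radius must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))


@dataclass
class SyntheticTissue:
    """A box of vessel segments and cell spheres with exact ground truth.

    ``seg_p0``/``seg_p1`` are (n, 3) endpoint arrays (μm), ``seg_r`` the radii;
    ``cells`` is an (m, 4) array of sphere centers and radii.  Densities are in
    the reporting units (mm⁻², mm⁻¹, fraction).
    """

    box: tuple[float, float, float]
    seg_p0: np.ndarray
    seg_p1: np.ndarray
    seg_r: np.ndarray
    cells: np.ndarray
    true_Lv: float
    true_Sv: float
    true_Vv: float
    anisotropy: float
    seed: int

    @property
    def segments(self) -> list[VesselSegment]:
        return [
            VesselSegment(tuple(a), tuple(b), float(r))
            for a, b, r in zip(self.seg_p0, self.seg_p1, self.seg_r)
        ]

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.box))


def _random_directions(rng: np.random.Generator, n: int, anisotropy: float) -> np.ndarray:
    """Unit directions: isotropic for anisotropy=0, else pulled toward the z axis.

    Concentration is achieved by adding ``anisotropy``·sign(u_z)·e_z to an
    isotropic direction and renormalizing; the distribution stays azimuthally
    symmetric about the vertical axis, the symmetry the vertical design
    assumes.
    """
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if anisotropy != 0.0:
        u[:, 2] += anisotropy * np.sign(u[:, 2])
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u


def _clip_to_box(
    p0: np.ndarray, p1: np.ndarray, box: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clip segments to the box; returns clipped endpoints and a keep mask."""
    d = p1 - p0
    t_lo = np.zeros(len(p0))
    t_hi = np.ones(len(p0))
    for ax in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = (0.0 - p0[:, ax]) / d[:, ax]
            t1 = (box[ax] - p0[:, ax]) / d[:, ax]
        lo = np.minimum(t0, t1)
        hi = np.maximum(t0, t1)
        parallel = np.abs(d[:, ax]) < 1e-12
        inside = (p0[:, ax] >= 0) & (p0[:, ax] <= box[ax])
        lo = np.where(parallel, np.where(inside, -np.inf, np.inf), lo)
        hi = np.where(parallel, np.where(inside, np.inf, -np.inf), hi)
        t_lo = np.maximum(t_lo, lo)
        t_hi = np.minimum(t_hi, hi)
    keep = t_hi > t_lo + 1e-12
    a = p0 + t_lo[:, None] * d
    b = p0 + t_hi[:, None] * d
    return a[keep], b[keep], keep


def generate_network(
    target_Lv: float,
    diameter_mean: float,
    diameter_cv: float = 0.0,
    anisotropy: float = 0.0,
    box: Sequence[float] = (400.0, 400.0, 300.0),
    segment_length: float = 80.0,
    seed: int = 0,
) -> SyntheticTissue:
    """Place random cylinders until the clipped length density reaches ``target_Lv``.

    Segment midpoints are uniform in the box dilated by half a segment length
    (a stationary Boolean segment process restricted to the box, so density is
    uniform inside); segments are clipped to the box and clipped lengths enter
    the exact ``true_Lv``.  ``target_Lv`` in mm⁻², diameters in μm.
    """
    if target_Lv <= 0 or diameter_mean <= 0:
        raise InvalidParameterError("target_Lv and diameter_mean must be > 0")
    box = tuple(float(b) for b in box)
    V = float(np.prod(box))
    if V <= 0:
        raise InvalidParameterError("box volume must be > 0")
    target_len = target_Lv * 1e-6 * V  # μm of centerline
    mean_r = diameter_mean / 2.0
    rng = np.random.default_rng(seed)
    p0s, p1s, rads = [], [], []
    total = 0.0
    batch = max(int(target_len / segment_length * 0.2), 64)
    n_draws = 0
    while total < target_len:
        n_draws += batch
        if n_draws > 100 * max(target_len / segment_length, 1.0) + 1e6:
            raise GenerationError("could not reach target length density")
        half = segment_length / 2.0
        mid = rng.uniform(
            [-half, -half, -half], [box[0] + half, box[1] + half, box[2] + half], size=(batch, 3)
        )
        u = _random_directions(rng, batch, anisotropy)
        a, b, keep = _clip_to_box(mid - half * u, mid + half * u, box)
        if diameter_cv > 0:
            sd = diameter_cv * mean_r
            lo = (0.05 * mean_r - mean_r) / sd
            r = stats.truncnorm.rvs(lo, np.inf, loc=mean_r, scale=sd, size=batch, random_state=rng)
        else:
            r = np.full(batch, mean_r)
        r = r[keep]
        lens = np.linalg.norm(b - a, axis=1)
        for ai, bi, ri, li in zip(a, b, r, lens):
            if total >= target_len:
                break
            p0s.append(ai)
            p1s.append(bi)
            rads.append(ri)
            total += li
    seg_p0 = np.array(p0s)
    seg_p1 = np.array(p1s)
    seg_r = np.array(rads)
    lens = np.linalg.norm(seg_p1 - seg_p0, axis=1)
    vessel_vv = float(np.sum(math.pi * seg_r**2 * lens) / V)
    if vessel_vv > _MAX_VESSEL_VOLUME_FRACTION:
        raise GenerationError(
            f"vessel volume fraction {vessel_vv:.3f} too dense for the <1% surface-overlap budget"
        )
    true_Lv = float(np.sum(lens) / V * 1e6)
    true_Sv = float(np.sum(2.0 * math.pi * seg_r * lens) / V * 1e3)
    return SyntheticTissue(
        box=box,
        seg_p0=seg_p0,
        seg_p1=seg_p1,
        seg_r=seg_r,
        cells=np.empty((0, 4)),
        true_Lv=true_Lv,
        true_Sv=true_Sv,
        true_Vv=0.0,
        anisotropy=float(anisotropy),
        seed=int(seed),
    )


def generate_cell_field(
    tissue: SyntheticTissue,
    target_Vv: float,
    cell_radius: float = 4.0,
    seed: int = 0,
) -> SyntheticTissue:
    """Add non-overlapping spheres until the volume fraction matches ``target_Vv``.

    Spheres are placed by random sequential addition, fully inside the box, so
    ``true_Vv`` is exactly n·(4/3 π R³)/V; the placed count is the nearest
    integer to the target (within 0.005 for any realistic sphere size).
    """
    if not 0.0 < target_Vv < 0.5:
        raise InvalidParameterError("target_Vv must lie in (0, 0.5)")
    if cell_radius <= 0:
        raise InvalidParameterError("cell_radius must be > 0")
    box = tissue.box
    if min(box) < 2 * cell_radius:
        raise GenerationError("box too small for the requested cell radius")
    V = tissue.volume_um3
    v_sphere = 4.0 / 3.0 * math.pi * cell_radius**3
    n_target = int(round(target_Vv * V / v_sphere))
    if n_target == 0:
        raise GenerationError("target_Vv too small to place a single cell")
    true_Vv = n_target * v_sphere / V
    if abs(true_Vv - target_Vv) > 0.005:
        raise GenerationError("cell radius too coarse to hit target_Vv within 0.005")
    rng = np.random.default_rng(seed)
    cell = 2.0 * cell_radius
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}
    lo = np.full(3, cell_radius)
    hi = np.array(box) - cell_radius
    placed = np.empty((n_target, 3))
    n_placed = 0
    attempts = 0
    max_attempts = 500 * n_target
    min_d2 = (2.0 * cell_radius) ** 2
    while n_placed < n_target:
        cand = rng.uniform(lo, hi, size=(max(n_target - n_placed, 64), 3))
        for c in cand:
            if n_placed >= n_target:
                break
            attempts += 1
            if attempts > max_attempts:
                raise GenerationError("sphere packing failed: too many rejected placements")
            key = tuple((c // cell).astype(int))
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        for other in grid.get((key[0] + di, key[1] + dj, key[2] + dk), ()):
                            d = c - other
                            if d @ d < min_d2:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault(key, []).append(c)
                placed[n_placed] = c
                n_placed += 1
    cells = np.column_stack([placed, np.full(n_target, cell_radius)])
    return replace(tissue, cells=cells, true_Vv=float(true_Vv))


# ---------------------------------------------------------------------------
# sectioning


def _raster_segments(
    mask: np.ndarray,
    tissue: SyntheticTissue,
    x0: float,
    half_thickness: float,
    pixel_size: float,
) -> None:
    """Rasterize exact finite-cylinder silhouettes within a slab onto ``mask``.

    A pixel is foreground if its center (y, z) is covered for some x in
    [x0−halfT, x0+halfT] by some cylinder, i.e. the axial projection lies in
    [0, length] and the radial distance is within the radius.  halfT = 0 gives
    the thin mid-plane intersection (elliptical profiles).
    """
    H, W = mask.shape
    ps = pixel_size
    d = tissue.seg_p1 - tissue.seg_p0
    lens = np.linalg.norm(d, axis=1)
    slab_lo, slab_hi = x0 - half_thickness, x0 + half_thickness
    for p0, dvec, ell, rho in zip(tissue.seg_p0, d, lens, tissue.seg_r):
        a = dvec / ell
        # x-range of the centerline portion relevant to this slab (± radius)
        x_min = min(p0[0], p0[0] + dvec[0]) - rho
        x_max = max(p0[0], p0[0] + dvec[0]) + rho
        if x_max < slab_lo or x_min > slab_hi:
            continue
        # clip centerline to the radius-extended slab for the (y, z) window
        if abs(dvec[0]) > 1e-12:
            t0 = (slab_lo - rho - p0[0]) / dvec[0]
            t1 = (slab_hi + rho - p0[0]) / dvec[0]
            tl, th = max(min(t0, t1), 0.0), min(max(t0, t1), 1.0)
        else:
            tl, th = 0.0, 1.0
        qa = p0 + tl * dvec
        qb = p0 + th * dvec
        y_lo, y_hi = min(qa[1], qb[1]) - rho, max(qa[1], qb[1]) + rho
        z_lo, z_hi = min(qa[2], qb[2]) - rho, max(qa[2], qb[2]) + rho
        c_lo = max(int(math.floor(y_lo / ps - 0.5)), 0)
        c_hi = min(int(math.ceil(y_hi / ps - 0.5)), W - 1)
        r_lo = max(int(math.floor(z_lo / ps - 0.5)), 0)
        r_hi = min(int(math.ceil(z_hi / ps - 0.5)), H - 1)
        if c_lo > c_hi or r_lo > r_hi:
            continue
        y = (np.arange(c_lo, c_hi + 1) + 0.5) * ps
        z = (np.arange(r_lo, r_hi + 1) + 0.5) * ps
        dy = (y - p0[1])[None, :]
        dz = (z - p0[2])[:, None]
        beta = a[0]
        alpha = -p0[0] * beta + dy * a[1] + dz * a[2]  # proj = beta*x + alpha
        # slab interval
        lo_x = np.full(alpha.shape, slab_lo)
        hi_x = np.full(alpha.shape, slab_hi)
        # axial-projection interval: 0 <= beta*x + alpha <= ell
        if abs(beta) > 1e-9:
            b1 = (0.0 - alpha) / beta
            b2 = (ell - alpha) / beta
            lo_x = np.maximum(lo_x, np.minimum(b1, b2))
            hi_x = np.minimum(hi_x, np.maximum(b1, b2))
        else:
            bad = (alpha < 0.0) | (alpha > ell)
            hi_x = np.where(bad, -np.inf, hi_x)
        # radial interval: A x^2 + B x + C <= rho^2
        A = 1.0 - beta * beta
        B = -2.0 * p0[0] - 2.0 * alpha * beta
        C = p0[0] ** 2 + dy**2 + dz**2 - alpha**2
        if A > 1e-9:
            disc = B * B - 4.0 * A * (C - rho * rho)
            feas = disc >= 0.0
            sq = np.sqrt(np.maximum(disc, 0.0))
            lo_x = np.maximum(lo_x, (-B - sq) / (2.0 * A))
            hi_x = np.where(feas, np.minimum(hi_x, (-B + sq) / (2.0 * A)), -np.inf)
        else:
            # axis ~ parallel to x: radial term effectively constant in x
            val = A * x0 * x0 + B * x0 + C
            hi_x = np.where(val <= rho * rho, hi_x, -np.inf)
        hit = lo_x <= hi_x
        if hit.any():
            mask[r_lo : r_hi + 1, c_lo : c_hi + 1] |= hit


def _raster_cells(
    mask: np.ndarray, tissue: SyntheticTissue, x0: float, pixel_size: float
) -> None:
    """Thin mid-plane discs of the cell spheres cut by the plane x = x0."""
    H, W = mask.shape
    ps = pixel_size
    for cx, cy, cz, R in tissue.cells:
        dx = cx - x0
        if abs(dx) >= R:
            continue
        r_eff = math.sqrt(R * R - dx * dx)
        c_lo = max(int(math.floor((cy - r_eff) / ps - 0.5)), 0)
        c_hi = min(int(math.ceil((cy + r_eff) / ps - 0.5)), W - 1)
        r_lo = max(int(math.floor((cz - r_eff) / ps - 0.5)), 0)
        r_hi = min(int(math.ceil((cz + r_eff) / ps - 0.5)), H - 1)
        if c_lo > c_hi or r_lo > r_hi:
            continue
        y = (np.arange(c_lo, c_hi + 1) + 0.5) * ps - cy
        z = (np.arange(r_lo, r_hi + 1) + 0.5) * ps - cz
        hit = z[:, None] ** 2 + y[None, :] ** 2 <= r_eff * r_eff
        mask[r_lo : r_hi + 1, c_lo : c_hi + 1] |= hit


def _raster_traces(
    mask: np.ndarray,
    tissue: SyntheticTissue,
    x0: float,
    half_thickness: float,
    pixel_size: float,
    half_width: float,
) -> None:
    """Rasterize the projected *centerlines* of the slab-clipped segments.

    This is the linear-feature image the projected length design counts:
    each centerline portion with |x − x0| <= halfT is projected onto (y, z)
    and drawn as a thin strip of the given half-width (a 2D capsule).
    """
    H, W = mask.shape
    ps = pixel_size
    for p0, p1 in zip(tissue.seg_p0, tissue.seg_p1):
        d = p1 - p0
        if abs(d[0]) > 1e-12:
            t0 = (x0 - half_thickness - p0[0]) / d[0]
            t1 = (x0 + half_thickness - p0[0]) / d[0]
            tl, th = max(min(t0, t1), 0.0), min(max(t0, t1), 1.0)
            if th <= tl:
                continue
        else:
            if abs(p0[0] - x0) > half_thickness:
                continue
            tl, th = 0.0, 1.0
        qa = p0 + tl * d
        qb = p0 + th * d
        ay, az = qa[1], qa[2]
        by, bz = qb[1], qb[2]
        y_lo, y_hi = min(ay, by) - half_width, max(ay, by) + half_width
        z_lo, z_hi = min(az, bz) - half_width, max(az, bz) + half_width
        c_lo = max(int(math.floor(y_lo / ps - 0.5)), 0)
        c_hi = min(int(math.ceil(y_hi / ps - 0.5)), W - 1)
        r_lo = max(int(math.floor(z_lo / ps - 0.5)), 0)
        r_hi = min(int(math.ceil(z_hi / ps - 0.5)), H - 1)
        if c_lo > c_hi or r_lo > r_hi:
            continue
        y = (np.arange(c_lo, c_hi + 1) + 0.5) * ps
        z = (np.arange(r_lo, r_hi + 1) + 0.5) * ps
        dy = (y - ay)[None, :]
        dz = (z - az)[:, None]
        ey, ez = by - ay, bz - az
        ee = ey * ey + ez * ez
        if ee < 1e-24:
            d2 = dy**2 + dz**2
        else:
            t = np.clip((dy * ey + dz * ez) / ee, 0.0, 1.0)
            d2 = (dy - t * ey) ** 2 + (dz - t * ez) ** 2
        hit = d2 <= half_width * half_width
        if hit.any():
            mask[r_lo : r_hi + 1, c_lo : c_hi + 1] |= hit


def cut_vertical_section(
    tissue: SyntheticTissue,
    plane_offset: float,
    thickness: float = 5.0,
    pixel_size: float = 0.5,
    mode: str = "projected",
    trace_half_width: float | None = None,
) -> SectionImage:
    """Cut one vertical section (plane x = offset, containing the z axis).

    ``mode='thin'`` rasterizes the mid-plane intersection of each cylinder;
    ``mode='projected'`` rasterizes the exact silhouette of each cylinder
    within the slab of the given thickness; ``mode='trace'`` rasterizes the
    projected centerlines as thin strips (default half-width one pixel) — the
    zero-width linear-feature image the length estimator's theory assumes,
    free of the overprojection the finite tube width adds to silhouettes.
    Image rows run along z (the vertical, surface-to-cartilage axis), columns
    along y (across the wound); the tissue mask is the full frame and the
    cell mask is always the thin mid-plane cut.
    """
    if mode not in ("thin", "projected", "trace"):
        raise InvalidParameterError(f"unknown section mode {mode!r}")
    if thickness <= 0 or pixel_size <= 0:
        raise InvalidParameterError("thickness and pixel_size must be > 0")
    if not 0.0 <= plane_offset <= tissue.box[0]:
        raise SectioningError(
            f"plane offset {plane_offset} outside box x-extent [0, {tissue.box[0]}]"
        )
    W = int(round(tissue.box[1] / pixel_size))
    H = int(round(tissue.box[2] / pixel_size))
    vessel = np.zeros((H, W), dtype=bool)
    if mode == "trace":
        if trace_half_width is None:
            trace_half_width = TRACE_HALF_WIDTH_UM
        _raster_traces(vessel, tissue, plane_offset, thickness / 2.0, pixel_size, trace_half_width)
    else:
        halfT = 0.0 if mode == "thin" else thickness / 2.0
        _raster_segments(vessel, tissue, plane_offset, halfT, pixel_size)
    cell = np.zeros((H, W), dtype=bool)
    _raster_cells(cell, tissue, plane_offset, pixel_size)
    return SectionImage(
        vessel_mask=vessel,
        tissue_mask=np.ones((H, W), dtype=bool),
        cell_mask=cell,
        pixel_size=pixel_size,
        vertical_axis="rows",
        section_thickness=thickness,
        section_position=plane_offset,
    )


def trace_segments_2d(
    tissue: SyntheticTissue, plane_offset: float, thickness: float = 5.0
) -> np.ndarray:
    """Projected centerline segments of the slab as an (n, 2, 2) array.

    Each vessel centerline is clipped to |x − offset| <= thickness/2 and
    projected onto the section plane; coordinates are image (y, z) μm.  This
    is the exact linear-feature overlay the projected length design counts.
    """
    out = []
    halfT = thickness / 2.0
    x0 = plane_offset
    for p0, p1 in zip(tissue.seg_p0, tissue.seg_p1):
        d = p1 - p0
        if abs(d[0]) > 1e-12:
            t0 = (x0 - halfT - p0[0]) / d[0]
            t1 = (x0 + halfT - p0[0]) / d[0]
            tl, th = max(min(t0, t1), 0.0), min(max(t0, t1), 1.0)
            if th <= tl:
                continue
        else:
            if abs(p0[0] - x0) > halfT:
                continue
            tl, th = 0.0, 1.0
        qa = p0 + tl * d
        qb = p0 + th * d
        out.append([[qa[1], qa[2]], [qb[1], qb[2]]])
    if not out:
        return np.empty((0, 2, 2))
    return np.array(out)


def cut_section_pair(
    tissue: SyntheticTissue,
    plane_offset: float,
    thickness: float = 5.0,
    pixel_size: float = 0.5,
) -> SectionImage:
    """One section carrying all the geometries the estimators assume.

    ``vessel_mask`` holds the thin mid-plane profiles (surface and
    volume-fraction counting); ``vessel_mask_projected`` the rasterized
    through-thickness centerline traces (visual/export); ``trace_segments``
    the exact projected-centerline overlay, which length-design counting
    uses when available (the raster version of a ~5-μm trace is only a few
    pixels long, so mask-based counting of it carries O(pixel/length) bias).
    """
    thin = cut_vertical_section(tissue, plane_offset, thickness, pixel_size, mode="thin")
    H, W = thin.vessel_mask.shape
    proj = np.zeros((H, W), dtype=bool)
    _raster_traces(
        proj, tissue, plane_offset, thickness / 2.0, pixel_size, TRACE_HALF_WIDTH_UM
    )
    thin.vessel_mask_projected = proj
    thin.trace_segments = trace_segments_2d(tissue, plane_offset, thickness)
    return thin


# ---------------------------------------------------------------------------
# whole synthetic studies


@dataclass
class RenderConfig:
    """Geometry used when a synthetic study is rendered into section images."""

    box: tuple[float, float, float] = (300.0, 300.0, 180.0)
    n_sections: int = 4
    pixel_size: float = 0.25
    section_thickness: float = 5.0
    segment_length: float = 100.0
    anisotropy: float = 0.0
    cell_radius: float = 4.0
    margin: float = 12.0

    def section_offsets(self) -> np.ndarray:
        return np.linspace(self.margin, self.box[0] - self.margin, self.n_sections)


@dataclass
class SyntheticWound:
    """One simulated wound: drawn true parameters plus optional rendered tissue."""

    wound_id: str
    group: str
    true: dict
    A0: float
    A7: float
    thicknesses: tuple
    tissue: SyntheticTissue | None = None
    sections: list | None = None
    measurement: object | None = None  # parameter-level WoundMeasurement


@dataclass
class SyntheticStudy:
    """A full multi-arm synthetic study plus its ground-truth ledger."""

    wounds: list[SyntheticWound]
    group_params: dict
    n_per_group: int
    seed: int
    rendered: bool

    def truth_ledger(self) -> dict:
        """JSON-serializable record of every drawn true parameter."""
        return {
            "seed": self.seed,
            "n_per_group": self.n_per_group,
            "rendered": self.rendered,
            "wounds": [
                {"wound_id": w.wound_id, "group": w.group, **{k: float(v) for k, v in w.true.items()}}
                for w in self.wounds
            ],
        }


def reference_group_params() -> dict:
    """Per-arm (mean, SD) simulation parameters from the published summaries."""
    out = {}
    for g in GROUPS:
        ref = REFERENCE_GROUPS[g]
        out[g] = {
            "closure": ref["closure"],
            "Lv": ref["Lv"],
            "Sv": ref["Sv"],
            "Vv": group_vv(g),
            "volume": ref["volume"],
        }
    return out


def _draw_truncated(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd < 0:
        raise GenerationError("negative SD in group parameters")
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


#: deterministic relative offsets giving six thickness readings with exact mean
_THICKNESS_PATTERN = np.array([-0.05, -0.03, -0.01, 0.01, 0.03, 0.05])


def generate_study(
    group_params: dict | None = None,
    n_per_group: int = 8,
    seed: int = 0,
    render: bool = False,
    render_config: RenderConfig | None = None,
) -> SyntheticStudy:
    """Draw per-wound true parameters per arm; optionally render tissues/sections.

    Per-wound closure, Lv, Sv, Vv and wound volume are drawn from truncated
    normal distributions (truncated at zero, closure also at 100) with the
    given group means/SDs; the default parameters reproduce the published
    four-arm, n = 8 design.  With ``render=True`` each wound additionally gets
    a vessel network (target_Lv = its drawn Lv, cylinder diameter set by the
    drawn Sv/(π·Lv) identity), a cell field at its drawn Vv and
    ``n_sections`` paired thin/projected section images.  Without rendering,
    wound measurements are the drawn parameters themselves with the derived
    quantities (Rdiff, diameter, totals) computed by the estimator formulas.
    """
    from .estimators import WoundMeasurement  # local import avoids cycle at module load

    if group_params is None:
        group_params = reference_group_params()
    if n_per_group < 2:
        raise InvalidParameterError("n_per_group must be >= 2")
    if render_config is None:
        render_config = RenderConfig()
    rng = np.random.default_rng(seed)
    seed_seq = np.random.SeedSequence(seed)
    wounds: list[SyntheticWound] = []
    for group in group_params:
        gp = group_params[group]
        closure = _draw_truncated(rng, *gp["closure"], 0.0, 100.0, n_per_group)
        Lv = _draw_truncated(rng, *gp["Lv"], 1e-6, np.inf, n_per_group)
        Sv = _draw_truncated(rng, *gp["Sv"], 1e-6, np.inf, n_per_group)
        Vv = _draw_truncated(rng, *gp["Vv"], 1e-6, 0.49, n_per_group)
        volume = _draw_truncated(rng, *gp["volume"], 1e-6, np.inf, n_per_group)
        for i in range(n_per_group):
            wid = f"{group}_{i:02d}"
            A0 = PUNCH_AREA_MM2
            A7 = A0 * (1.0 - closure[i] / 100.0)
            t_mean = volume[i] / A7
            thicknesses = tuple(t_mean * (1.0 + _THICKNESS_PATTERN))
            true = {
                "closure": closure[i],
                "Lv": Lv[i],
                "Sv": Sv[i],
                "Vv": Vv[i],
                "volume": volume[i],
                "diameter_um": Sv[i] / (math.pi * Lv[i]) * 1e3,
            }
            wound = SyntheticWound(
                wound_id=wid,
                group=group,
                true=true,
                A0=A0,
                A7=A7,
                thicknesses=thicknesses,
            )
            if render:
                child = seed_seq.spawn(1)[0]
                crng = np.random.default_rng(child)
                tissue = generate_network(
                    target_Lv=float(Lv[i]),
                    diameter_mean=float(true["diameter_um"]),
                    anisotropy=render_config.anisotropy,
                    box=render_config.box,
                    segment_length=render_config.segment_length,
                    seed=int(crng.integers(2**31)),
                )
                tissue = generate_cell_field(
                    tissue,
                    target_Vv=float(Vv[i]),
                    cell_radius=render_config.cell_radius,
                    seed=int(crng.integers(2**31)),
                )
                wound.tissue = tissue
                wound.sections = [
                    cut_section_pair(
                        tissue,
                        float(off),
                        thickness=render_config.section_thickness,
                        pixel_size=render_config.pixel_size,
                    )
                    for off in render_config.section_offsets()
                ]
                true["tissue_Lv"] = tissue.true_Lv
                true["tissue_Sv"] = tissue.true_Sv
                true["tissue_Vv"] = tissue.true_Vv
            else:
                sv, lv, vv = float(Sv[i]), float(Lv[i]), float(Vv[i])
                wound.measurement = WoundMeasurement(
                    wound_id=wid,
                    group=group,
                    A0=A0,
                    A7=A7,
                    thicknesses=thicknesses,
                    volume=float(volume[i]),
                    closure=float(closure[i]),
                    Sv=sv,
                    Lv=lv,
                    Rdiff=radial_diffusion(lv),
                    diameter=vessel_diameter(sv, lv),
                    Vv=vv,
                    surface_area_total=totals(sv, float(volume[i])),
                    length_total=totals(lv, float(volume[i])),
                    inflam_volume_total=totals(vv, float(volume[i])),
                )
            wounds.append(wound)
    return SyntheticStudy(
        wounds=wounds,
        group_params=group_params,
        n_per_group=n_per_group,
        seed=int(seed),
        rendered=bool(render),
    )
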