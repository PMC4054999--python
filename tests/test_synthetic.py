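import json
import math

import numpy as np
import pytest

import woundstereo as ws
from woundstereo.errors import GenerationError, InvalidParameterError, SectioningError
from woundstereo.synthetic import SyntheticTissue, cut_vertical_section, trace_segments_2d


def manual_tissue(segments, box=(60.0, 60.0, 60.0), cells=None):
    p0 = np.array([s[0] for s in segments], float)
    p1 = np.array([s[1] for s in segments], float)
    r = np.array([s[2] for s in segments], float)
    V = float(np.prod(box))
    lens = np.linalg.norm(p1 - p0, axis=1) if len(segments) else np.zeros(0)
    return SyntheticTissue(
        box=box,
        seg_p0=p0.reshape(-1, 3),
        seg_p1=p1.reshape(-1, 3),
        seg_r=r,
        cells=cells if cells is not None else np.empty((0, 4)),
        true_Lv=float(lens.sum() / V * 1e6),
        true_Sv=float((2 * math.pi * r * lens).sum() / V * 1e3) if len(segments) else 0.0,
        true_Vv=0.0,
        anisotropy=0.0,
        seed=0,
    )


class TestGenerateNetwork:
    def test_stopping_rule_and_bookkeeping(self):
        tis = ws.generate_network(5000.0, 2.0, box=(500.0, 500.0, 500.0), seed=1)
        assert tis.true_Lv >= 5000.0
        # overshoot bounded by one segment's contribution
        one_seg = 80.0 / (500.0**3) * 1e6
        assert tis.true_Lv <= 5000.0 + one_seg
        lens = np.linalg.norm(tis.seg_p1 - tis.seg_p0, axis=1)
        V = 500.0**3
        assert tis.true_Lv == pytest.approx(lens.sum() / V * 1e6)
        assert tis.true_Sv == pytest.approx((2 * math.pi * tis.seg_r * lens).sum() / V * 1e3)

    def test_same_seed_identical(self):
        a = ws.generate_network(3000.0, 1.5, box=(200.0, 200.0, 200.0), seed=7)
        b = ws.generate_network(3000.0, 1.5, box=(200.0, 200.0, 200.0), seed=7)
        assert np.array_equal(a.seg_p0, b.seg_p0)
        assert np.array_equal(a.seg_r, b.seg_r)

    def test_cylinder_identity_exact_for_constant_diameter(self):
        tis = ws.generate_network(4000.0, 1.8, diameter_cv=0.0, box=(300.0,) * 3, seed=2)
        assert tis.true_Sv / tis.true_Lv * 1e3 == pytest.approx(math.pi * 1.8, rel=1e-12)

    def test_unreachable_density_rejected(self):
        with pytest.raises(GenerationError):
            ws.generate_network(60000.0, 2.0, box=(200.0,) * 3, seed=0)

    def test_segments_clipped_inside_box(self):
        tis = ws.generate_network(5000.0, 2.0, box=(150.0, 150.0, 150.0), seed=5)
        for arr in (tis.seg_p0, tis.seg_p1):
            assert arr.min() >= -1e-9
            assert arr.max() <= 150.0 + 1e-9


class TestCellField:
    def test_stopping_rule(self):
        tis = ws.generate_network(2000.0, 2.0, box=(200.0,) * 3, seed=1)
        tis = ws.generate_cell_field(tis, 0.12, cell_radius=5.0, seed=2)
        assert abs(tis.true_Vv - 0.12) <= 0.005
        v = 4 / 3 * math.pi * 125.0
        assert tis.true_Vv == pytest.approx(len(tis.cells) * v / 200.0**3)

    def test_non_overlapping_spheres(self):
        tis = ws.generate_network(2000.0, 2.0, box=(150.0,) * 3, seed=1)
        tis = ws.generate_cell_field(tis, 0.08, cell_radius=6.0, seed=3)
        c = tis.cells[:, :3]
        d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= (12.0 - 1e-9) ** 2

    def test_boundary_target_rejected(self):
        tis = ws.generate_network(2000.0, 2.0, box=(150.0,) * 3, seed=1)
        with pytest.raises(InvalidParameterError):
            ws.generate_cell_field(tis, 0.0)
        with pytest.raises(InvalidParameterError):
            ws.generate_cell_field(tis, 0.5)

    def test_same_seed_identical(self):
        tis = ws.generate_network(2000.0, 2.0, box=(150.0,) * 3, seed=1)
        a = ws.generate_cell_field(tis, 0.1, cell_radius=5.0, seed=9)
        b = ws.generate_cell_field(tis, 0.1, cell_radius=5.0, seed=9)
        assert np.array_equal(a.cells, b.cells)


class TestSectioning:
    def test_empty_tissue_gives_empty_mask(self):
        tis = manual_tissue([])
        sec = cut_vertical_section(tis, 30.0, 5.0, 0.5, mode="thin")
        assert not sec.vessel_mask.any()
        assert sec.tissue_mask.all()

    def test_perpendicular_tube_yields_disc(self):
        """A tube along x cut by the thin plane leaves a disc of its radius."""
        rho = 6.0
        tis = manual_tissue([((0.0, 30.0, 30.0), (60.0, 30.0, 30.0), rho)])
        ps = 0.5
        sec = cut_vertical_section(tis, 30.0, 5.0, ps, mode="thin")
        area = sec.vessel_mask.sum() * ps**2
        assert area == pytest.approx(math.pi * rho**2, rel=0.03)
        rows, cols = np.nonzero(sec.vessel_mask)
        rad = np.hypot((rows + 0.5) * ps - 30.0, (cols + 0.5) * ps - 30.0)
        assert rad.max() <= rho + ps

    def test_oblique_tube_profile_is_elongated(self):
        rho = 4.0
        tis = manual_tissue([((10.0, 30.0, 10.0), (50.0, 30.0, 50.0), rho)])
        sec = cut_vertical_section(tis, 30.0, 5.0, 0.25, mode="thin")
        rows, cols = np.nonzero(sec.vessel_mask)
        z_extent = (rows.max() - rows.min()) * 0.25
        y_extent = (cols.max() - cols.min()) * 0.25
        # 45° inclination: ellipse major axis = 2ρ√2 along z, minor 2ρ along y
        assert z_extent == pytest.approx(2 * rho * math.sqrt(2), abs=0.6)
        assert y_extent == pytest.approx(2 * rho, abs=0.6)

    def test_projected_mode_matches_voxel_oracle(self):
        """Silhouette foreground area equals a fine voxel rasterization within 2%."""
        rng = np.random.default_rng(12)
        segs = []
        for _ in range(8):
            a = rng.uniform(5, 55, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            segs.append((tuple(a), tuple(np.clip(a + 35 * d, 0, 60)), 2.5))
        tis = manual_tissue(segs)
        ps = 0.5
        x0, T = 30.0, 5.0
        sec = cut_vertical_section(tis, x0, T, ps, mode="projected")
        fine = ps / 4
        n = int(60 / fine)
        ys = (np.arange(n) + 0.5) * fine
        zs = (np.arange(n) + 0.5) * fine
        xs = np.arange(x0 - T / 2, x0 + T / 2 + fine / 2, fine / 2)
        hit = np.zeros((n, n), bool)
        for p0, p1, rho in segs:
            p0, p1 = np.array(p0), np.array(p1)
            d = p1 - p0
            ell = np.linalg.norm(d)
            a = d / ell
            for x in xs:
                P = np.stack(
                    np.broadcast_arrays(x, ys[None, :], zs[:, None]), axis=-1
                ).reshape(-1, 3)
                dp = P - p0
                proj = dp @ a
                rad2 = (dp**2).sum(1) - proj**2
                inside = (proj >= 0) & (proj <= ell) & (rad2 <= rho**2)
                hit |= inside.reshape(n, n)
        area_impl = sec.vessel_mask.sum() * ps**2
        area_oracle = hit.sum() * fine**2
        assert area_impl == pytest.approx(area_oracle, rel=0.02)

    def test_sectioning_conservation(self):
        """Summed thin-profile area × spacing approximates total tube volume."""
        tis = ws.generate_network(8000.0, 2.0, box=(80.0, 80.0, 80.0), segment_length=40.0, seed=3)
        ps = 0.25
        dx = 1.0
        offsets = np.arange(dx / 2, 80.0, dx)
        total = sum(
            cut_vertical_section(tis, float(x), 5.0, ps, mode="thin").vessel_mask.sum() * ps**2
            for x in offsets
        )
        lens = np.linalg.norm(tis.seg_p1 - tis.seg_p0, axis=1)
        vol = float((math.pi * tis.seg_r**2 * lens).sum())
        assert total * dx == pytest.approx(vol, rel=0.05)

    def test_plane_outside_box_rejected(self, small_tissue):
        with pytest.raises(SectioningError):
            cut_vertical_section(small_tissue, 1000.0)

    def test_trace_segments_clip_to_slab(self):
        tis = manual_tissue([((0.0, 10.0, 10.0), (60.0, 40.0, 40.0), 1.0)])
        tr = trace_segments_2d(tis, 30.0, 5.0)
        assert tr.shape == (1, 2, 2)
        # centerline traverses x at unit rate; slab is 5 μm of x -> the
        # projected piece spans 2.5 μm of y and z around the midpoint (25, 25)
        (a, b) = tr[0]
        assert sorted([a[0], b[0]]) == pytest.approx([23.75, 26.25])
        assert sorted([a[1], b[1]]) == pytest.approx([23.75, 26.25])
        assert trace_segments_2d(tis, 30.0, 5.0).shape == tr.shape
        assert len(trace_segments_2d(manual_tissue([]), 30.0, 5.0)) == 0


class TestGenerateStudy:
    def test_zero_sd_gives_identical_wounds(self):
        params = {
            "a": {k: (v, 0.0) for k, v in dict(closure=30.0, Lv=5000.0, Sv=20.0, Vv=0.15, volume=14.0).items()},
            "b": {k: (v, 0.0) for k, v in dict(closure=40.0, Lv=6000.0, Sv=22.0, Vv=0.12, volume=15.0).items()},
        }
        study = ws.generate_study(params, n_per_group=4, seed=5)
        for g in ("a", "b"):
            vals = [w.true["Lv"] for w in study.wounds if w.group == g]
            assert len(set(vals)) == 1

    def test_truth_ledger_deterministic(self):
        a = ws.generate_study(n_per_group=3, seed=77)
        b = ws.generate_study(n_per_group=3, seed=77)
        assert json.dumps(a.truth_ledger()) == json.dumps(b.truth_ledger())

    def test_parameter_level_measurement_identities(self):
        study = ws.generate_study(n_per_group=3, seed=9)
        for w in study.wounds:
            m = w.measurement
            assert m.volume == pytest.approx(np.mean(w.thicknesses) * w.A7)
            assert m.closure == pytest.approx(ws.wound_closure(w.A0, w.A7))
            assert m.Rdiff == pytest.approx(ws.radial_diffusion(m.Lv))
            assert m.diameter == pytest.approx(ws.vessel_diameter(m.Sv, m.Lv))
            assert m.length_total == pytest.approx(m.Lv * m.volume)

    def test_group_means_track_reference_over_draws(self):
        """Sample means of drawn Lv stay within 2 SE of the configured means."""
        params = ws.reference_group_params()
        n = 16
        draws = {g: [] for g in params}
        for seed in range(8):
            study = ws.generate_study(params, n_per_group=n, seed=1000 + seed)
            for g in params:
                draws[g] += [w.true["Lv"] for w in study.wounds if w.group == g]
        for g, vals in draws.items():
            mean, sd = params[g]["Lv"]
            se = sd / math.sqrt(len(vals))
            # truncation at zero slightly raises the mean; 2 SE + 1% slack
            assert abs(np.mean(vals) - mean) < 2 * se + 0.01 * mean

    def test_invalid_sd_rejected(self):
        params = ws.reference_group_params()
        params["untreated"]["Lv"] = (4116.0, -1.0)
        with pytest.raises(GenerationError):
            ws.generate_study(params, n_per_group=2, seed=1)
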