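import numpy as np
import pytest

import woundstereo as ws
from woundstereo.counting import (
    count_boundary_intersections,
    count_point_hits,
    count_profile_intersections,
    count_trace_intersections,
    count_wound_fields,
)
from woundstereo.errors import SamplingError
from woundstereo.synthetic import cut_section_pair

from oracles import oracle_curve_counts, oracle_point_hits, random_blob_mask


def disc_mask(shape, center, radius, pixel_size):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = (xx + 0.5) * pixel_size
    py = (yy + 0.5) * pixel_size
    return (px - center[0]) ** 2 + (py - center[1]) ** 2 <= radius**2


class TestBoundaryIntersections:
    def test_empty_mask_counts_zero(self):
        sys_ = ws.build_test_system("surface", 320.0, (64.0, 64.0), 4.0)
        mask = np.zeros((200, 200), bool)
        assert count_boundary_intersections(mask, sys_, 0.5) == 0

    def test_line_through_circle_crosses_twice(self):
        ps = 0.5
        mask = disc_mask((400, 400), (100.0, 100.0), 50.0, ps)
        line = ws.build_line_system(180.0, (180.0, 180.0), 1)
        n = count_boundary_intersections(mask, line, ps, origin=(10.0, 10.0))
        assert n == 2

    def test_profile_containing_arc_counts_zero(self):
        ps = 0.5
        mask = disc_mask((400, 400), (100.0, 100.0), 90.0, ps)
        sys_ = ws.build_test_system("surface", 64.0, (40.0, 40.0), 4.0)
        assert count_boundary_intersections(mask, sys_, ps, origin=(80.0, 80.0)) == 0

    def test_parity_of_crossings_per_arc(self):
        """Crossings of a closed boundary are even unless the arc ends inside.

        For each arc the transition count is even exactly when both endpoints
        lie on the same side of the profile boundary (both in or both out).
        """
        from oracles import _bilinear_inside

        ps = 0.5
        mask = disc_mask((300, 300), (75.0, 75.0), 30.0, ps)
        smooth = ws.smooth_mask(mask)
        sys_ = ws.build_test_system("surface", 640.0, (130.0, 130.0), 4.0)
        origin = (10.0, 10.0)
        per_arc = count_boundary_intersections(mask, sys_, ps, origin=origin, per_arc=True)
        for arc, c in zip(sys_.arcs, per_arc):
            a = _bilinear_inside(smooth, *(arc.vertices[0] + origin), ps)
            b = _bilinear_inside(smooth, *(arc.vertices[-1] + origin), ps)
            assert c % 2 == (1 if a != b else 0)
        assert sum(per_arc) > 0

    def test_translation_invariance_whole_pixels(self):
        ps = 0.5
        mask = random_blob_mask(5, shape=(240, 240))
        sys_ = ws.build_test_system("surface", 160.0, (50.0, 50.0), 4.0)
        base = count_boundary_intersections(mask, sys_, ps, origin=(20.0, 20.0))
        shifted = np.roll(mask, (7, -9), axis=(0, 1))
        moved = count_boundary_intersections(
            shifted, sys_, ps, origin=(20.0 - 9 * ps, 20.0 + 7 * ps)
        )
        assert base == moved

    def test_out_of_extent_raises(self):
        sys_ = ws.build_test_system("surface", 320.0, (64.0, 64.0), 4.0)
        with pytest.raises(SamplingError):
            count_boundary_intersections(np.zeros((40, 40), bool), sys_, 0.5)

    def test_resolution_stability(self):
        """Halving the pixel size changes smooth-profile counts by <= 2%."""
        tis = ws.generate_network(600.0, 10.0, box=(200.0, 200.0, 130.0), segment_length=60.0, seed=9)
        sys_ = ws.build_test_system("surface", 1280.0, (120.0, 120.0), 4.0)
        counts = {}
        for ps in (0.5, 0.25):
            total = 0
            for off in np.linspace(20.0, 180.0, 10):
                sec = ws.cut_vertical_section(tis, float(off), 5.0, ps, mode="thin")
                total += count_boundary_intersections(sec.vessel_mask, sys_, ps, origin=(40.0, 5.0))
            counts[ps] = total
        assert counts[0.5] > 50
        assert abs(counts[0.25] / counts[0.5] - 1) <= 0.02


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_crossings_match_dense_sampling_oracle(self, seed):
        ps = 0.5
        mask = random_blob_mask(seed)
        sys_ = ws.build_test_system("surface", 96.0, (40.0, 40.0), 3.0)
        origin = (15.0, 15.0)
        assert count_boundary_intersections(mask, sys_, ps, origin) == oracle_curve_counts(
            mask, sys_, ps, origin, runs=False
        )
        assert count_profile_intersections(mask, sys_, ps, origin) == oracle_curve_counts(
            mask, sys_, ps, origin, runs=True
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_point_hits_match_per_point_oracle(self, seed):
        ps = 0.5
        cell = random_blob_mask(seed + 100)
        tissue = cell | random_blob_mask(seed + 200)
        grid = ws.build_point_grid(192, (70.0, 70.0)) + 2.0
        assert count_point_hits(cell, tissue, grid, ps) == oracle_point_hits(cell, tissue, grid, ps)

    def test_point_hits_trivial_cases(self):
        grid = ws.build_point_grid(192, (60.0, 60.0))
        full = np.ones((200, 200), bool)
        empty = np.zeros((200, 200), bool)
        assert count_point_hits(empty, full, grid, 0.5) == (0, 192)
        assert count_point_hits(full, full, grid, 0.5) == (192, 192)


class TestTraceIntersections:
    def test_single_transversal_crossing(self):
        line = ws.build_line_system(40.0, (40.0, 40.0), 1)
        traces = np.array([[[20.0, 0.0], [20.0, 40.0]]])  # vertical trace
        assert count_trace_intersections(traces, line) == 1

    def test_parallel_trace_never_crosses(self):
        line = ws.build_line_system(40.0, (40.0, 40.0), 1)
        traces = np.array([[[0.0, 30.0], [40.0, 30.0]]])
        assert count_trace_intersections(traces, line) == 0

    def test_cycloid_crossing_count_matches_membership_runs_of_fat_trace(self):
        """The geometric count agrees with run counting on a well-resolved strip."""
        sys_ = ws.build_test_system("length", 320.0, (64.0, 64.0), 4.0)
        rng = np.random.default_rng(8)
        traces = np.stack(
            [
                np.column_stack([rng.uniform(5, 59, 6), rng.uniform(5, 59, 6)]),
                np.column_stack([rng.uniform(5, 59, 6), rng.uniform(5, 59, 6)]),
            ],
            axis=1,
        )
        geometric = count_trace_intersections(traces, sys_)
        ps = 0.125
        mask = np.zeros((512, 512), bool)
        for (ax, ay), (bx, by) in traces:
            for t in np.linspace(0, 1, 4000):
                x, y = ax + t * (bx - ax), ay + t * (by - ay)
                c, r = int(x / ps), int(y / ps)
                mask[max(r - 4, 0) : r + 5, max(c - 4, 0) : c + 5] |= (
                    (np.arange(max(r - 4, 0), r + 5)[:, None] + 0.5) * ps - y
                ) ** 2 + ((np.arange(max(c - 4, 0), c + 5)[None, :] + 0.5) * ps - x) ** 2 <= 0.25
        runs = count_profile_intersections(mask, sys_, ps)
        assert abs(runs - geometric) <= max(2, 0.2 * geometric)


class TestWoundFields:
    @pytest.fixture()
    def probes(self):
        surf = ws.build_test_system("surface", 192.0, (48.0, 48.0), 4.0)
        leng = ws.build_test_system("length", 192.0, (48.0, 48.0), 4.0)
        return surf, leng

    def test_blank_section_all_zero(self, probes):
        surf, leng = probes
        blank = ws.SectionImage(
            vessel_mask=np.zeros((600, 1000), bool),
            tissue_mask=np.ones((600, 1000), bool),
            cell_mask=np.zeros((600, 1000), bool),
            pixel_size=0.5,
        )
        plan = ws.plan_fields((30.0, 470.0), (48.0, 48.0), 5, seed=1)
        counts = count_wound_fields(blank, plan, surf, leng)
        assert len(counts) == 5
        assert all(c.I_surface == 0 and c.I_length == 0 and c.P_p == 0 for c in counts)
        assert all(c.P_T == 192 for c in counts)

    def test_locality_of_counts(self, probes):
        """Vessels present only under one field produce counts only there."""
        surf, leng = probes
        vessel = np.zeros((600, 1000), bool)
        plan = ws.plan_fields((30.0, 470.0), (48.0, 48.0), 5, seed=2)
        cx = plan.centers[3]
        vessel[280:320, int((cx - 10) / 0.5) : int((cx + 10) / 0.5)] = True
        sec = ws.SectionImage(
            vessel_mask=vessel,
            tissue_mask=np.ones_like(vessel),
            cell_mask=np.zeros_like(vessel),
            pixel_size=0.5,
        )
        counts = count_wound_fields(sec, plan, surf, leng)
        nonzero = [c.field_id for c in counts if c.I_surface + c.I_length > 0]
        assert nonzero == [3]

    def test_compositionality_with_single_field_calls(self, small_tissue):
        surf = ws.build_test_system("surface", 128.0, (32.0, 32.0), 4.0)
        leng = ws.build_test_system("length", 128.0, (32.0, 32.0), 4.0)
        sec = cut_section_pair(small_tissue, 40.0, 5.0, 0.5)
        plan = ws.plan_fields((16.0, 64.0), (32.0, 32.0), 1, seed=5)
        (fc,) = count_wound_fields(sec, plan, surf, leng)
        ox = plan.centers[0] - 16.0
        oy = (80.0 - 32.0) / 2.0
        assert fc.I_surface == count_boundary_intersections(
            sec.vessel_mask, surf, 0.5, (ox, oy)
        )
        assert fc.I_length == count_trace_intersections(sec.trace_segments, leng, (ox, oy))
        P_p, P_T = count_point_hits(
            sec.cell_mask, sec.tissue_mask, surf.point_grid + np.array([ox, oy]), 0.5
        )
        assert (fc.P_p, fc.P_T) == (P_p, P_T)

    def test_field_outside_section_raises(self, probes):
        surf, leng = probes
        blank = ws.SectionImage(
            vessel_mask=np.zeros((100, 200), bool),
            tissue_mask=np.ones((100, 200), bool),
            cell_mask=np.zeros((100, 200), bool),
            pixel_size=0.5,
        )
        plan = ws.plan_fields((0.0, 240.0), (48.0, 48.0), 5, seed=1)
        with pytest.raises(SamplingError):
            count_wound_fields(blank, plan, surf, leng)
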