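"""Quadrat embedding, inclination and substratum classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cichlidhab.geometry import (
    GeometryError,
    NodeGrid,
    apply_water_level_offset,
    cell_attributes,
    classify_substratum,
    depth_summary,
    embed_grid,
    read_node_depths,
    solve_node_position,
    square_inclination,
    triangle_normal,
    write_node_depths,
)


class TestSolveNodePosition:
    def test_equilateral_triangle_in_plane(self):
        x, y = solve_node_position((0, 0, 0), (1, 0, 0), 0.0, 1.0, 1.0, orientation=1)
        assert x == pytest.approx(0.5)
        assert y == pytest.approx(math.sqrt(3) / 2)

    def test_vertical_offset_shrinks_planar_circle(self):
        # both sphere equations must hold in 3D
        x, y = solve_node_position((0, 0, 0), (1, 0, 0), 0.5, 1.0, 1.0, orientation=1)
        assert x == pytest.approx(0.5)
        assert y == pytest.approx(math.sqrt(0.5), abs=1e-9)
        p = np.array([x, y, 0.5])
        assert np.linalg.norm(p - [0, 0, 0]) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(p - [1, 0, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_orientation_selects_mirror_solution(self):
        xp, yp = solve_node_position((0, 0, 0), (1, 0, 0), 0.0, 1.0, 1.0, orientation=1)
        xm, ym = solve_node_position((0, 0, 0), (1, 0, 0), 0.0, 1.0, 1.0, orientation=-1)
        assert xp == pytest.approx(xm)
        assert yp == pytest.approx(-ym)

    def test_vertical_offset_exceeding_distance_errors(self):
        with pytest.raises(GeometryError, match="vertical offset"):
            solve_node_position((0, 0, 0), (1, 0, 0), 1.2, 1.0, 1.0)

    def test_coincident_anchors_error(self):
        with pytest.raises(GeometryError, match="[Cc]oincident"):
            solve_node_position((0, 0, 0), (0, 0, 1), 0.5, 1.0, 1.0)

    def test_disjoint_circles_error(self):
        with pytest.raises(GeometryError, match="do not intersect"):
            solve_node_position((0, 0, 0), (5, 0, 0), 0.0, 1.0, 1.0)


class TestEmbedGrid:
    def test_flat_grid_is_the_unit_lattice(self):
        grid = NodeGrid(depth=np.full((3, 3), 5.0))
        emb = embed_grid(grid)
        for i in range(3):
            for j in range(3):
                assert emb.coords[i, j] == pytest.approx([j, i, 5.0])
        assert emb.max_residual < 1e-12

    def test_single_cell_uniform_slope(self):
        # one cell, rows at depth 1.0 and 1.5: row spacing sqrt(0.75)
        grid = NodeGrid(depth=np.array([[1.0, 1.0], [1.5, 1.5]]))
        emb = embed_grid(grid)
        assert emb.coords[1, 0, 1] == pytest.approx(math.sqrt(0.75))
        # recompute all four edge lengths from the output coordinates
        c = emb.coords
        for a, b in [((0, 0), (0, 1)), ((1, 0), (1, 1)), ((0, 0), (1, 0)), ((0, 1), (1, 1))]:
            assert np.linalg.norm(c[a] - c[b]) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_slope_total_extent(self):
        # 10 rows of 0.5 m depth gain: closed-form extent 10*sqrt(0.75)
        depth = 1.0 + 0.5 * np.arange(11)[:, None] * np.ones((1, 3))
        emb = embed_grid(NodeGrid(depth=depth))
        assert emb.coords[10, 0, 1] == pytest.approx(10 * math.sqrt(0.75), abs=1e-9)
        assert emb.max_residual < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_noiseless_surface_reembeds_exactly(self, seed):
        rng = np.random.default_rng(seed)
        depth = 3.0 + 0.3 * np.arange(9)[:, None] + 0.2 * rng.standard_normal((9, 7)).cumsum(1) * 0.1
        emb = embed_grid(NodeGrid(depth=depth))
        assert emb.max_residual < 1e-6

    def test_infeasible_edge_names_node(self):
        depth = np.array([[1.0, 1.0], [2.5, 2.5]])
        with pytest.raises(GeometryError, match=r"\(1,0\)"):
            embed_grid(NodeGrid(depth=depth))

    def test_refinement_preserves_exact_solution(self):
        depth = 2.0 + 0.4 * np.arange(4)[:, None] * np.ones((1, 4))
        plain = embed_grid(NodeGrid(depth=depth))
        refined = embed_grid(NodeGrid(depth=depth), refine=True)
        assert np.allclose(plain.coords, refined.coords, atol=1e-6)

    def test_node_depth_tsv_round_trip(self, tmp_path):
        grid = NodeGrid(depth=np.array([[2.0, 2.1], [2.5, 2.6]]))
        p = tmp_path / "nodes.tsv"
        write_node_depths(grid, p)
        back = read_node_depths(p)
        assert np.allclose(back.depth, grid.depth)


class TestInclination:
    def test_triangle_normal_horizontal(self):
        n = triangle_normal((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert abs(n[2]) == pytest.approx(1.0)

    def test_triangle_normal_45_degrees(self):
        n = triangle_normal((0, 0, 0), (1, 0, 0), (0, 1, 1))
        angle = math.degrees(math.acos(abs(n[2])))
        assert angle == pytest.approx(45.0)
        # orthogonal to both edges
        assert np.dot(n, [1, 0, 0]) == pytest.approx(0, abs=1e-9)
        assert np.dot(n, [0, 1, 1]) == pytest.approx(0, abs=1e-9)

    def test_collinear_points_error(self):
        with pytest.raises(GeometryError, match="degenerate"):
            triangle_normal((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_flat_square_zero_inclination(self):
        corners = [(0, 0, 7), (1, 0, 7), (1, 1, 7), (0, 1, 7)]
        assert square_inclination(corners) == pytest.approx(0.0)

    def test_tilted_plane_30_degrees(self):
        # planar cell where each 1 m down-slope chord drops 0.5 m
        h = math.sqrt(0.75)
        corners = [(0, 0, 0), (1, 0, 0), (1, h, 0.5), (0, h, 0.5)]
        assert square_inclination(corners) == pytest.approx(30.0, abs=1e-9)

    def test_nonplanar_cell_mean_of_four_distinct_angles(self):
        corners = [(0, 0, 0), (1, 0, 0.3), (1, 1, 0.1), (0, 1, 0.25)]
        # independent per-triangle computation via cross products
        pts = [np.array(p, float) for p in corners]
        angles = []
        for drop in range(4):
            tri = [pts[k] for k in range(4) if k != drop]
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            n = n / np.linalg.norm(n)
            angles.append(math.degrees(math.acos(abs(n[2]))))
        assert len(set(round(a, 6) for a in angles)) > 1
        assert square_inclination(corners) == pytest.approx(np.mean(angles))

    @pytest.mark.parametrize("slope", [0.1, 0.3, 0.5, 0.8])
    def test_planar_recovery_through_embedding(self, slope):
        # surface = single plane: every cell recovers arcsin(slope) exactly
        depth = 2.0 + slope * np.arange(7)[:, None] * np.ones((1, 5))
        emb = embed_grid(NodeGrid(depth=depth))
        attrs = cell_attributes(emb)
        expected = math.degrees(math.asin(slope))
        assert np.allclose(attrs["inclination_deg"], expected, atol=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        depth = 3.0 + 0.3 * np.arange(5)[:, None] + 0.05 * rng.standard_normal((5, 4))
        emb = embed_grid(NodeGrid(depth=depth))
        attrs = cell_attributes(emb)
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = emb.coords.copy()
        moved[:, :, :2] = moved[:, :, :2] @ R.T + np.array([12.0, -4.0])
        from cichlidhab.geometry import EmbeddedGrid

        attrs2 = cell_attributes(EmbeddedGrid(coords=moved, residuals=emb.residuals))
        assert np.allclose(attrs["inclination_deg"], attrs2["inclination_deg"], atol=1e-9)
        assert np.allclose(attrs["mean_depth_m"], attrs2["mean_depth_m"])


class TestSubstratum:
    @pytest.mark.parametrize(
        "size,cls",
        [
            (60, "rock"),
            (10, "rubble"),
            (0.4, "sand"),
            (0.5, "gravel"),
            (3, "rubble"),
            (20, "stone"),
            (50, "stone"),
            (50.001, "rock"),
        ],
    )
    def test_examples_and_boundaries(self, size, cls):
        assert classify_substratum(size) == cls

    @pytest.mark.parametrize("bad", [0, -1, float("nan"), float("inf")])
    def test_invalid_sizes_error(self, bad):
        with pytest.raises(ValueError):
            classify_substratum(bad)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    def test_total_partition_of_positive_sizes(self, size):
        assert classify_substratum(size) in {"rock", "stone", "rubble", "gravel", "sand"}


class TestWaterLevelAndSummary:
    def test_offset_shifts_depths(self):
        grid = NodeGrid(depth=np.array([[2.1, 5.0], [9.0, 13.6]]))
        shifted = apply_water_level_offset(grid, 0.5)
        assert np.allclose(shifted.depth, grid.depth + 0.5)
        assert np.allclose(apply_water_level_offset(grid, 0.0).depth, grid.depth)

    def test_offset_to_nonpositive_depth_errors(self):
        grid = NodeGrid(depth=np.array([[2.1, 5.0], [9.0, 13.6]]))
        with pytest.raises(ValueError, match="non-positive"):
            apply_water_level_offset(grid, -2.1)

    def test_inclination_invariant_under_offset(self):
        rng = np.random.default_rng(1)
        depth = 3.0 + 0.3 * np.arange(5)[:, None] + 0.05 * rng.standard_normal((5, 4))
        grid = NodeGrid(depth=depth)
        a1 = cell_attributes(embed_grid(grid))
        a2 = cell_attributes(embed_grid(apply_water_level_offset(grid, 1.3)))
        assert np.allclose(a1["inclination_deg"], a2["inclination_deg"], atol=1e-9)

    def test_depth_summary_printed_limits(self):
        grid = NodeGrid(depth=np.array([[2.1, 2.1], [13.6, 13.6]]))
        s = depth_summary(grid)
        assert s["range"] == pytest.approx(11.5)
        assert s["min"] == 2.1 and s["max"] == 13.6

    def test_depth_summary_translation_invariant_range(self):
        grid = NodeGrid(depth=np.array([[2.1, 3.0], [9.0, 13.6]]))
        s1 = depth_summary(grid)
        s2 = depth_summary(apply_water_level_offset(grid, 0.7))
        assert s1["range"] == pytest.approx(s2["range"])
        assert depth_summary(NodeGrid(depth=np.full((2, 2), 4.0)))["range"] == 0.0
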