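"""Geometry: margin expansion, walls, overlaps, volumes, rasterization."""

import numpy as np
import pytest
from conftest import (
    brute_force_expand,
    brute_force_rasterize,
    lens_volume,
    sphere_mask,
)

from hypotriage import (
    ContourStack,
    MarginSpec,
    StructureMask,
    expand_margin,
    fractional_overlap,
    rasterize_contours,
    structure_volume,
    wall_from_solid,
)
from hypotriage.errors import (
    CoregistrationError,
    EmptyStructureError,
    ExtentError,
    InvalidContourError,
)


def grid(shape=(20, 20, 20), spacing=1.0, origin=None):
    if origin is None:
        origin = (0.0, 0.0, 0.0)
    return StructureMask(np.zeros(shape, bool), (spacing,) * 3, origin)


class TestStructureMask:
    def test_invariants(self):
        with pytest.raises(ValueError):
            StructureMask(np.zeros((4, 4, 4), bool), spacing=(1.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            StructureMask(np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            StructureMask(np.zeros((4, 4, 4), bool), axis_labels=("R", "L", "S"))

    def test_volume_is_count_times_voxel_volume(self):
        mask = grid((12, 12, 12))
        mask.voxels[1:11, 1:11, 1:11] = True  # 10 mm cube on a 1 mm grid
        assert mask.volume_mm3 == pytest.approx(1000.0)
        assert structure_volume(mask) == pytest.approx(1.0)
        assert structure_volume(grid()) == 0.0

    def test_sphere_volume_close_to_analytic(self):
        mask = sphere_mask(36.5, spacing=1.0)
        analytic = 4.0 / 3.0 * np.pi * 36.5**3 / 1000.0
        assert analytic == pytest.approx(203.7, rel=1e-3)
        assert structure_volume(mask) == pytest.approx(analytic, rel=0.02)

    def test_coregistration_requires_identical_grids(self):
        a, b = grid(), grid(origin=(0.5, 0.0, 0.0))
        assert not a.same_grid(b)
        with pytest.raises(CoregistrationError):
            fractional_overlap(a.with_voxels(np.ones(a.shape, bool)), b)


class TestExpandMargin:
    def test_zero_margins_are_identity(self):
        ctv = grid()
        ctv.voxels[8:12, 8:12, 8:12] = True
        out = expand_margin(ctv, MarginSpec.isotropic(0.0))
        assert np.array_equal(out.voxels, ctv.voxels)

    def test_isotropic_margin_gives_digitized_ball(self):
        ctv = grid((25, 25, 25))
        ctv.voxels[12, 12, 12] = True
        out = expand_margin(ctv, MarginSpec.isotropic(10.0))
        x, y, z = np.meshgrid(*(np.arange(25) - 12.0,) * 3, indexing="ij", sparse=True)
        ball = x**2 + y**2 + z**2 <= 10.0**2 + 1e-9
        assert np.array_equal(out.voxels, ball)

    def test_asymmetric_margin_matches_brute_force_and_extents(self):
        # posterior margin 7 mm, everything else 10 mm; axis 1 increases
        # anteriorly, so the posterior direction is decreasing index.
        ctv = grid((25, 25, 25))
        ctv.voxels[12, 12, 12] = True
        margins = MarginSpec()
        out = expand_margin(ctv, margins)
        assert np.array_equal(out.voxels, brute_force_expand(ctv, margins))
        js = np.argwhere(out.voxels)[:, 1]
        assert 12 - js.min() == 7  # posterior reach
        assert js.max() - 12 == 10  # anterior reach
        for axis in (0, 2):
            idx = np.argwhere(out.voxels)[:, axis]
            assert idx.max() - 12 == 10 and 12 - idx.min() == 10

    def test_axis_labels_drive_the_posterior_direction(self):
        # Same voxel content, posterior-increasing axis ("P" label):
        ctv = grid((25, 25, 25))
        ctv.voxels[12, 12, 12] = True
        ctv.axis_labels = ("R", "P", "S")
        out = expand_margin(ctv, MarginSpec())
        js = np.argwhere(out.voxels)[:, 1]
        assert js.max() - 12 == 7 and 12 - js.min() == 10

    def test_matches_brute_force_on_random_small_ctvs(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            ctv = StructureMask(
                np.zeros((18, 18, 18), bool), spacing=(1.5, 2.0, 2.5)
            )
            idx = rng.integers(6, 12, size=(5, 3))
            ctv.voxels[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            margins = MarginSpec(*rng.uniform(0.0, 8.0, 6).round(1))
            out = expand_margin(ctv, margins)
            assert np.array_equal(out.voxels, brute_force_expand(ctv, margins))

    def test_expansion_is_monotone_in_margins(self):
        rng = np.random.default_rng(11)
        ctv = grid((16, 16, 16))
        idx = rng.integers(5, 11, size=(4, 3))
        ctv.voxels[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        small = MarginSpec(*rng.uniform(0, 4, 6))
        big = MarginSpec(*(getattr(small, n) + rng.uniform(0, 4) for n in
                           ("right", "left", "anterior", "posterior", "inferior", "superior")))
        inner = expand_margin(ctv, small).voxels
        outer = expand_margin(ctv, big).voxels
        assert np.all(outer[inner])  # inner subset of outer
        assert np.all(outer[ctv.voxels])  # PTV contains CTV

    def test_empty_ctv_raises(self):
        with pytest.raises(EmptyStructureError):
            expand_margin(grid(), MarginSpec())


class TestWallFromSolid:
    def test_sphere_shell_volume_close_to_analytic(self):
        organ = sphere_mask(20.0, spacing=1.0)
        wall = wall_from_solid(organ, 3.0)
        shell = 4.0 / 3.0 * np.pi * (20.0**3 - 17.0**3)
        assert wall.volume_mm3 == pytest.approx(shell, rel=0.05)

    def test_thick_wall_is_whole_organ(self):
        organ = sphere_mask(8.0, spacing=1.0)
        wall = wall_from_solid(organ, 9.0)
        assert np.array_equal(wall.voxels, organ.voxels)

    def test_wall_is_disjoint_from_interior_and_subset_of_organ(self):
        organ = sphere_mask(15.0, spacing=1.0)
        wall = wall_from_solid(organ, 4.0)
        interior = organ.voxels & ~wall.voxels
        assert not np.any(wall.voxels & interior)
        assert np.all(organ.voxels[wall.voxels])

    def test_empty_organ_raises(self):
        with pytest.raises(EmptyStructureError):
            wall_from_solid(grid(), 3.0)


class TestFractionalOverlap:
    def test_identical_masks_give_one(self):
        mask = sphere_mask(10.0)
        assert fractional_overlap(mask, mask) == 1.0

    def test_disjoint_masks_give_zero(self):
        base = grid((30, 10, 10))
        a = base.with_voxels(np.zeros(base.shape, bool))
        b = base.with_voxels(np.zeros(base.shape, bool))
        a.voxels[:5] = True
        b.voxels[20:] = True
        assert fractional_overlap(a, b) == 0.0

    @pytest.mark.parametrize("spacing,tol", [(1.0, 0.03), (0.5, 0.015)])
    def test_sphere_lens_ratio_converges_to_analytic(self, spacing, tol):
        r_oar, r_ptv, distance = 15.0, 20.0, 25.0
        # Build both spheres on one grid covering both centers.
        half = 24.0
        n_x = int((distance + 2 * half) / spacing) + 1
        n_yz = int(2 * half / spacing) + 1
        origin = (-half, -half, -half)
        axes = [origin[0] + spacing * np.arange(n_x),
                origin[1] + spacing * np.arange(n_yz),
                origin[2] + spacing * np.arange(n_yz)]
        x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
        template = StructureMask(
            np.zeros((n_x, n_yz, n_yz), bool), (spacing,) * 3, origin
        )
        oar = template.with_voxels(x**2 + y**2 + z**2 <= r_oar**2)
        ptv = template.with_voxels((x - distance) ** 2 + y**2 + z**2 <= r_ptv**2)
        expected = lens_volume(r_oar, r_ptv, distance) / (4.0 / 3.0 * np.pi * r_oar**3)
        assert fractional_overlap(oar, ptv) == pytest.approx(expected, rel=tol)

    def test_invariant_under_whole_voxel_translation(self):
        rng = np.random.default_rng(3)
        base = grid((20, 20, 20))
        a = base.with_voxels(rng.random(base.shape) < 0.2)
        b = base.with_voxels(rng.random(base.shape) < 0.3)
        f0 = fractional_overlap(a, b)
        shifted_a = a.with_voxels(np.roll(a.voxels, (2, -1, 3), axis=(0, 1, 2)))
        shifted_b = b.with_voxels(np.roll(b.voxels, (2, -1, 3), axis=(0, 1, 2)))
        assert fractional_overlap(shifted_a, shifted_b) == f0

    def test_empty_oar_raises(self):
        base = grid()
        with pytest.raises(EmptyStructureError):
            fractional_overlap(base, base.with_voxels(np.ones(base.shape, bool)))


class TestRasterizeContours:
    def test_square_contour_covers_expected_voxels(self):
        # 10x10 mm square; voxel centers at 0.5..14.5 -> 100 centers inside.
        template = grid((15, 15, 3), origin=(0.5, 0.5, 0.0))
        stack = ContourStack("square", [(1.0, [[(2.0, 2.0), (12.0, 2.0), (12.0, 12.0), (2.0, 12.0)]])])
        out = rasterize_contours(stack, template)
        assert out.n_true == 100
        assert out.voxels[:, :, 1].sum() == 100  # nearest plane z=1

    def test_empty_stack_gives_all_false(self):
        out = rasterize_contours(ContourStack("empty", []), grid())
        assert out.n_true == 0

    def test_disjoint_squares_are_additive(self):
        template = grid((30, 30, 3), origin=(0.5, 0.5, 0.0))
        square_a = [(2.0, 2.0), (8.0, 2.0), (8.0, 8.0), (2.0, 8.0)]
        square_b = [(15.0, 15.0), (25.0, 15.0), (25.0, 25.0), (15.0, 25.0)]
        both = rasterize_contours(ContourStack("s", [(1.0, [square_a, square_b])]), template)
        only_a = rasterize_contours(ContourStack("a", [(1.0, [square_a])]), template)
        only_b = rasterize_contours(ContourStack("b", [(1.0, [square_b])]), template)
        assert both.n_true == only_a.n_true + only_b.n_true

    def test_matches_ray_casting_oracle_on_irregular_polygon(self):
        rng = np.random.default_rng(9)
        template = grid((25, 25, 5), origin=(0.25, 0.25, 0.0))
        # star-shaped polygon with irrational-ish vertices (no center hits edges)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 9))
        radii = rng.uniform(4.0, 11.0, 9)
        vertices = [(12.1 + r * np.cos(t), 12.2 + r * np.sin(t)) for r, t in zip(radii, angles)]
        stack = ContourStack("star", [(2.0, [vertices])])
        out = rasterize_contours(stack, template)
        assert np.array_equal(out.voxels, brute_force_rasterize(stack, template))

    def test_degenerate_polygon_raises(self):
        with pytest.raises(InvalidContourError):
            ContourStack("bad", [(0.0, [[(0.0, 0.0), (1.0, 1.0)]])])

    def test_stack_outside_grid_raises(self):
        template = grid((10, 10, 3))
        stack = ContourStack("far", [(1.0, [[(50.0, 50.0), (60.0, 50.0), (60.0, 60.0)]])])
        with pytest.raises(ExtentError):
            rasterize_contours(stack, template)

    def test_slice_z_must_increase(self):
        square = [[(0.0, 0.0), (1.0, 0.0), (1.0, 1.0)]]
        with pytest.raises(ValueError):
            ContourStack("z", [(1.0, square), (1.0, square)])
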