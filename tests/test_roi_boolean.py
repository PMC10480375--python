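"""Dual-ROI construction, Boolean engines, and fragment filtering."""

import numpy as np
import pytest
import trimesh

from augvol import mesh_io, roi_boolean, validate_mesh
from augvol.errors import EmptyDiffError, InvalidROIError
from augvol.roi_boolean import (
    boolean_intersect,
    boolean_subtract,
    boolean_union,
    box_roi,
    clip_half_space,
    drop_disconnected,
    make_roi_pair,
)
from augvol.volume import enclosed_volume

from oracles import ray_parity_difference_volume


def tvol(mesh):
    return enclosed_volume(mesh).volume_mm3


class TestROIPair:
    def test_cube_scaling_law(self, unit_cube):
        pair = make_roi_pair(unit_cube, scale=0.99)
        assert tvol(pair.inner) == pytest.approx(0.99**3, rel=1e-9)

    def test_sphere_scaling_law(self, icosphere):
        pair = make_roi_pair(icosphere, scale=0.95)
        assert tvol(pair.inner) / tvol(pair.outer) == pytest.approx(
            0.95**3, rel=1e-9
        )

    @pytest.mark.parametrize("scale", [1.0, 0.5, 1.2])
    def test_scale_out_of_range(self, unit_cube, scale):
        with pytest.raises(InvalidROIError):
            make_roi_pair(unit_cube, scale=scale)

    def test_open_shape_rejected(self, unit_cube):
        open_mesh = validate_mesh((unit_cube.vertices, unit_cube.faces[:-1]))
        with pytest.raises(InvalidROIError):
            make_roi_pair(open_mesh)

    def test_inner_strictly_contained_in_outer(self):
        pair = box_roi([0, 0, 0], [10, 8, 6], scale=0.98)
        lo, hi = pair.outer.bounds
        assert (pair.inner.vertices > lo).all() and (pair.inner.vertices < hi).all()


class TestClipHalfSpace:
    def test_cube_clip_volume(self, unit_cube):
        out = clip_half_space(unit_cube, [0.3, 0, 0], [1, 0, 0])
        assert mesh_io.is_watertight(out)
        assert tvol(out) == pytest.approx(0.8, rel=1e-9)

    def test_sphere_cap_volume(self, icosphere):
        h = 2.0  # keep z <= 3 of an r=5 sphere: cap of height h removed
        out = clip_half_space(icosphere, [0, 0, 3.0], [0, 0, 1])
        cap = np.pi * h**2 * (3 * 5.0 - h) / 3
        expected = 4 / 3 * np.pi * 125 - cap
        assert tvol(out) == pytest.approx(expected, rel=5e-3)

    def test_plane_missing_solid(self, unit_cube):
        out = clip_half_space(unit_cube, [5, 0, 0], [1, 0, 0])
        assert tvol(out) == pytest.approx(1.0, rel=1e-9)
        assert len(clip_half_space(unit_cube, [-5, 0, 0], [1, 0, 0]).faces) == 0


class TestBooleanIntersect:
    def test_overlapping_cubes(self, unit_cube):
        other = unit_cube.copy()
        other.apply_translation([0.5, 0, 0])
        out = boolean_intersect(unit_cube, other)
        assert tvol(out) == pytest.approx(0.5, rel=1e-9)

    def test_disjoint_cubes_empty(self, unit_cube):
        other = unit_cube.copy()
        other.apply_translation([5, 0, 0])
        assert len(boolean_intersect(unit_cube, other).faces) == 0

    def test_self_intersection_idempotent(self, unit_cube):
        assert tvol(boolean_intersect(unit_cube, unit_cube.copy())) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_sphere_in_box(self, icosphere):
        box = validate_mesh(trimesh.creation.box((20, 20, 20)))
        out = boolean_intersect(icosphere, box)
        assert tvol(out) == pytest.approx(tvol(icosphere), rel=1e-9)


class TestBooleanSubtract:
    def test_box_minus_half_cube(self, unit_cube):
        big = validate_mesh(trimesh.creation.box((2, 1, 1)))
        big.apply_translation([0.5, 0, 0])
        cube = unit_cube.copy()
        cube.apply_translation([-0.5, -0.5, -0.5])  # unit_cube is centred
        big.apply_translation([-0.5, -0.5, -0.5])
        out = boolean_subtract(big, cube)
        assert tvol(out) == pytest.approx(1.0, rel=1e-9)

    def test_self_difference_empty(self, unit_cube):
        assert len(boolean_subtract(unit_cube, unit_cube.copy()).faces) == 0

    def test_voxel_subtract_spheres_analytic(self):
        R, d = 5.0, 3.0
        a = validate_mesh(trimesh.creation.icosphere(3, R))
        b = a.copy()
        b.apply_translation([d, 0, 0])
        out = boolean_subtract(a, b, engine="voxel", pitch=0.1)
        lens = np.pi * (4 * R + d) * (2 * R - d) ** 2 / 12
        expected = 4 / 3 * np.pi * R**3 - lens
        assert tvol(out) == pytest.approx(expected, rel=0.01)

    def test_exact_and_voxel_engines_agree(self, icosphere):
        box = validate_mesh(trimesh.creation.box((6, 6, 6)))
        box.apply_translation([3, 0, 0])
        exact = boolean_subtract(icosphere, box, engine="exact")
        vox = boolean_subtract(icosphere, box, engine="voxel", pitch=0.1)
        assert tvol(vox) == pytest.approx(tvol(exact), rel=0.01)


class TestBooleanIdentities:
    def test_inclusion_exclusion_exact_engine(self, unit_cube):
        """vol(A) + vol(B) = vol(A u B) + vol(A n B) on overlapping boxes."""
        a = unit_cube
        b = unit_cube.copy()
        b.apply_translation([0.4, 0.3, 0.0])
        inter = tvol(boolean_intersect(a, b))
        union_analytic = 2.0 - 0.6 * 0.7 * 1.0
        assert tvol(a) + tvol(b) - inter == pytest.approx(
            union_analytic, rel=1e-3
        )

    def test_subtract_plus_intersect_recovers_whole(self, icosphere):
        box = validate_mesh(trimesh.creation.box((6, 6, 6)))
        box.apply_translation([3, 1, 0])
        diff = tvol(boolean_subtract(icosphere, box, engine="exact"))
        inter = tvol(boolean_intersect(icosphere, box, engine="exact"))
        assert diff + inter == pytest.approx(tvol(icosphere), rel=1e-3)

    def test_identities_voxel_engine_shared_grid(self):
        """Same identities hold for the voxel engine on non-convex operands."""
        from augvol import voxel as vx

        a = validate_mesh(trimesh.creation.icosphere(3, 5.0))
        b = a.copy()
        b.apply_translation([3.5, 1.0, 0.5])
        lo = np.minimum(a.bounds[0], b.bounds[0])
        hi = np.maximum(a.bounds[1], b.bounds[1])
        grid = vx.VoxelGrid.for_bounds(lo, hi, 0.1)
        oa, ob = vx.voxelize_solid(a, grid), vx.voxelize_solid(b, grid)
        vol = lambda occ: tvol(vx.mesh_from_occupancy(occ, grid))  # noqa: E731
        assert vol(oa & ~ob) + vol(oa & ob) == pytest.approx(vol(oa), rel=1e-3)
        assert vol(oa | ob) + vol(oa & ob) == pytest.approx(
            vol(oa) + vol(ob), rel=1e-3
        )

    def test_voxel_backend_matches_ray_parity_oracle(self):
        """Independent oblique-ray parity oracle agrees within 1 %."""
        sphere = validate_mesh(trimesh.creation.icosphere(3, 5.0))
        box = validate_mesh(trimesh.creation.box((5, 5, 5)))
        box.apply_translation([2.5, 1.5, 0.5])
        diff = boolean_subtract(sphere, box, engine="voxel", pitch=0.1)
        backend = tvol(diff)
        oracle = ray_parity_difference_volume(sphere, box, pitch=0.15)
        assert backend == pytest.approx(oracle, rel=0.01)


class TestDropDisconnected:
    def _with_specks(self, icosphere):
        parts = [icosphere]
        for i, c in enumerate([(8, 0, 0), (0, 9, 0), (0, 0, -8)]):
            s = trimesh.creation.icosphere(1, 0.3)
            s.apply_translation(c)
            parts.append(s)
        return trimesh.util.concatenate(parts)

    def test_largest_keeps_main_blob(self, icosphere):
        main_vol = tvol(icosphere)
        kept = drop_disconnected(self._with_specks(icosphere), policy="largest")
        assert tvol(kept) == pytest.approx(main_vol, rel=1e-9)
        assert len(mesh_io.connected_components(kept)) == 1

    def test_threshold_keeps_large_enough(self, icosphere):
        mid = trimesh.creation.icosphere(3, 3.0)
        mid.apply_translation([12, 0, 0])
        mesh = trimesh.util.concatenate([self._with_specks(icosphere), mid])
        kept = drop_disconnected(mesh, policy="threshold", threshold=0.1)
        assert len(mesh_io.connected_components(kept)) == 2

    def test_single_component_identity(self, icosphere):
        kept = drop_disconnected(icosphere, policy="largest")
        assert tvol(kept) == pytest.approx(tvol(icosphere), rel=1e-12)

    def test_equal_components_deterministic_tie_break(self, unit_cube):
        a = unit_cube.copy()
        b = unit_cube.copy()
        b.apply_translation([3, 0, 0])
        for mesh in (
            trimesh.util.concatenate([a, b]),
            trimesh.util.concatenate([b, a]),
        ):
            kept = drop_disconnected(mesh, policy="largest")
            # lowest lexicographic minimum-vertex wins: the unshifted cube
            assert kept.vertices[:, 0].min() == pytest.approx(
                a.vertices[:, 0].min()
            )

    def test_empty_input_raises(self):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(EmptyDiffError):
            drop_disconnected(empty)
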