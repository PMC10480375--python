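"""Dual region-of-interest definition, mesh Booleans, and fragment filtering.

The measurement isolates the grafted volume by intersecting the closed
baseline solid with an outer ROI solid (ROI 1) and each closed augmented
solid with a slightly scaled-down copy (ROI 2), then subtracting baseline
from augmented.  The size offset between the two ROIs guarantees that the
baseline walls fully cover the augmented walls, so the subtraction leaves
only the added material (plus, for particulate grafts, free-floating
specks that are dropped by connected-component filtering).

Two Boolean engines are used:

* **exact** — successive capped half-space clipping, applicable whenever
  one operand is convex (always true for box/convex ROI solids, and for the
  convex-subtrahend decomposition of a difference).  Exact up to floating
  point.
* **voxel** — shared-grid occupancy algebra (see :mod:`augvol.voxel`) for
  the general case, in particular augmented-minus-baseline where both
  solids are closed scan patches.

``engine="auto"`` picks exact when a convex operand allows it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from . import voxel as _voxel
from .errors import BooleanError, EmptyDiffError, InvalidROIError, SolidifyError
from .mesh_io import is_watertight, validate_mesh, connected_components
from .solidify import find_boundary_loops, triangulate_polygon_2d

_EMPTY = lambda: trimesh.Trimesh(  # noqa: E731
    vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int)
)


@dataclass
class ROIPair:
    """Outer (ROI 1) and inner (ROI 2) region-of-interest solids.

    ``inner`` is ``outer`` scaled about its centroid by ``scale`` in
    (0.9, 1.0): slightly smaller, so the baseline intersection's walls
    strictly cover the augmented intersection's walls.
    """

    outer: trimesh.Trimesh
    inner: trimesh.Trimesh
    scale: float


def make_roi_pair(shape: trimesh.Trimesh, scale: float = 0.98) -> ROIPair:
    """Build the dual-ROI pair from a watertight (typically box) solid."""
    if not (0.9 < scale < 1.0):
        raise InvalidROIError(f"scale must be in (0.9, 1.0), got {scale}")
    if not is_watertight(shape):
        raise InvalidROIError("ROI shape must be watertight")
    centroid = shape.vertices.mean(axis=0)
    inner = shape.copy()
    inner.vertices = centroid + scale * (inner.vertices - centroid)
    return ROIPair(outer=shape.copy(), inner=inner, scale=scale)


def box_roi(min_corner, max_corner, scale: float = 0.98) -> ROIPair:
    """Axis-aligned box ROI from its min/max corners (baseline frame, mm)."""
    lo = np.asarray(min_corner, float)
    hi = np.asarray(max_corner, float)
    if (hi <= lo).any():
        raise InvalidROIError("box max corner must exceed min corner on every axis")
    box = trimesh.creation.box(extents=hi - lo)
    box.apply_translation((lo + hi) / 2.0)
    return make_roi_pair(validate_mesh(box), scale=scale)


# ---------------------------------------------------------------------------
# exact engine: capped half-space clipping

def clip_half_space(mesh: trimesh.Trimesh, point, normal) -> trimesh.Trimesh:
    """Exact clip of a watertight solid by the half-space (x-p)·n <= 0.

    The open cut is capped by ear-clipping each boundary loop in the cut
    plane.  Nested loops (a cross-section with holes) are not handled by
    the exact engine and raise :class:`BooleanError`; callers fall back to
    the voxel engine.
    """
    p = np.asarray(point, float)
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=-n, plane_origin=p, cap=False
    )
    if sliced is None or len(sliced.faces) == 0:
        return _EMPTY()
    sliced = validate_mesh(sliced)
    try:
        loops = find_boundary_loops(sliced)
    except Exception as exc:
        raise BooleanError(f"cut boundary is non-manifold: {exc}") from exc
    if not loops:
        return sliced  # plane missed the solid entirely

    # in-plane 2D frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    verts = np.asarray(sliced.vertices, float)
    polys2 = [np.column_stack([verts[lp] @ u, verts[lp] @ v]) for lp in loops]
    if len(polys2) > 1:
        from shapely.geometry import Polygon

        shp = [Polygon(pp).buffer(0) for pp in polys2]
        for i in range(len(shp)):
            for j in range(len(shp)):
                if i != j and shp[i].contains(shp[j].representative_point()):
                    raise BooleanError("nested cut loops (cross-section with holes)")

    cap_faces = []
    for lp, pp in zip(loops, polys2):
        try:
            tris = triangulate_polygon_2d(pp)
        except SolidifyError as exc:
            raise BooleanError(f"cannot triangulate cut cap: {exc}") from exc
        cap_faces.append(np.asarray(lp)[tris])
    faces = np.vstack([sliced.faces] + cap_faces)
    out = validate_mesh((verts, faces))
    if not is_watertight(out):
        raise BooleanError("capped clip is not watertight")
    return out


def _unique_planes(convex: trimesh.Trimesh):
    """Deduplicated outward (point, normal) face planes of a convex solid."""
    normals = convex.face_normals
    origins = convex.triangles[:, 0]
    offs = (normals * origins).sum(axis=1)
    key = np.round(np.column_stack([normals, offs]) / 1e-8).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    return [(origins[i], normals[i]) for i in sorted(idx)]


def _check_solid(mesh: trimesh.Trimesh, name: str) -> None:
    if len(mesh.faces) == 0:
        return
    if not is_watertight(mesh):
        raise BooleanError(f"{name} operand must be watertight")


def _shared_grid(a, b, pitch):
    lo = np.minimum(a.bounds[0], b.bounds[0])
    hi = np.maximum(a.bounds[1], b.bounds[1])
    return _voxel.VoxelGrid.for_bounds(lo, hi, pitch)


def boolean_intersect(
    a: trimesh.Trimesh,
    b: trimesh.Trimesh,
    engine: str = "auto",
    pitch: float = _voxel.DEFAULT_PITCH,
) -> trimesh.Trimesh:
    """Watertight intersection of two solids; empty mesh if disjoint."""
    _check_solid(a, "first")
    _check_solid(b, "second")
    if len(a.faces) == 0 or len(b.faces) == 0:
        return _EMPTY()
    if (a.bounds[1] < b.bounds[0]).any() or (b.bounds[1] < a.bounds[0]).any():
        return _EMPTY()
    if engine == "auto":
        engine = "exact" if (b.is_convex or a.is_convex) else "voxel"
    if engine == "exact":
        if b.is_convex:
            subject, cutter = a, b
        elif a.is_convex:
            subject, cutter = b, a
        else:
            raise BooleanError("exact engine needs a convex operand")
        try:
            out = subject
            for p, n in _unique_planes(cutter):
                out = clip_half_space(out, p, n)
                if len(out.faces) == 0:
                    return _EMPTY()
            return out
        except BooleanError:
            engine = "voxel"  # robust fallback
    grid = _shared_grid(a, b, pitch)
    occ = _voxel.voxelize_solid(a, grid) & _voxel.voxelize_solid(b, grid)
    return _voxel.mesh_from_occupancy(occ, grid)


def boolean_subtract(
    a: trimesh.Trimesh,
    b: trimesh.Trimesh,
    engine: str = "auto",
    pitch: float = _voxel.DEFAULT_PITCH,
) -> trimesh.Trimesh:
    """Watertight difference a − b (possibly multiple components).

    With a convex subtrahend the difference is computed exactly as a
    disjoint union of clipped pieces (one per subtrahend plane); the pieces
    are returned concatenated without vertex sharing, so each remains
    individually watertight.  Otherwise the shared-grid voxel engine is
    used — the pipeline's augmented-minus-baseline case, where grid sharing
    makes the coincident far-field surfaces cancel cleanly.
    """
    _check_solid(a, "first")
    _check_solid(b, "second")
    if len(a.faces) == 0:
        return _EMPTY()
    if len(b.faces) == 0 or (a.bounds[1] < b.bounds[0]).any() or (
        b.bounds[1] < a.bounds[0]
    ).any():
        return a.copy()
    if engine == "auto":
        engine = "exact" if b.is_convex else "voxel"
    if engine == "exact":
        if not b.is_convex:
            raise BooleanError("exact subtraction needs a convex subtrahend")
        try:
            pieces = []
            remainder = a
            for p, n in _unique_planes(b):
                # piece outside this plane, inside all previous ones
                piece = clip_half_space(remainder, p, -np.asarray(n, float))
                if len(piece.faces):
                    pieces.append(piece)
                remainder = clip_half_space(remainder, p, n)
                if len(remainder.faces) == 0:
                    break
            if not pieces:
                return _EMPTY()
            return trimesh.util.concatenate(pieces)
        except BooleanError:
            engine = "voxel"
    grid = _shared_grid(a, b, pitch)
    occ = _voxel.voxelize_solid(a, grid) & ~_voxel.voxelize_solid(b, grid)
    return _voxel.mesh_from_occupancy(occ, grid)


def boolean_union(
    a: trimesh.Trimesh,
    b: trimesh.Trimesh,
    pitch: float = _voxel.DEFAULT_PITCH,
) -> trimesh.Trimesh:
    """Watertight union via the voxel engine (used for consistency checks)."""
    _check_solid(a, "first")
    _check_solid(b, "second")
    if len(a.faces) == 0:
        return b.copy()
    if len(b.faces) == 0:
        return a.copy()
    grid = _shared_grid(a, b, pitch)
    occ = _voxel.voxelize_solid(a, grid) | _voxel.voxelize_solid(b, grid)
    return _voxel.mesh_from_occupancy(occ, grid)


# ---------------------------------------------------------------------------
# fragment filtering

def _component_volume(comp: trimesh.Trimesh) -> float:
    return abs(_voxel.signed_volume(comp))


def drop_disconnected(
    diff: trimesh.Trimesh, policy: str = "largest", threshold: float = 0.05
) -> trimesh.Trimesh:
    """Remove free-floating fragments from a difference mesh.

    ``policy="largest"`` keeps the single largest-volume face-adjacency
    component (ties broken deterministically by the lexicographically
    smallest minimum vertex coordinate).  ``policy="threshold"`` keeps all
    components whose volume is at least ``threshold`` times the largest —
    for particulate grafts that legitimately split into attached-but-
    separate pieces.
    """
    if diff is None or len(diff.faces) == 0:
        raise EmptyDiffError("difference mesh is empty")
    if policy not in ("largest", "threshold"):
        raise ValueError(f"unknown policy {policy!r}")
    comps = connected_components(diff)
    if len(comps) == 1:
        return comps[0]
    vols = np.array([_component_volume(c) for c in comps])
    if policy == "largest":
        vmax = vols.max()
        tie = np.flatnonzero(vols >= vmax * (1 - 1e-12))
        if len(tie) == 1:
            return comps[tie[0]]
        keys = [tuple(np.min(comps[i].vertices, axis=0)) for i in tie]
        return comps[tie[int(np.lexsort(np.array(keys).T[::-1])[0])]]
    keep = vols >= threshold * vols.max()
    kept = [c for c, k in zip(comps, keep) if k]
    return trimesh.util.concatenate(kept) if len(kept) > 1 else kept[0]
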