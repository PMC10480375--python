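"""Turn a trimmed open surface patch into a watertight solid.

A surface scan is an open sheet; enclosed volume is only defined for a
closed solid.  The workflow crops the scan to the neighbourhood of the
augmentation, finds the single open boundary loop, extrudes that rim away
from the scanned surface and caps the opening with a triangulated face.
Because the *same* closed baseline solid is subtracted later, the absolute
depth of the closure cancels out of the measured augmented volume — it only
has to exceed the registration residual scale.

Two closure modes are provided:

* ``"plane"`` (default): every rim vertex is extruded along the closing
  direction onto a plane ``depth`` below the lowest rim point.  The cap is
  planar, so it cannot poke back through a strongly curved surface.
* ``"translate"``: the rim is translated rigidly by ``depth`` and capped by
  a (generally non-planar) membrane spanning the displaced loop.

Self-intersecting (non-simple) rims are rejected rather than repaired:
failure must be loud, mirroring how a scan whose margin cuts the augmented
region is excluded rather than patched.
"""

from __future__ import annotations

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .errors import (
    EmptyCropError,
    MultiLoopError,
    NonManifoldBoundaryError,
    SolidifyError,
)
from .mesh_io import validate_mesh, is_watertight


# ---------------------------------------------------------------------------
# cropping

def crop_mesh(mesh: trimesh.Trimesh, keep_region) -> trimesh.Trimesh:
    """Sub-mesh of faces lying fully inside ``keep_region``.

    ``keep_region`` is one of:

    * ``{"type": "box", "min": [...], "max": [...]}`` — axis-aligned box;
      use ``±inf`` entries for unbounded axes,
    * ``{"type": "sphere", "center": [...], "radius": r}``,
    * ``{"type": "halfspace", "point": [...], "normal": [...]}`` — keeps the
      side the normal points away from (normal is the outward direction),
    * ``{"type": "faces", "indices": [...]}`` — explicit face-index set,
    * a callable ``f(vertices) -> bool mask`` over the (n, 3) vertex array.

    A face survives only if all three of its vertices are kept; vertex
    indices are compacted in the result.
    """
    if isinstance(keep_region, dict) and keep_region.get("type") == "faces":
        face_idx = np.asarray(keep_region["indices"], dtype=int)
        if len(face_idx) == 0:
            raise EmptyCropError("empty explicit face set")
        sub = mesh.submesh([face_idx], append=True)
        return validate_mesh(sub)

    verts = np.asarray(mesh.vertices, float)
    if callable(keep_region):
        keep_v = np.asarray(keep_region(verts), bool)
    else:
        kind = keep_region["type"]
        if kind == "box":
            lo = np.asarray(keep_region["min"], float)
            hi = np.asarray(keep_region["max"], float)
            keep_v = ((verts >= lo) & (verts <= hi)).all(axis=1)
        elif kind == "sphere":
            c = np.asarray(keep_region["center"], float)
            r = float(keep_region["radius"])
            keep_v = ((verts - c) ** 2).sum(axis=1) <= r * r
        elif kind == "halfspace":
            p = np.asarray(keep_region["point"], float)
            n = np.asarray(keep_region["normal"], float)
            keep_v = (verts - p) @ n <= 0
        else:
            raise ValueError(f"unknown keep_region type {kind!r}")

    keep_f = keep_v[mesh.faces].all(axis=1)
    if not keep_f.any():
        raise EmptyCropError("crop keeps no faces")
    sub = mesh.submesh([np.flatnonzero(keep_f)], append=True)
    return validate_mesh(sub)


# ---------------------------------------------------------------------------
# boundary loops

def find_boundary_loops(mesh: trimesh.Trimesh) -> list:
    """Ordered vertex-index cycles along open edges.

    An edge belongs to the boundary iff it is incident to exactly one face.
    Boundary edges are chained into closed cycles; a watertight mesh yields
    an empty list.  Boundary vertices touched by more than two boundary
    edges (non-manifold junctions) raise.
    """
    edges = np.sort(mesh.edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []

    neighbours: dict = {}
    for a, b in boundary:
        neighbours.setdefault(int(a), []).append(int(b))
        neighbours.setdefault(int(b), []).append(int(a))
    for v, nb in neighbours.items():
        if len(nb) != 2:
            raise NonManifoldBoundaryError(
                f"boundary vertex {v} has {len(nb)} boundary edges (expected 2)"
            )

    loops = []
    visited = set()
    for start in sorted(neighbours):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxt = [v for v in neighbours[cur] if v != prev]
            nxt = nxt[0] if nxt else neighbours[cur][0]
            if nxt == start:
                break
            if nxt in visited:
                raise NonManifoldBoundaryError("boundary edges do not form simple cycles")
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        if len(loop) < 3:
            raise NonManifoldBoundaryError("boundary cycle shorter than 3 vertices")
        loops.append(loop)
    return loops


# ---------------------------------------------------------------------------
# cap triangulation (ear clipping)

def _polygon_area2(pts2: np.ndarray) -> float:
    x, y = pts2[:, 0], pts2[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def triangulate_polygon_2d(pts2: np.ndarray) -> np.ndarray:
    """Ear-clip a simple 2D polygon into triangles (indices into ``pts2``).

    Deterministic, O(n^2); raises :class:`SolidifyError` on self-intersecting
    input.  Holes are not supported (callers crop so rims are simple loops).
    """
    pts2 = np.asarray(pts2, float)
    n = len(pts2)
    if n < 3:
        raise SolidifyError("polygon needs at least 3 vertices")
    poly = Polygon(pts2)
    if not poly.is_valid or poly.area <= 0:
        raise SolidifyError("rim projects to a self-intersecting or degenerate polygon")

    idx = list(range(n))
    if _polygon_area2(pts2) < 0:  # enforce CCW
        idx = idx[::-1]
    tris = []
    guard = 0
    eps = 1e-12 * max(poly.area, 1.0)
    while len(idx) > 3:
        guard += 1
        if guard > 2 * n * n:
            raise SolidifyError("ear clipping failed to converge (degenerate rim)")
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            a, b, c = pts2[i0], pts2[i1], pts2[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= eps:  # reflex or degenerate corner
                continue
            # no other active vertex strictly inside the candidate ear
            others = [j for j in idx if j not in (i0, i1, i2)]
            P = pts2[others]
            d0 = (b[0] - a[0]) * (P[:, 1] - a[1]) - (b[1] - a[1]) * (P[:, 0] - a[0])
            d1 = (c[0] - b[0]) * (P[:, 1] - b[1]) - (c[1] - b[1]) * (P[:, 0] - b[0])
            d2 = (a[0] - c[0]) * (P[:, 1] - c[1]) - (a[1] - c[1]) * (P[:, 0] - c[0])
            if ((d0 > -eps) & (d1 > -eps) & (d2 > -eps)).any():
                continue
            tris.append((i0, i1, i2))
            del idx[k]
            clipped = True
            break
        if not clipped:
            raise SolidifyError("no ear found; rim polygon is degenerate")
    tris.append((idx[0], idx[1], idx[2]))
    return np.asarray(tris, dtype=int)


def _closing_direction(mesh: trimesh.Trimesh) -> np.ndarray:
    """Negated area-weighted mean face normal: away from the scanned surface."""
    normals = mesh.face_normals
    areas = mesh.area_faces
    mean = (normals * areas[:, None]).sum(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        raise SolidifyError("patch has no well-defined average normal")
    return -mean / norm


# ---------------------------------------------------------------------------
# closure

def close_to_solid(
    mesh: trimesh.Trimesh,
    depth: float = 5.0,
    direction=None,
    mode: str = "plane",
) -> trimesh.Trimesh:
    """Close an open surface patch into a watertight solid.

    ``direction`` is the closing direction (defaults to the negated
    area-weighted average patch normal); ``depth`` (mm, > 0) is how far the
    rim is extruded along it.  The patch must have exactly one open boundary
    loop; already-closed extra components (e.g. free-floating scan fragments,
    which are watertight blobs) are passed through untouched.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if mode not in ("plane", "translate"):
        raise ValueError("mode must be 'plane' or 'translate'")

    loops = find_boundary_loops(mesh)
    if len(loops) == 0:
        raise MultiLoopError("mesh is already closed; nothing to solidify")
    if len(loops) > 1:
        raise MultiLoopError(
            f"{len(loops)} boundary loops found; crop tighter so only one remains"
        )
    loop = loops[0]

    if direction is None:
        d = _closing_direction(mesh)
    else:
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)

    verts = np.asarray(mesh.vertices, float)
    rim = verts[loop]
    if mode == "plane":
        # extrude each rim vertex onto the plane `depth` below the lowest rim point
        h = rim @ d
        plane_h = h.max() + depth  # d points away from surface; larger h = deeper
        displaced = rim + np.outer(plane_h - h, d)
    else:
        displaced = rim + depth * d

    # 2D frame orthogonal to the closing direction for cap triangulation
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    pts2 = np.column_stack([displaced @ u, displaced @ v])
    cap_local = triangulate_polygon_2d(pts2)

    nv = len(verts)
    new_verts = np.vstack([verts, displaced])
    loop_arr = np.asarray(loop)
    m = len(loop_arr)
    nxt = np.roll(np.arange(m), -1)
    # side walls: quad (rim_i, rim_{i+1}, disp_{i+1}, disp_i) as two triangles
    walls = []
    for i in range(m):
        a, b = loop_arr[i], loop_arr[nxt[i]]
        a2, b2 = nv + i, nv + nxt[i]
        walls.append((a, b, b2))
        walls.append((a, b2, a2))
    cap = cap_local + nv

    faces = np.vstack([mesh.faces, np.asarray(walls), cap])
    solid = validate_mesh((new_verts, faces))
    if not is_watertight(solid):
        raise SolidifyError("closure did not produce a watertight solid")
    if solid.volume <= 0:
        # validate_mesh orients outward for watertight meshes; a non-positive
        # volume here means a genuinely degenerate closure
        raise SolidifyError("closed solid has non-positive volume")
    return solid
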