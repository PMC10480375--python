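"""Reading, writing, validation and description of triangulated surface scans.

Intraoral scanners export STL, a triangle-soup format with no topology, units
or metadata.  This module turns such files into validated, topologically
connected :class:`trimesh.Trimesh` objects (millimetre units are assumed
throughout the package; volumes are converted to cm^3 only at reporting).

Validation performs, in order:

* merge duplicate vertices within a tolerance (STL repeats every vertex per
  facet; merging is what makes boundary-loop detection possible downstream),
* drop faces that repeat a vertex index or have (near) zero area,
* drop duplicate faces,
* recompute normals from winding order, making winding globally consistent
  and, for watertight meshes, outward-oriented.  Stored STL normals are
  ignored: scanner exports carry unreliable normals, and the signed-volume
  arithmetic used later depends on consistent orientation.

Landmarks for coarse alignment travel in a 3-row CSV sidecar
(``label,x,y,z``), per-vertex registration weights in a ``vertex_index,weight``
CSV, since STL has no annotation channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .errors import EmptyMeshError, DegenerateLandmarksError, MeshIOError, SchemaError

DEFAULT_MERGE_TOL = 1e-6  # mm; scanner export precision is unspecified, so configurable


@dataclass(frozen=True)
class LandmarkSet:
    """Exactly three labelled points (mm) in a fixed correspondence order."""

    labels: tuple
    points: np.ndarray  # (3, 3) float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (3, 3):
            raise DegenerateLandmarksError(
                f"landmark set must be exactly 3 points, got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)
        # non-collinearity: triangle spanned by the three points has real area
        area = 0.5 * np.linalg.norm(
            np.cross(pts[1] - pts[0], pts[2] - pts[0])
        )
        scale = max(np.ptp(pts), 1.0)
        if area < 1e-9 * scale**2:
            raise DegenerateLandmarksError(
                f"landmarks are collinear (area {area:.3g} mm^2)"
            )


@dataclass
class MeshSummary:
    n_vertices: int
    n_faces: int
    bounds_min: np.ndarray
    bounds_max: np.ndarray
    watertight: bool
    n_components: int
    n_boundary_edges: int

    def as_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_faces": self.n_faces,
            "bounds_min": [float(v) for v in self.bounds_min],
            "bounds_max": [float(v) for v in self.bounds_max],
            "watertight": bool(self.watertight),
            "n_components": self.n_components,
            "n_boundary_edges": self.n_boundary_edges,
        }


def _merge_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float):
    """Unify vertices whose coordinates agree within ``tol`` (grid snap)."""
    if len(vertices) == 0:
        return vertices, faces
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def validate_mesh(
    mesh: trimesh.Trimesh | tuple,
    merge_tol: float = DEFAULT_MERGE_TOL,
    area_tol: float = 1e-12,
) -> trimesh.Trimesh:
    """Return a cleaned, consistently wound copy of ``mesh``.

    Accepts a Trimesh or a ``(vertices, faces)`` pair.  Raises
    :class:`EmptyMeshError` if nothing survives cleaning.
    """
    if isinstance(mesh, trimesh.Trimesh):
        vertices, faces = np.asarray(mesh.vertices, float), np.asarray(mesh.faces)
    else:
        vertices, faces = (np.asarray(mesh[0], float), np.asarray(mesh[1], int))
    if len(faces) == 0:
        raise EmptyMeshError("mesh has no faces")

    vertices, faces = _merge_vertices(vertices, faces, merge_tol)

    # faces repeating a vertex index collapse to an edge or point
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    faces = faces[ok]

    if len(faces):
        # duplicate faces: same vertex set regardless of rotation/winding
        key = np.sort(faces, axis=1)
        _, keep = np.unique(key, axis=0, return_index=True)
        faces = faces[np.sort(keep)]

    if len(faces):
        tri = vertices[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        degen = areas <= area_tol
        if degen.any():
            # a zero-area face is dropped only if one of its edges is
            # unshared: slivers whose every edge pairs with a neighbour keep
            # an otherwise closed surface closed (e.g. cap triangulations
            # collapsed by float32 STL rounding) and contribute no volume
            edges = np.sort(
                faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            _, inverse, counts = np.unique(
                edges, axis=0, return_inverse=True, return_counts=True
            )
            dangling = (counts[inverse].reshape(-1, 3) < 2).any(axis=1)
            faces = faces[~(degen & dangling)]

    if len(faces) == 0:
        raise EmptyMeshError("mesh is empty after validation")

    out = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    out.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(out)  # consistent winding; outward if watertight
    return out


def read_stl(path, merge_tol: float = DEFAULT_MERGE_TOL) -> trimesh.Trimesh:
    """Read a binary or ASCII STL file (auto-detected) and validate it."""
    try:
        raw = trimesh.load(str(path), file_type="stl", process=False)
    except EmptyMeshError:
        raise
    except Exception as exc:  # trimesh raises a zoo of types here
        raise MeshIOError(f"cannot read STL {path!r}: {exc}") from exc
    if isinstance(raw, trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path!r} contains no triangles")
        raw = trimesh.util.concatenate(geoms)
    if raw.faces is None or len(raw.faces) == 0:
        raise EmptyMeshError(f"{path!r} contains no triangles")
    return validate_mesh(raw, merge_tol=merge_tol)


def write_stl(mesh: trimesh.Trimesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL; ``dialect`` is ``"binary"`` or ``"ascii"``."""
    if mesh is None or len(mesh.faces) == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    try:
        data = trimesh.exchange.stl.export_stl(mesh) if dialect == "binary" else \
            trimesh.exchange.stl.export_stl_ascii(mesh)
        mode = "wb" if dialect == "binary" else "w"
        with open(path, mode) as fh:
            fh.write(data)
    except (OSError, IOError) as exc:
        raise MeshIOError(f"cannot write STL {path!r}: {exc}") from exc


def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of undirected edges incident to exactly one face."""
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


def is_watertight(mesh: trimesh.Trimesh) -> bool:
    """Every undirected edge shared by exactly two faces."""
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(len(counts) and (counts == 2).all())


def connected_components(mesh: trimesh.Trimesh) -> list:
    """Split into face-adjacency connected components (open ones included)."""
    return list(mesh.split(only_watertight=False, repair=False))


def mesh_summary(mesh: trimesh.Trimesh) -> MeshSummary:
    """Describe a validated mesh: counts, bounds, watertightness, components."""
    if len(mesh.faces) == 0:
        raise EmptyMeshError("cannot summarise an empty mesh")
    return MeshSummary(
        n_vertices=len(mesh.vertices),
        n_faces=len(mesh.faces),
        bounds_min=mesh.bounds[0].copy(),
        bounds_max=mesh.bounds[1].copy(),
        watertight=is_watertight(mesh),
        n_components=len(connected_components(mesh)),
        n_boundary_edges=boundary_edge_count(mesh),
    )


def read_landmarks(path) -> LandmarkSet:
    """Read a ``label,x,y,z`` CSV sidecar with exactly three rows (mm)."""
    try:
        df = pd.read_csv(path)
    except (OSError, IOError) as exc:
        raise MeshIOError(f"cannot read landmarks {path!r}: {exc}") from exc
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise SchemaError(f"landmark file needs columns {sorted(required)}")
    if len(df) != 3:
        raise SchemaError(f"landmark file must have exactly 3 rows, got {len(df)}")
    return LandmarkSet(
        labels=tuple(df["label"].astype(str)),
        points=df[["x", "y", "z"]].to_numpy(float),
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    pd.DataFrame(
        {
            "label": list(landmarks.labels),
            "x": landmarks.points[:, 0],
            "y": landmarks.points[:, 1],
            "z": landmarks.points[:, 2],
        }
    ).to_csv(path, index=False)


def read_weights(path, n_vertices: int) -> np.ndarray:
    """Read a ``vertex_index,weight`` CSV into a dense per-vertex array.

    Unlisted vertices get weight 1.0 (i.e. the file may list only the
    down-weighted region, as a painted weight map would).
    """
    df = pd.read_csv(path)
    if not {"vertex_index", "weight"}.issubset(df.columns):
        raise SchemaError("weight file needs columns vertex_index,weight")
    weights = np.ones(n_vertices, dtype=float)
    idx = df["vertex_index"].to_numpy(int)
    if len(idx) and (idx.min() < 0 or idx.max() >= n_vertices):
        raise SchemaError("weight file indexes a vertex outside the mesh")
    weights[idx] = df["weight"].to_numpy(float)
    return weights


def write_weights(weights: np.ndarray, path) -> None:
    pd.DataFrame(
        {"vertex_index": np.arange(len(weights)), "weight": weights}
    ).to_csv(path, index=False)
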