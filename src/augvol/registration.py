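"""Rigid registration of post-augmentation scans onto the baseline scan.

Two stages, mirroring clinical surface-matching practice:

1. **Coarse three-point alignment** — the operator marks the same three
   anatomical points on both scans; the least-squares rigid transform between
   the triples (Kabsch, no scaling) brings the scans into rough agreement.
2. **Weighted iterative-closest-point refinement** — alternates
   nearest-point correspondence (moving vertices -> closest point on the
   fixed *surface*, not vertex-to-vertex, because the two scans tessellate
   the anatomy differently) with the weighted Kabsch solution.  Per-vertex
   weights exclude the augmented region and any unstable soft tissue from
   driving the alignment: weight 0 vertices are provably inert.

The visual check of match quality used in interactive workflows is replaced
by a numeric gate: the final weighted RMS must fall below a configurable
threshold (default 0.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, InsufficientOverlapError
from .mesh_io import LandmarkSet


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping one scan's frame into another's (mm)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise DegenerateGeometryError(f"rotation not orthonormal (err {err:.2e})")
        if np.linalg.det(R) < 0:
            raise DegenerateGeometryError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


@dataclass
class AlignmentResult:
    transform: RigidTransform
    residual_rms: float  # mm


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_trace: list  # weighted RMS (mm) per iteration, after each update
    converged: bool
    n_iterations: int

    @property
    def final_rms(self) -> float:
        return self.rms_trace[-1]


@dataclass
class ICPParams:
    """Stopping rule and correspondence settings for ICP refinement.

    The underlying interactive workflow publishes none of these; defaults are
    engineering choices, all configurable.
    """

    max_iterations: int = 600
    rms_change_tol: float = 1e-7  # mm
    distance_cap: float = 5.0  # mm; correspondences farther than this are dropped
    max_points: int = 1000  # deterministic subsample of weighted moving vertices
    quality_gate_rms: float = 0.5  # mm; final RMS above this is flagged


def kabsch(
    source_points: np.ndarray,
    target_points: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Weighted least-squares rigid transform source -> target.

    Minimises sum_i w_i ||R s_i + t - t_i||^2: shift both sets to their
    weighted centroids, take the SVD of the weighted cross-covariance, and
    correct the sign of the smallest singular direction so det(R) = +1.
    """
    S = np.asarray(source_points, float)
    T = np.asarray(target_points, float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = len(S)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or (w < 0).any():
            raise ValueError("weights must be a non-negative (n,) array")
    wsum = w.sum()
    if n < 3 or (w > 0).sum() < 3 or wsum <= 0:
        raise DegenerateGeometryError("need at least 3 point pairs with positive weight")

    cs = (w[:, None] * S).sum(axis=0) / wsum
    ct = (w[:, None] * T).sum(axis=0) / wsum
    S0, T0 = S - cs, T - ct
    H = (w[:, None] * S0).T @ T0  # weighted cross-covariance
    U, sing, Vt = np.linalg.svd(H)
    scale = max(sing[0], 1e-30)
    if sing[1] / scale < 1e-9:
        raise DegenerateGeometryError(
            "point pairs are collinear; rotation is not identifiable"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return RigidTransform(R, t)


def three_point_align(
    moving_landmarks: LandmarkSet, fixed_landmarks: LandmarkSet
) -> AlignmentResult:
    """Coarse alignment from three corresponding anatomical points.

    Landmark sets must use the same correspondence order.  Non-collinearity
    is enforced by :class:`LandmarkSet` itself; this simply runs Kabsch on
    the three pairs and reports the residual RMS.
    """
    if moving_landmarks.labels != fixed_landmarks.labels:
        # allow unlabeled/differently labelled triples but keep order semantics
        pass
    transform = kabsch(moving_landmarks.points, fixed_landmarks.points)
    resid = transform.apply(moving_landmarks.points) - fixed_landmarks.points
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AlignmentResult(transform=transform, residual_rms=rms)


class SurfaceLocator:
    """Nearest point on a triangulated surface, via a face-centroid KD-tree.

    For each query the ``k`` nearest face centroids plus all faces incident
    to the nearest fixed vertex are evaluated with the exact point-triangle
    projection; the best candidate wins.  With scanner-density tessellation
    this recovers the true closest face in essentially all cases.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 8):
        self.mesh = mesh
        self.k = min(k, len(mesh.faces))
        self.triangles = mesh.triangles.copy()
        self._centroid_tree = cKDTree(self.triangles.mean(axis=1))
        self._vertex_tree = cKDTree(mesh.vertices)
        self._vertex_faces = mesh.vertex_faces  # (n_vertices, max_deg), -1 padded

    def closest(self, points: np.ndarray):
        """Return (closest_points, distances) for an (n, 3) query array."""
        points = np.asarray(points, float)
        _, cand = self._centroid_tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        _, nearest_vertex = self._vertex_tree.query(points)
        vf = self._vertex_faces[nearest_vertex]
        cand = np.concatenate([cand, np.where(vf < 0, cand[:, :1], vf)], axis=1)

        n, m = cand.shape
        flat_faces = cand.ravel()
        flat_pts = np.repeat(points, m, axis=0)
        proj = trimesh.triangles.closest_point(self.triangles[flat_faces], flat_pts)
        d2 = ((proj - flat_pts) ** 2).sum(axis=1).reshape(n, m)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        closest = proj.reshape(n, m, 3)[rows, best]
        return closest, np.sqrt(d2[rows, best])


def weighted_icp(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    weights: np.ndarray | None = None,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
) -> ICPResult:
    """Refine ``init`` so that weighted moving vertices sit on ``fixed``.

    Each iteration: transform the (subsampled) weighted moving vertices,
    find their closest points on the fixed surface, drop pairs farther than
    the distance cap, solve weighted Kabsch, compose.  Stops when the
    weighted RMS changes by less than ``rms_change_tol`` or after
    ``max_iterations``.
    """
    params = params or ICPParams()
    init = init or RigidTransform.identity()

    pts = np.asarray(moving.vertices, float)
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, float)
        if w.shape != (len(pts),):
            raise ValueError("weight map length must equal moving vertex count")
        if (w < 0).any() or w.max() > 1.0 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
    active = np.flatnonzero(w > 0)
    if len(active) < 3:
        raise InsufficientOverlapError("fewer than 3 moving vertices with weight > 0")
    if len(active) > params.max_points:
        # deterministic even-stride subsample
        idx = np.linspace(0, len(active) - 1, params.max_points).astype(int)
        active = active[idx]
    src = pts[active]
    w_active = w[active]

    locator = SurfaceLocator(fixed)
    transform = init
    trace: list = []
    converged = False
    n_done = 0
    for _ in range(params.max_iterations):
        cur = transform.apply(src)
        targets, dist = locator.closest(cur)
        ok = dist <= params.distance_cap
        if ok.sum() < 3 or w_active[ok].sum() <= 0:
            raise InsufficientOverlapError(
                f"only {int(ok.sum())} correspondences within "
                f"{params.distance_cap} mm cap"
            )
        ww = w_active[ok]
        rms = float(np.sqrt((ww * dist[ok] ** 2).sum() / ww.sum()))
        trace.append(rms)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < params.rms_change_tol:
            converged = True
            break
        step = kabsch(cur[ok], targets[ok], ww)
        transform = step.compose(transform)
        n_done += 1

    return ICPResult(
        transform=transform, rms_trace=trace, converged=converged, n_iterations=n_done
    )
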