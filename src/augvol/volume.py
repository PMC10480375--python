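"""Enclosed-volume computation and the slice-summation oracle.

The primary measurement is the divergence-theorem (signed tetrahedron)
volume of a watertight mesh: V = (1/6)|Σ_f v0 · (v1 × v2)|, evaluated per
connected component after orientation normalisation and summed, so a stray
inverted component can never cancel volume out of a noisy Boolean result.

The slice oracle mirrors the manual gold-standard workflow — annotate the
cross-section on parallel slices and sum area × thickness — and exists as
an independent cross-check: agreement between the two is the geometric
form of the manual/semiautomatic method equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import EmptyMeshError, OpenMeshError
from .mesh_io import connected_components, is_watertight
from .voxel import signed_volume

_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


@dataclass
class VolumeResult:
    """Measured volume with provenance (mm assumed; cm^3 = mm^3 / 1000)."""

    volume_mm3: float
    n_components: int
    method: str  # "divergence" | "slice"
    parameters: dict = field(default_factory=dict)

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def as_dict(self) -> dict:
        return {
            "volume_cm3": self.volume_cm3,
            "volume_mm3": self.volume_mm3,
            "n_components": self.n_components,
            "method": self.method,
            "parameters": self.parameters,
        }


def _oriented_components(mesh: trimesh.Trimesh) -> list:
    if mesh is None or len(mesh.faces) == 0:
        raise EmptyMeshError("volume of an empty mesh is undefined")
    comps = connected_components(mesh)
    for comp in comps:
        if not is_watertight(comp):
            raise OpenMeshError(
                "mesh component is not watertight; enclosed volume is undefined"
            )
        if not comp.is_winding_consistent:
            trimesh.repair.fix_normals(comp)
    return comps


def enclosed_volume(mesh: trimesh.Trimesh) -> VolumeResult:
    """Divergence-theorem volume of a watertight (multi-component) mesh."""
    comps = _oriented_components(mesh)
    total = sum(abs(signed_volume(c)) for c in comps)
    return VolumeResult(
        volume_mm3=total, n_components=len(comps), method="divergence", parameters={}
    )


def _section_area(mesh: trimesh.Trimesh, origin, normal) -> float:
    sec = mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return 0.0
    planar, _ = sec.to_2D()
    loops = [lp for lp in planar.discrete if len(lp) >= 3]
    if not loops:
        return 0.0
    # even-odd rule by nesting depth: a loop inside an odd number of other
    # loops is a hole boundary and subtracts its area
    from shapely.geometry import Point, Polygon

    polys = [Polygon(lp).buffer(0) for lp in loops]
    total = 0.0
    for i, (lp, poly) in enumerate(zip(loops, polys)):
        x, y = lp[:, 0], lp[:, 1]
        area = abs(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
        pt = Point(*lp[0])
        depth = sum(
            1
            for j, other in enumerate(polys)
            if j != i and other.contains(pt)
        )
        total += area if depth % 2 == 0 else -area
    return float(total)


def slice_volume_oracle(
    mesh: trimesh.Trimesh, slice_thickness: float = 0.25, axis: str = "auto"
) -> VolumeResult:
    """Riemann-sum volume from parallel cross-sections (mid-slice rule).

    Planes are placed at slice mid-points along ``axis`` (``"x"|"y"|"z"``,
    or ``"auto"`` = the longest bounding-box axis); each cross-section's
    even-odd polygon area is multiplied by the slice thickness and summed.
    Converges to the divergence-theorem volume as the thickness shrinks.
    """
    if slice_thickness <= 0:
        raise ValueError("slice thickness must be positive")
    comps = _oriented_components(mesh)  # also validates watertightness
    if axis == "auto":
        axis = "xyz"[int(np.argmax(mesh.extents))]
    direction = _AXES[axis]
    k = int(np.argmax(direction))
    lo, hi = mesh.bounds[0][k], mesh.bounds[1][k]
    n_slices = max(int(np.ceil((hi - lo) / slice_thickness - 1e-9)), 1)
    total = 0.0
    for i in range(n_slices):
        coord = lo + (i + 0.5) * slice_thickness
        origin = np.zeros(3)
        origin[k] = coord
        area = sum(_section_area(c, origin, direction) for c in comps)
        total += area * slice_thickness
    return VolumeResult(
        volume_mm3=total,
        n_components=len(comps),
        method="slice",
        parameters={"slice_thickness_mm": slice_thickness, "axis": axis},
    )
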