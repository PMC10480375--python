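"""Synthetic scan-pair generator with analytically known added volume.

No public scan data exists for ridge-augmentation volumetry, so every stage
of the pipeline is exercised on phantoms: a ridge-shaped open baseline
surface (extruded rounded profile with smooth seeded undulations,
tessellated at scanner-like density) plus one of three augmentation
geometries layered on top of it, mirroring the grafting techniques used
clinically:

* ``B``  — solid cortical block: rounded-rectangular plateau (a hemispheric
  variant is available for closed-form ground truth),
* ``S1`` — split block: a thin plate spanning a wider footprint over
  particulate filler, with granular surface texture,
* ``S2`` — shell: a curved (cosine-arched) shell over particulate filler.

The augmented surface is the baseline height field plus a technique-
specific added-height field ``d(x, y)``; the ground-truth added volume is
the 2D integral of ``d`` over the footprint, evaluated on a fine quadrature
grid of the *analytic* field (for the hemisphere, in closed form) — i.e. by
machinery entirely disjoint from the mesh-measurement pipeline, so
agreement is evidence rather than tautology.  The added-height field is
rescaled so the truth hits a per-technique target volume, with defaults at
the scales typical of these grafts (B ≈ 0.35, S1 ≈ 0.76, S2 ≈ 0.82 cm^3).

The augmented scan is emitted in a perturbed frame under a known random
rigid pose (so registration is genuinely exercised), with its own i.i.d.
vertex noise along local normals, optional free-floating spherical
fragments (scan debris), per-scan landmark triples, and a per-vertex
weight map that masks the augmented region out of the ICP.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from scipy.spatial import cKDTree

from .errors import MarginError
from .mesh_io import (
    LandmarkSet,
    read_stl,
    validate_mesh,
    write_landmarks,
    write_stl,
    write_weights,
)
from .registration import RigidTransform

TECHNIQUES = ("B", "S1", "S2")
#: per-technique target added volume, cm^3 (typical for these grafts)
DEFAULT_TARGETS_CM3 = {"B": 0.35, "S1": 0.76, "S2": 0.82}
DEFAULT_TARGET_SDS_CM3 = {"B": 0.085, "S1": 0.15, "S2": 0.17}


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic specimen."""

    technique: str = "B"
    seed: int = 0
    # seed of the baseline anatomy; several techniques measured on the same
    # specimen share it (defaults to ``seed``)
    baseline_seed: int | None = None
    # ridge geometry (mm)
    ridge_width: float = 30.0  # x extent (bucco-lingual)
    ridge_length: float = 40.0  # y extent (mesio-distal)
    crest_height: float = 12.0
    crest_halfwidth: float = 5.0
    crest_slope: float = 2.0
    undulation_amp: float = 0.15
    # tessellation / noise
    grid_step: float = 0.25  # scanner-like edge length
    noise_sd: float = 0.0  # mm, along vertex normals
    landmark_noise_sd: float = 0.05
    # augmentation
    target_volume_cm3: float | None = None  # None -> technique default
    bump_shape: str = "default"  # B only: "default" | "hemisphere"
    hemisphere_radius: float = 4.3
    center_y: float = 3.0
    n_floating_fragments: int = 0
    fragment_radius: float = 0.5
    # pose perturbation of the augmented scan
    pose_rotation_deg: float = 5.0
    pose_translation_mm: float = 3.0
    # set True only to construct the margin-failure case deliberately
    allow_margin_violation: bool = False

    def __post_init__(self):
        if self.technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if self.noise_sd < 0 or self.grid_step <= 0:
            raise ValueError("noise_sd must be >= 0 and grid_step > 0")

    @property
    def anatomy_seed(self) -> int:
        return self.seed if self.baseline_seed is None else self.baseline_seed

    @property
    def target_mm3(self) -> float:
        t = self.target_volume_cm3
        if t is None:
            t = DEFAULT_TARGETS_CM3[self.technique]
        return t * 1000.0


@dataclass
class PhantomTruth:
    ground_truth_volume_mm3: float
    applied_pose: RigidTransform  # maps baseline frame -> augmented-scan frame
    roi_min: np.ndarray  # outer ROI box, baseline frame
    roi_max: np.ndarray


@dataclass
class PhantomPair:
    spec: PhantomSpec
    baseline: trimesh.Trimesh
    baseline_landmarks: LandmarkSet
    augmented: trimesh.Trimesh  # in the perturbed scan frame
    augmented_landmarks: LandmarkSet
    weights: np.ndarray  # per augmented-scan vertex, 0 on the graft
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# analytic height fields

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _undulation_params(spec: PhantomSpec):
    rng = np.random.default_rng(np.random.SeedSequence([spec.anatomy_seed, 11]))
    n = 6
    return (
        rng.uniform(0.3, 1.0, n) * spec.undulation_amp,  # amplitudes
        rng.uniform(2 * np.pi / 25.0, 2 * np.pi / 6.0, (n, 2)),  # wave vectors
        rng.uniform(0, 2 * np.pi, n),  # phases
    )


def base_height(spec: PhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Baseline ridge surface z(x, y): logistic crest profile + undulation."""
    z = spec.crest_height / (
        1.0 + np.exp((np.abs(x) - spec.crest_halfwidth) / spec.crest_slope)
    )
    z = z + 0.6 * np.cos(2 * np.pi * y / spec.ridge_length)
    amps, waves, phases = _undulation_params(spec)
    for a, (kx, ky), ph in zip(amps, waves, phases):
        z = z + a * np.sin(kx * x + ky * y + ph)
    return z


@dataclass
class _AugField:
    """Analytic added-height field d(x, y) with its footprint box."""

    fn: callable
    foot_min: np.ndarray  # (2,) xy
    foot_max: np.ndarray
    analytic_integral: float | None = None  # mm^3, if known in closed form


def _texture(spec: PhantomSpec, fx, fy, n_bumps: int = 25, amp: float = 0.35):
    """Granular particulate texture: seeded Gaussian bumps inside a box."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    cx = rng.uniform(fx[0], fx[1], n_bumps)
    cy = rng.uniform(fy[0], fy[1], n_bumps)
    sg = rng.uniform(0.6, 1.2, n_bumps)
    aa = rng.uniform(0.3, 1.0, n_bumps) * amp

    def tex(x, y):
        out = np.zeros(np.broadcast(x, y).shape)
        for a, ux, uy, s in zip(aa, cx, cy, sg):
            out += a * np.exp(-(((x - ux) ** 2 + (y - uy) ** 2) / (2 * s * s)))
        return out

    return tex


def aug_field(spec: PhantomSpec) -> _AugField:
    """Unit-scale added-height field for the spec's technique."""
    y0 = spec.center_y
    if spec.technique == "B" and spec.bump_shape == "hemisphere":
        r = spec.hemisphere_radius

        def fn(x, y):
            rho2 = x**2 + (y - y0) ** 2
            return np.sqrt(np.maximum(r * r - rho2, 0.0))

        return _AugField(
            fn=fn,
            foot_min=np.array([-r, y0 - r]),
            foot_max=np.array([r, y0 + r]),
            analytic_integral=2.0 / 3.0 * np.pi * r**3,
        )

    if spec.technique == "B":
        ax, ay, edge, h = 5.5, 5.5, 1.5, 3.2

        def fn(x, y):
            ex = _smoothstep((ax - np.abs(x)) / edge)
            ey = _smoothstep((ay - np.abs(y - y0)) / edge)
            return h * ex * ey

        return _AugField(
            fn=fn,
            foot_min=np.array([-ax, y0 - ay]),
            foot_max=np.array([ax, y0 + ay]),
        )

    if spec.technique == "S1":
        # thin plate fixed ~5 mm from the crest over particulate filler:
        # wide flat-topped slab with granular texture
        ax, ay, edge, h = 7.0, 9.0, 1.2, 4.5
        tex = _texture(spec, (-ax, ax), (y0 - ay, y0 + ay))

        def fn(x, y):
            ex = _smoothstep((ax - np.abs(x)) / edge)
            ey = _smoothstep((ay - np.abs(y - y0)) / edge)
            return (h + tex(x, y)) * ex * ey

        return _AugField(
            fn=fn,
            foot_min=np.array([-ax, y0 - ay]),
            foot_max=np.array([ax, y0 + ay]),
        )

    # S2: curved shell (cosine arch across x) over particulate filler
    ax, ay, edge, h = 7.5, 9.0, 1.2, 5.0
    tex = _texture(spec, (-ax, ax), (y0 - ay, y0 + ay), amp=0.3)

    def fn(x, y):
        arch = np.cos(0.5 * np.pi * np.clip(x / ax, -1, 1))
        ey = _smoothstep((ay - np.abs(y - y0)) / edge)
        ex = _smoothstep((ax - np.abs(x)) / edge)
        return (h * arch + tex(x, y) * ex) * ey

    return _AugField(
        fn=fn,
        foot_min=np.array([-ax, y0 - ay]),
        foot_max=np.array([ax, y0 + ay]),
    )


def _truth_integral(fld: _AugField, quad_step: float = 0.02) -> float:
    """Fine midpoint-rule integral of the analytic field (mm^3)."""
    if fld.analytic_integral is not None:
        return fld.analytic_integral
    lo, hi = fld.foot_min, fld.foot_max
    nx = int(np.ceil((hi[0] - lo[0]) / quad_step))
    ny = int(np.ceil((hi[1] - lo[1]) / quad_step))
    xs = lo[0] + (np.arange(nx) + 0.5) * (hi[0] - lo[0]) / nx
    ys = lo[1] + (np.arange(ny) + 0.5) * (hi[1] - lo[1]) / ny
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cell = ((hi[0] - lo[0]) / nx) * ((hi[1] - lo[1]) / ny)
    return float(fld.fn(X, Y).sum() * cell)


# ---------------------------------------------------------------------------
# mesh construction

def _grid_mesh(spec: PhantomSpec, height_fn) -> trimesh.Trimesh:
    hx, hy = spec.ridge_width / 2.0, spec.ridge_length / 2.0
    nx = int(round(spec.ridge_width / spec.grid_step)) + 1
    ny = int(round(spec.ridge_length / spec.grid_step)) + 1
    xs = np.linspace(-hx, hx, nx)
    ys = np.linspace(-hy, hy, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = height_fn(X, Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
    faces = np.vstack([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _apply_noise(mesh: trimesh.Trimesh, sd: float, seed_key) -> trimesh.Trimesh:
    if sd <= 0:
        return mesh
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    disp = rng.normal(0.0, sd, len(mesh.vertices))
    out = mesh.copy()
    out.vertices = out.vertices + disp[:, None] * mesh.vertex_normals
    return out


def _landmark_points(spec: PhantomSpec) -> np.ndarray:
    hx, hy = spec.ridge_width / 2.0, spec.ridge_length / 2.0
    xy = np.array(
        [
            [-hx + 4.0, -hy + 4.0],
            [hx - 4.0, -hy + 4.0],
            [0.0, -hy + 9.0],
        ]
    )
    z = base_height(spec, xy[:, 0], xy[:, 1])
    return np.column_stack([xy, z])


def _random_pose(spec: PhantomSpec) -> RigidTransform:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(spec.pose_rotation_deg) * rng.uniform(0.5, 1.0)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-1.0, 1.0, 3) * spec.pose_translation_mm
    return RigidTransform(R, t)


def generate_baseline(spec: PhantomSpec):
    """Open ridge surface + landmark triple, in the baseline frame."""
    surf = _grid_mesh(spec, lambda x, y: base_height(spec, x, y))
    surf = _apply_noise(surf, spec.noise_sd, [spec.anatomy_seed, 19])
    landmarks = LandmarkSet(labels=("L1", "L2", "L3"), points=_landmark_points(spec))
    return validate_mesh(surf), landmarks


def generate_augmented(spec: PhantomSpec):
    """Augmented scan (perturbed frame), weight map, landmarks and truth.

    Raises :class:`MarginError` when the augmentation footprint sits too
    close to the scan border for the downstream ROI to fit — the analogue
    of a scan whose margin clips the augmented region.
    """
    fld = aug_field(spec)
    hx, hy = spec.ridge_width / 2.0, spec.ridge_length / 2.0
    safety = 6.0  # mm clearance for ROI pad + cropped wall + placement jitter
    lo, hi = fld.foot_min, fld.foot_max
    if (
        lo[0] < -hx + safety
        or hi[0] > hx - safety
        or lo[1] < -hy + safety
        or hi[1] > hy - safety
    ):
        if not spec.allow_margin_violation:
            raise MarginError(
                "augmentation footprint is too close to the scan margin "
                f"(footprint {lo}..{hi}, scan ±[{hx}, {hy}], "
                f"safety {safety} mm)"
            )

    base_I = _truth_integral(fld)
    if spec.technique == "B" and spec.bump_shape == "hemisphere":
        scale = 1.0  # closed-form truth; no rescaling
        truth_mm3 = fld.analytic_integral
    else:
        scale = spec.target_mm3 / base_I
        truth_mm3 = spec.target_mm3

    def aug_height(x, y):
        return base_height(spec, x, y) + scale * fld.fn(x, y)

    surf = _grid_mesh(spec, aug_height)

    # weight map: zero on the dilated footprint, ramp to one over 2 mm
    V = surf.vertices
    dil = 2.0
    dx = np.maximum(np.maximum(lo[0] - dil - V[:, 0], V[:, 0] - hi[0] - dil), 0.0)
    dy = np.maximum(np.maximum(lo[1] - dil - V[:, 1], V[:, 1] - hi[1] - dil), 0.0)
    dist = np.sqrt(dx**2 + dy**2)
    weights = _smoothstep(dist / 2.0)

    surf = _apply_noise(surf, spec.noise_sd, [spec.seed, 23])

    # free-floating fragments (scan debris) above the augmented surface
    parts = [surf]
    if spec.n_floating_fragments > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 29]))
        for _ in range(spec.n_floating_fragments):
            cx = rng.uniform(lo[0] + 1, hi[0] - 1)
            cy = rng.uniform(lo[1] + 1, hi[1] - 1)
            cz = aug_height(np.array([cx]), np.array([cy]))[0] + rng.uniform(1.2, 2.0)
            frag = trimesh.creation.icosphere(
                subdivisions=1, radius=spec.fragment_radius
            )
            frag.apply_translation([cx, cy, cz])
            parts.append(frag)
        weights = np.concatenate(
            [weights] + [np.zeros(len(p.vertices)) for p in parts[1:]]
        )
    merged = trimesh.util.concatenate(parts) if len(parts) > 1 else surf

    # ROI (baseline frame): footprint + margin, z spanning body to above graft
    pad = 2.5
    roi_min = np.array([lo[0] - pad, lo[1] - pad, 0.0])
    roi_max = np.array([hi[0] + pad, hi[1] + pad, 0.0])
    xs = np.linspace(roi_min[0], roi_max[0], 40)
    ys = np.linspace(roi_min[1], roi_max[1], 40)
    Xr, Yr = np.meshgrid(xs, ys, indexing="ij")
    zb = base_height(spec, Xr, Yr)
    za = aug_height(Xr, Yr)
    roi_min[2] = zb.min() - 2.0
    roi_max[2] = za.max() + 2.0 + (2.5 if spec.n_floating_fragments else 0.0)

    pose = _random_pose(spec)
    scan = merged.copy()
    scan.vertices = pose.apply(scan.vertices)

    lm_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 31]))
    pts = _landmark_points(spec)
    pts_moving = pose.apply(pts)
    if spec.landmark_noise_sd > 0:
        pts_moving = pts_moving + lm_rng.normal(0, spec.landmark_noise_sd, (3, 3))
    landmarks = LandmarkSet(labels=("L1", "L2", "L3"), points=pts_moving)

    truth = PhantomTruth(
        ground_truth_volume_mm3=float(truth_mm3),
        applied_pose=pose,
        roi_min=roi_min,
        roi_max=roi_max,
    )
    # NB: validate_mesh would renumber vertices; keep raw ordering so the
    # weight map stays aligned (the grid mesh is already clean by construction)
    return scan, weights, landmarks, truth


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Full baseline + augmented phantom pair for one specimen."""
    baseline, lm_base = generate_baseline(spec)
    scan, weights, lm_aug, truth = generate_augmented(spec)
    return PhantomPair(
        spec=spec,
        baseline=baseline,
        baseline_landmarks=lm_base,
        augmented=scan,
        augmented_landmarks=lm_aug,
        weights=weights,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# study generation

def generate_study(
    n_specimens: int,
    out_dir,
    seed: int = 0,
    techniques=TECHNIQUES,
    noise_sd: float = 0.0,
    n_floating_fragments: int = 0,
    base_spec: PhantomSpec | None = None,
) -> pd.DataFrame:
    """Write an n-specimen phantom study to disk; return the truth manifest.

    Per specimen: one baseline STL + landmarks, and per technique an
    augmented STL, landmarks, weight map and ROI box, with per-technique
    target volumes drawn around the in-vitro scales.  Same seed → identical
    files.
    """
    if n_specimens < 1:
        raise ValueError("need at least 1 specimen")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    rows = []
    for i in range(n_specimens):
        sid = f"spec{i:03d}"
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        for j, tech in enumerate(techniques):
            mu = DEFAULT_TARGETS_CM3[tech]
            sdv = DEFAULT_TARGET_SDS_CM3[tech]
            target = float(np.clip(rng.normal(mu, sdv), mu - 2 * sdv, mu + 2 * sdv))
            spec = dataclasses.replace(
                base_spec or PhantomSpec(),
                technique=tech,
                seed=seed * 10007 + i * 101 + j,
                baseline_seed=seed * 10007 + i * 101,
                target_volume_cm3=target,
                noise_sd=noise_sd,
                n_floating_fragments=n_floating_fragments,
            )
            pair = generate_phantom(spec)
            if j == 0:
                write_stl(pair.baseline, sdir / "baseline.stl")
                write_landmarks(pair.baseline_landmarks, sdir / "baseline_landmarks.csv")
            write_stl(pair.augmented, sdir / f"{tech}.stl")
            write_landmarks(pair.augmented_landmarks, sdir / f"{tech}_landmarks.csv")
            # STL re-reading merges/renumbers vertices; transfer the weight
            # map onto the file's vertex order by nearest neighbour
            reread = read_stl(sdir / f"{tech}.stl")
            _, nn = cKDTree(pair.augmented.vertices).query(reread.vertices)
            write_weights(pair.weights[nn], sdir / f"{tech}_weights.csv")
            pair.truth.applied_pose.save(sdir / f"{tech}_pose.txt")
            rows.append(
                {
                    "specimen": sid,
                    "technique": tech,
                    "truth_cm3": pair.truth.ground_truth_volume_mm3 / 1000.0,
                    "roi_min_x": pair.truth.roi_min[0],
                    "roi_min_y": pair.truth.roi_min[1],
                    "roi_min_z": pair.truth.roi_min[2],
                    "roi_max_x": pair.truth.roi_max[0],
                    "roi_max_y": pair.truth.roi_max[1],
                    "roi_max_z": pair.truth.roi_max[2],
                    "pose_file": f"{sid}/{tech}_pose.txt",
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
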