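"""Independent reference computations used only by the test suite.

These deliberately avoid the code paths of the package: ray casting is
Möller–Trumbore along an oblique direction (the package voxelizer uses
vertical-column scanline parity), the ANOVA oracle accumulates sums of
squares with explicit loops, and the signed-rank oracle enumerates all
2^n sign assignments.
"""

import itertools

import numpy as np


def ray_parity_inside(mesh, points, direction=(0.113, 0.071, 0.991)):
    """Point-in-solid by ray parity (Möller–Trumbore), vectorised per chunk."""
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)
    tri = mesh.triangles  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    pvec = np.cross(d, e2)  # (m, 3)
    det = (e1 * pvec).sum(axis=1)
    ok_det = np.abs(det) > 1e-14
    inv = np.where(ok_det, det, 1.0)

    points = np.asarray(points, float)
    inside = np.zeros(len(points), dtype=bool)
    chunk = max(1, int(2_000_000 // max(len(tri), 1)))
    for s in range(0, len(points), chunk):
        P = points[s : s + chunk]  # (p, 3)
        tvec = P[:, None, :] - v0[None, :, :]  # (p, m, 3)
        u = (tvec * pvec[None, :, :]).sum(axis=2) / inv[None, :]
        qvec = np.cross(tvec, e1[None, :, :])
        v = (qvec * d).sum(axis=2) / inv[None, :]
        t = (qvec * e2[None, :, :]).sum(axis=2) / inv[None, :]
        hit = ok_det[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        inside[s : s + chunk] = hit.sum(axis=1) % 2 == 1
    return inside


def _grid_points(lo, hi, pitch):
    axes = [
        lo[k] + (np.arange(int(np.ceil((hi[k] - lo[k]) / pitch))) + 0.5) * pitch
        for k in range(3)
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def ray_parity_volume(mesh, pitch):
    """Volume by counting inside-grid points with the ray-parity test."""
    lo, hi = mesh.bounds
    pts = _grid_points(lo, hi, pitch)
    return ray_parity_inside(mesh, pts).sum() * pitch**3


def ray_parity_difference_volume(a, b, pitch):
    """Volume of the set difference a \\ b by point-in-solid parity.

    Works on the *input* solids directly (a point is in the difference iff
    it is inside ``a`` and outside ``b``), fully independent of any mesh
    Boolean output.
    """
    lo = np.minimum(a.bounds[0], b.bounds[0]) - pitch
    hi = np.maximum(a.bounds[1], b.bounds[1]) + pitch
    pts = _grid_points(lo, hi, pitch)
    in_diff = ray_parity_inside(a, pts) & ~ray_parity_inside(b, pts)
    return in_diff.sum() * pitch**3


def anova_two_way_oracle(X):
    """Two-way (subjects × raters) ANOVA mean squares via explicit loops."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += X[i, j]
    grand /= n * k
    ssr = 0.0
    for i in range(n):
        m = sum(X[i, j] for j in range(k)) / k
        ssr += k * (m - grand) ** 2
    ssc = 0.0
    for j in range(k):
        m = sum(X[i, j] for i in range(n)) / n
        ssc += n * (m - grand) ** 2
    sst = 0.0
    for i in range(n):
        for j in range(k):
            sst += (X[i, j] - grand) ** 2
    sse = sst - ssr - ssc
    return {
        "MSR": ssr / (n - 1),
        "MSC": ssc / (k - 1),
        "MSE": sse / ((n - 1) * (k - 1)),
    }


def icc_a1_oracle(X):
    """ICC(A,1) straight from the oracle mean squares."""
    X = np.asarray(X, float)
    n, k = X.shape
    ms = anova_two_way_oracle(X)
    return (ms["MSR"] - ms["MSE"]) / (
        ms["MSR"] + (k - 1) * ms["MSE"] + k / n * (ms["MSC"] - ms["MSE"])
    )


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = _midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2.0
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def _midranks(a):
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a))
    sorted_a = a[order]
    i = 0
    while i < len(a):
        j = i
        while j < len(a) and sorted_a[j] == sorted_a[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks
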