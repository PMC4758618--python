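"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive search,
textbook formulas) and shares no selection/measurement logic with the
package code paths it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.special import stdtr


def gaussian_quadrature_voxels(shape, center, photons, sigma_z_vox, sigma_xy_vox,
                               oversample=64):
    """Per-voxel mass of a 3D Gaussian by midpoint quadrature.

    ``shape`` is (nz, ny, nx); sigmas are in voxel units; each voxel is
    subdivided ``oversample`` times per axis and the Gaussian density summed
    at sub-voxel midpoints.
    """
    nz, ny, nx = shape
    cz, cy, cx = center
    out = np.zeros(shape)
    step = 1.0 / oversample
    # sub-voxel midpoint offsets relative to the voxel's lower edge (i - 0.5)
    sub = (np.arange(oversample) + 0.5) * step

    def density_1d(n, c, s):
        # (n, oversample) density at each voxel's sub-points
        pts = (np.arange(n)[:, None] - 0.5) + sub[None, :] - c
        return np.exp(-pts ** 2 / (2 * s * s)) / (s * math.sqrt(2 * math.pi))

    gz = density_1d(nz, cz, sigma_z_vox).sum(axis=1) * step
    gy = density_1d(ny, cy, sigma_xy_vox).sum(axis=1) * step
    gx = density_1d(nx, cx, sigma_xy_vox).sum(axis=1) * step
    out = photons * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return out


def brute_force_find_foci(values, edge_margin, min_separation, smooth_sigma=1.0,
                          max_spots=None):
    """Exhaustive re-implementation of brightest-spots detection.

    Same contract as ``find_foci`` but with explicit neighbor loops and a
    full O(n^2) greedy pass; returns a list of (z, y, x) positions.
    """
    v = np.asarray(values, dtype=np.float64)
    if smooth_sigma > 0:
        v = ndimage.gaussian_filter(v, smooth_sigma)
    nz, ny, nx = v.shape
    padded = np.pad(v, 1, mode="edge")
    maxima = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                val = v[z, y, x]
                neigh = []
                for dz_, dy_, dx_ in product((-1, 0, 1), repeat=3):
                    if dz_ == dy_ == dx_ == 0:
                        continue
                    neigh.append(padded[z + 1 + dz_, y + 1 + dy_, x + 1 + dx_])
                if all(val >= nv for nv in neigh) and any(val > nv for nv in neigh):
                    maxima.append((val, z, y, x))
    maxima.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    accepted = []
    for val, z, y, x in maxima:
        if not (edge_margin <= z < nz - edge_margin
                and edge_margin <= y < ny - edge_margin
                and edge_margin <= x < nx - edge_margin):
            continue
        ok = True
        for az, ay, ax in accepted:
            if (z - az) ** 2 + (y - ay) ** 2 + (x - ax) ** 2 < min_separation ** 2:
                ok = False
                break
        if ok:
            accepted.append((z, y, x))
            if max_spots is not None and len(accepted) >= max_spots:
                break
    return accepted


def max_bipartite_matching_count(truth_pos, cand_pos, tol):
    """Maximum number of one-to-one truth/candidate pairs within ``tol``,
    by exhaustive recursion (small instances only)."""
    truth_pos = np.asarray(truth_pos, dtype=float)
    cand_pos = np.asarray(cand_pos, dtype=float)
    edges = [
        [j for j in range(len(cand_pos))
         if np.linalg.norm(truth_pos[i] - cand_pos[j]) <= tol]
        for i in range(len(truth_pos))
    ]

    def rec(i, used):
        if i == len(edges):
            return 0
        best = rec(i + 1, used)
        for j in edges[i]:
            if j not in used:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


def welch_ttest(a, b):
    """Textbook Welch t test of b vs a: t, Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (b.mean() - a.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return t, df, p
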