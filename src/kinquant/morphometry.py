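"""Focus size and brightness by marginal-sum 1D Gaussian fitting.

A 5x5-pixel patch is cut from the z-slice of each focus's peak voxel, a
local background (median of the patch's 16 border pixels) is subtracted,
the patch is collapsed to row sums and column sums, and each 5-point
marginal is fit with the 4-parameter Gaussian

    y = a + (b - a) * exp(-(x - c)^2 / (2 d^2))

The per-axis FWHM values (2 sqrt(2 ln 2) d) are averaged into one focus
width; "peak height" is the mean fitted amplitude above baseline, b - a.
Fits that fail to converge or pin the bounded width are flagged and the
focus is excluded from population summaries (with a logged count), never
silently clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import RoiOutOfBoundsError
from .simulate import VoxelGrid

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian with unit s.d.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

PATCH_HALF = 2  # 5x5 patch

# width bounds (px): below 0.3 px a 5-point marginal carries no width
# information; above 5 px the profile is flat across the patch
_D_MIN, _D_MAX = 0.3, 5.0
_BOUND_TOL = 1e-6


@dataclass(frozen=True)
class PatchProfile:
    """Background-subtracted 5x5 patch and its marginal sums.

    ``row_sums[i]`` sums patch row ``i`` (a profile along y);
    ``col_sums[j]`` sums patch column ``j`` (a profile along x).  Both
    marginals total the same patch sum.
    """

    patch: np.ndarray
    local_background: float

    @property
    def row_sums(self) -> np.ndarray:
        return self.patch.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.patch.sum(axis=0)


@dataclass(frozen=True)
class GaussianFit1D:
    """Result of a 4-parameter 1D Gaussian fit to a 5-point marginal.

    ``a`` baseline, ``b`` peak value (the model evaluated at ``c`` equals
    ``b``), ``c`` center (px), ``d`` s.d. (px).
    """

    a: float
    b: float
    c: float
    d: float
    converged: bool
    residual_norm: float

    @property
    def amplitude(self) -> float:
        """Height above baseline, b - a."""
        return self.b - self.a

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.d


@dataclass(frozen=True)
class FocusSize:
    """Averaged morphometry of one focus from its row and column fits."""

    focus_id: str
    fwhm_px: float
    fwhm_um: float
    peak_height: float


def extract_patch(grid: VoxelGrid, center: tuple[int, int, int]) -> PatchProfile:
    """Cut the 5x5 patch around ``center`` from its z-slice and subtract the
    local background (median of the 16 border pixels)."""
    z, y, x = (int(v) for v in center)
    nz, ny, nx = grid.shape
    h = PATCH_HALF
    if not (0 <= z < nz and h <= y < ny - h and h <= x < nx - h):
        raise RoiOutOfBoundsError(
            f"5x5 patch at center {(z, y, x)} crosses the boundary of grid {grid.shape}")
    patch = grid.values[z, y - h:y + h + 1, x - h:x + h + 1].astype(np.float64)
    border = np.concatenate([patch[0, :], patch[-1, :], patch[1:-1, 0], patch[1:-1, -1]])
    bg = float(np.median(border))
    return PatchProfile(patch=patch - bg, local_background=bg)


def fit_gaussian_1d(profile: np.ndarray) -> GaussianFit1D:
    """Nonlinear least-squares fit of ``a + (b-a) exp(-(x-c)^2/(2 d^2))``.

    Initialized at a = min, b = max, c = argmax, d = 1 px; the center is
    bounded to the window and the width to [0.3, 5] px.  A fit that ends
    pinned at a width bound (or fails to converge) is reported with
    ``converged=False``; five points constrain four parameters only weakly,
    so such fits are excluded rather than clamped.
    """
    y = np.asarray(profile, dtype=np.float64)
    n = y.size
    x = np.arange(n, dtype=np.float64)

    def resid(p: np.ndarray) -> np.ndarray:
        a, b, c, d = p
        return a + (b - a) * np.exp(-((x - c) ** 2) / (2.0 * d * d)) - y

    p0 = np.array([float(y.min()), float(y.max()), float(np.argmax(y)), 1.0])
    lower = np.array([-np.inf, -np.inf, 0.0, _D_MIN])
    upper = np.array([np.inf, np.inf, float(n - 1), _D_MAX])
    p0 = np.clip(p0, lower, upper)
    try:
        result = least_squares(resid, p0, bounds=(lower, upper), xtol=1e-12,
                               ftol=1e-12, gtol=1e-12)
    except Exception:  # singular Jacobian on pathological profiles
        return GaussianFit1D(*p0, converged=False, residual_norm=float("inf"))
    a, b, c, d = (float(v) for v in result.x)
    pinned = d <= _D_MIN + _BOUND_TOL or d >= _D_MAX - _BOUND_TOL
    converged = bool(result.success) and not pinned and d > 0
    return GaussianFit1D(a=a, b=b, c=c, d=d, converged=converged,
                         residual_norm=float(np.linalg.norm(result.fun)))


def focus_size(row_fit: GaussianFit1D, col_fit: GaussianFit1D,
               pixel_size_um: float, focus_id: str = "?") -> FocusSize | None:
    """Average the two per-axis fits into one focus size.

    Returns ``None`` when either fit failed (the focus is excluded from
    population summaries; callers count exclusions).
    """
    if not (row_fit.converged and col_fit.converged):
        return None
    fwhm_px = 0.5 * (row_fit.fwhm + col_fit.fwhm)
    return FocusSize(focus_id=focus_id, fwhm_px=fwhm_px,
                     fwhm_um=fwhm_px * pixel_size_um,
                     peak_height=0.5 * (row_fit.amplitude + col_fit.amplitude))


def measure_sizes(grid: VoxelGrid, centers: list[tuple[int, int, int]],
                  focus_ids: list[str] | None = None) -> pd.DataFrame:
    """Morphometry for a list of peak voxels.

    Returns a table (focus_id, z, y, x, fwhm_px, fwhm_um, peak_height,
    converged); non-converged rows carry NaN measurements and the failure
    count is logged.
    """
    ids = focus_ids or [f"spot_{i:04d}" for i in range(len(centers))]
    rows = []
    n_failed = 0
    for fid, c in zip(ids, centers):
        profile = extract_patch(grid, c)
        row_fit = fit_gaussian_1d(profile.row_sums)
        col_fit = fit_gaussian_1d(profile.col_sums)
        size = focus_size(row_fit, col_fit, grid.dx, focus_id=fid)
        if size is None:
            n_failed += 1
            rows.append({"focus_id": fid, "z": c[0], "y": c[1], "x": c[2],
                         "fwhm_px": np.nan, "fwhm_um": np.nan,
                         "peak_height": np.nan, "converged": False})
        else:
            rows.append({"focus_id": fid, "z": c[0], "y": c[1], "x": c[2],
                         "fwhm_px": size.fwhm_px, "fwhm_um": size.fwhm_um,
                         "peak_height": size.peak_height, "converged": True})
    if n_failed:
        logger.warning("morphometry: %d/%d foci excluded (fit failure)",
                       n_failed, len(centers))
    return pd.DataFrame(rows, columns=["focus_id", "z", "y", "x", "fwhm_px",
                                       "fwhm_um", "peak_height", "converged"])
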