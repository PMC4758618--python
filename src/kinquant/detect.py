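"""Kinetochore focus detection.

Finds candidate foci as the brightest local maxima of a (lightly smoothed)
z-stack, greedily selected in descending intensity with non-maximum
suppression, and removes any candidate within ``edge_margin`` voxels of an
x, y or z image boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .simulate import VoxelGrid


@dataclass(frozen=True)
class SpotCandidate:
    """A detected focus: its peak voxel, intensity, and rank (0 = brightest)."""

    z: int
    y: int
    x: int
    peak_value: float      # raw grid value at the peak voxel
    smoothed_value: float  # value after pre-smoothing (ranking key)
    rank: int

    @property
    def position(self) -> tuple[int, int, int]:
        return (self.z, self.y, self.x)


@dataclass(frozen=True)
class DetectionParams:
    """Detection configuration.

    ``edge_margin``: candidates closer than this (in voxels) to any boundary
    are discarded.  ``min_separation``: minimum Euclidean distance (voxel
    units) between accepted peaks.  ``smooth_sigma``: isotropic Gaussian
    pre-smoothing in voxels (0 disables).  Stop after ``max_spots`` accepted
    peaks and/or below ``threshold`` (on the smoothed intensity).
    """

    edge_margin: int = 3
    min_separation: float = 5.0
    max_spots: int | None = None
    threshold: float | None = None
    smooth_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.edge_margin < 0:
            raise ConfigError("edge_margin must be >= 0")
        if self.min_separation < 1:
            raise ConfigError("min_separation must be >= 1")
        if self.max_spots is not None and self.max_spots < 1:
            raise ConfigError("max_spots must be >= 1")
        if self.smooth_sigma < 0:
            raise ConfigError("smooth_sigma must be >= 0")


def find_foci(grid: VoxelGrid, params: DetectionParams | None = None) -> list[SpotCandidate]:
    """Brightest-spots detection.

    The stack is Gaussian-smoothed, voxels that are 26-neighborhood local
    maxima (and strictly above at least one neighbor, so constant regions
    yield nothing) are ranked by descending smoothed intensity with
    lexicographic (z, y, x) tie-breaking, and peaks are accepted greedily
    subject to the edge margin and minimum pairwise separation.  Ordering is
    fully deterministic.
    """
    params = params or DetectionParams()
    nz, ny, nx = grid.shape
    if min(nz, ny, nx) <= 2 * params.edge_margin:
        raise ConfigError(
            f"grid shape {grid.shape} too small for edge_margin={params.edge_margin}")
    values = grid.values.astype(np.float64)
    if params.smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(values, params.smooth_sigma)
    else:
        smoothed = values

    footprint_max = ndimage.maximum_filter(smoothed, size=3, mode="reflect")
    footprint_min = ndimage.minimum_filter(smoothed, size=3, mode="reflect")
    # >= all neighbors and > at least one: plateaus survive, flats do not
    is_max = (smoothed >= footprint_max) & (smoothed > footprint_min)
    coords = np.argwhere(is_max)
    if coords.size == 0:
        return []

    peak_vals = smoothed[tuple(coords.T)]
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -peak_vals))
    coords = coords[order]
    peak_vals = peak_vals[order]

    m = params.edge_margin
    sep2 = params.min_separation ** 2
    accepted: list[SpotCandidate] = []
    accepted_pos: list[np.ndarray] = []
    for (z, y, x), sval in zip(coords, peak_vals):
        if params.threshold is not None and sval < params.threshold:
            break
        if not (m <= z < nz - m and m <= y < ny - m and m <= x < nx - m):
            continue
        pos = np.array([z, y, x], dtype=float)
        if any(float(np.sum((pos - p) ** 2)) < sep2 for p in accepted_pos):
            continue
        accepted.append(SpotCandidate(int(z), int(y), int(x),
                                      float(values[z, y, x]), float(sval),
                                      rank=len(accepted)))
        accepted_pos.append(pos)
        if params.max_spots is not None and len(accepted) >= params.max_spots:
            break
    return accepted


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching detected candidates against planted ground truth."""

    recall: float
    precision: float
    pairs: tuple[tuple[str, int, float], ...]  # (focus_id, candidate rank, distance)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_to_truth(candidates: list[SpotCandidate], truth: pd.DataFrame,
                   tol: float = 2.0) -> MatchResult:
    """Greedy one-to-one nearest matching of candidates to planted foci.

    All candidate/truth pairs within Euclidean distance ``tol`` (voxel units)
    are considered in ascending distance order (ties broken by truth row then
    candidate rank); each candidate and each truth row matches at most once.
    Recall = matched / planted; precision = matched / detected (1.0 when
    nothing was detected, i.e. no false positives).
    """
    if tol < 1:
        raise ConfigError("tol must be >= 1")
    n_true = len(truth)
    n_cand = len(candidates)
    if n_true == 0 or n_cand == 0:
        return MatchResult(recall=0.0 if n_true else 1.0,
                           precision=1.0 if n_cand == 0 else 0.0, pairs=())
    tpos = truth[["z", "y", "x"]].to_numpy(dtype=float)
    cpos = np.array([[c.z, c.y, c.x] for c in candidates], dtype=float)
    d = np.sqrt(((tpos[:, None, :] - cpos[None, :, :]) ** 2).sum(axis=2))
    ti, ci = np.nonzero(d <= tol)
    order = np.lexsort((ci, ti, d[ti, ci]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[str, int, float]] = []
    for k in order:
        t, c = int(ti[k]), int(ci[k])
        if t in used_t or c in used_c:
            continue
        used_t.add(t)
        used_c.add(c)
        pairs.append((str(truth["focus_id"].iloc[t]), candidates[c].rank,
                      float(d[t, c])))
    return MatchResult(recall=len(pairs) / n_true, precision=len(pairs) / n_cand,
                       pairs=tuple(pairs))


def candidates_to_frame(candidates: list[SpotCandidate]) -> pd.DataFrame:
    """Candidate list as a table (focus_id, z, y, x, peak_value)."""
    return pd.DataFrame({
        "focus_id": [f"spot_{c.rank:04d}" for c in candidates],
        "z": [c.z for c in candidates],
        "y": [c.y for c in candidates],
        "x": [c.x for c in candidates],
        "peak_value": [c.peak_value for c in candidates],
    })
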