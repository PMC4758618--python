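"""Synthetic fluorescence z-stack generator with known ground truth.

Emulates widefield imaging of post-anaphase budding-yeast cells carrying
fluorescently tagged kinetochore proteins: each dividing cell shows 1-2
diffraction-limited kinetochore foci over a diffuse cellular background,
recorded as a 17-slice z-stack with 0.205 um lateral pixels and 0.4 um axial
spacing.  Foci are rendered as voxel-integrated anisotropic 3D Gaussians
(error-function differences per axis, exact at coarse voxels), per-focus
brightness is lognormal within each genotype arm, and a camera model adds
Poisson photon noise plus Gaussian read noise before 16-bit quantization.

Genotype scenarios plant known fold-changes of the observables the analysis
pipeline measures (background-subtracted box intensity, fitted marginal FWHM
and peak height), so recovery can be validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ConfigError

# ---------------------------------------------------------------------------
# Defaults describing the imaging regime being emulated
# ---------------------------------------------------------------------------

#: Lateral pixel size, um (63x objective, 2x2 binned CCD).
DEFAULT_PIXEL_SIZE_UM = 0.205
#: Axial slice spacing, um.
DEFAULT_Z_STEP_UM = 0.4
#: Number of z slices per stack.
DEFAULT_NZ = 17
#: Camera bit depth (quantization ceiling 2**16 - 1).
DEFAULT_BIT_DEPTH = 16
#: Baseline integrated photon count per wild-type focus.  The source imaging
#: system's absolute gain is unknown; this value puts the peak voxel ~8-fold
#: above the diffuse background at comfortable SNR, and every downstream
#: comparison is a ratio, so the absolute scale is immaterial.
DEFAULT_BASELINE_PHOTONS = 5000.0

_QUANTILE_STREAM = 777      # shared brightness-quantile stream (see methods)
_POSITION_STREAM = 101
_NOISE_STREAM = 202


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """A 3D intensity lattice with physical voxel dimensions.

    ``values`` is indexed ``(z, y, x)``.  Floating dtype marks an un-quantized
    (pre-camera) photon-expectation grid; integer dtype marks camera output.
    Voxel ``i`` spans the interval ``[i - 0.5, i + 0.5]`` along its axis, so
    integer coordinates address voxel centers and sub-voxel positions are
    continuous.
    """

    values: np.ndarray
    dx: float = DEFAULT_PIXEL_SIZE_UM
    dy: float = DEFAULT_PIXEL_SIZE_UM
    dz: float = DEFAULT_Z_STEP_UM
    bit_depth: int = DEFAULT_BIT_DEPTH
    channel: str = "GFP"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ConfigError(f"VoxelGrid values must be 3D (z,y,x), got ndim={self.values.ndim}")
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ConfigError("voxel dimensions must be positive")
        if np.issubdtype(self.values.dtype, np.floating):
            if not np.all(np.isfinite(self.values)):
                raise ConfigError("VoxelGrid values must be finite")
        if np.any(self.values < 0):
            raise ConfigError("VoxelGrid values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def nz(self) -> int:
        return self.values.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def quantized(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    def copy(self) -> "VoxelGrid":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class OpticsModel:
    """Widefield point-spread-function and camera parameters.

    The PSF is an anisotropic 3D Gaussian; defaults approximate a
    diffraction-limited 1.4 NA widefield system for green fluorophores
    (lateral s.d. 0.12 um, axial s.d. 0.35 um).
    """

    sigma_xy: float = 0.12          # um
    sigma_z: float = 0.35           # um
    bg_level: float = 100.0         # mean diffuse background, counts
    bg_gradient: tuple[float, float] | None = None  # (dI/dy, dI/dx) counts/px
    read_noise_sd: float = 2.0      # counts
    photon_noise: bool = True

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ConfigError("PSF sigmas must be positive")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd must be >= 0")
        if self.bg_level < 0:
            raise ConfigError("bg_level must be >= 0")


@dataclass(frozen=True)
class ArmSpec:
    """One genotype arm of a scenario.

    Exactly one of two parameterizations applies:

    * intensity arms set ``intensity_fold`` (true fold-change of per-focus
      integrated brightness vs the control arm) and leave
      ``peakheight_fold`` unset;
    * morphometry arms set ``peakheight_fold`` and ``fwhm_fold`` (target
      fold-changes of the *fitted* marginal peak height and FWHM), and the
      generator numerically solves the underlying PSF width and amplitude
      that realize them (see :func:`solve_morphometry_scaling`).

    ``cv`` is the lognormal coefficient of variation of per-focus brightness.
    ``channels`` maps fluorophore label to its fraction of each focus's
    brightness (dual-tag competition arms split 0.5/0.5).
    """

    label: str
    intensity_fold: float = 1.0
    fwhm_fold: float = 1.0
    peakheight_fold: float | None = None
    cv: float = 0.2
    width_cv: float = 0.0
    channels: Mapping[str, float] = field(default_factory=lambda: {"GFP": 1.0})

    def __post_init__(self) -> None:
        if self.intensity_fold <= 0 or self.fwhm_fold <= 0:
            raise ConfigError(f"arm {self.label!r}: folds must be positive")
        if self.peakheight_fold is not None and self.peakheight_fold <= 0:
            raise ConfigError(f"arm {self.label!r}: peakheight_fold must be positive")
        if self.cv < 0 or self.width_cv < 0:
            raise ConfigError(f"arm {self.label!r}: cv must be >= 0")
        total = sum(self.channels.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ConfigError(f"arm {self.label!r}: channel fractions must sum to 1, got {total}")

    @property
    def is_morphometry(self) -> bool:
        return self.peakheight_fold is not None


@dataclass(frozen=True)
class GenotypeScenario:
    """Named simulation preset: a control arm followed by mutant arms.

    The first arm is the normalization reference.  ``kind`` is
    ``"intensity"``, ``"morphometry"`` or ``"dualtag"`` and decides which
    measurements the pipeline runs.
    """

    name: str
    arms: tuple[ArmSpec, ...]
    n_foci: int = 150
    baseline_photons: float = DEFAULT_BASELINE_PHOTONS
    kind: str = "intensity"
    source: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.arms:
            raise ConfigError(f"scenario {self.name!r} has no arms")
        if self.n_foci < 1:
            raise ConfigError("n_foci must be >= 1")
        if self.kind not in ("intensity", "morphometry", "dualtag"):
            raise ConfigError(f"unknown scenario kind {self.kind!r}")

    # Convenience accessors for the common two-arm (control, mutant) layout.
    @property
    def control(self) -> ArmSpec:
        return self.arms[0]

    @property
    def cv(self) -> float:
        """Control-arm brightness CV."""
        return self.arms[0].cv

    @property
    def intensity_fold(self) -> float:
        """Planted intensity fold of the mutant arm (two-arm scenarios)."""
        if len(self.arms) != 2:
            raise ConfigError(f"scenario {self.name!r} has {len(self.arms)} arms; "
                              "access arm folds explicitly")
        return self.arms[1].intensity_fold

    @property
    def channel_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for arm in self.arms:
            for ch in arm.channels:
                if ch not in names:
                    names.append(ch)
        return tuple(names)


#: Column order of the ground-truth table written next to simulated stacks.
TRUTH_COLUMNS = ["focus_id", "cell_id", "z", "y", "x", "photons",
                 "sigma_xy_um", "channel", "genotype"]


# ---------------------------------------------------------------------------
# Focus rendering
# ---------------------------------------------------------------------------

def _axis_mass(n: int, center: float, sigma_px: float) -> tuple[np.ndarray, int, int]:
    """Integrated 1D Gaussian mass per voxel along one axis.

    Returns (fractions, lo, hi) where fractions covers voxels lo..hi-1 of an
    axis of length n; voxels outside a 6-sigma window carry < 1e-9 of the mass
    and are skipped.
    """
    half = 6.0 * sigma_px + 1.0
    lo = max(0, int(math.floor(center - half)))
    hi = min(n, int(math.ceil(center + half)) + 1)
    if hi <= lo:
        return np.zeros(0), 0, 0
    edges_lo = np.arange(lo, hi) - 0.5 - center
    edges_hi = edges_lo + 1.0
    s = sigma_px * math.sqrt(2.0)
    frac = 0.5 * (erf(edges_hi / s) - erf(edges_lo / s))
    return frac, lo, hi


def render_focus(grid: VoxelGrid, center: tuple[float, float, float],
                 photons: float, sigma_xy: float, sigma_z: float) -> VoxelGrid:
    """Add one diffraction-limited focus to ``grid`` (in place) and return it.

    The focus is an anisotropic 3D Gaussian with total integrated brightness
    ``photons``, centered at the sub-voxel position ``center`` (z, y, x) and
    integrated exactly over each voxel via per-axis error-function
    differences.  Counts falling outside the grid are lost, so the mass added
    equals ``photons`` times the in-grid Gaussian fraction.

    ``sigma_xy`` and ``sigma_z`` are in um and converted to voxel units with
    the grid's voxel dimensions.
    """
    if photons < 0:
        raise ConfigError(f"photons must be >= 0, got {photons}")
    if sigma_xy <= 0 or sigma_z <= 0:
        raise ConfigError("sigma_xy and sigma_z must be positive")
    if grid.quantized:
        raise ConfigError("cannot render into a quantized grid")
    nz, ny, nx = grid.shape
    cz, cy, cx = center
    if not (-0.5 <= cz <= nz - 0.5 and -0.5 <= cy <= ny - 0.5 and -0.5 <= cx <= nx - 0.5):
        raise ConfigError(f"focus center {center} outside grid of shape {grid.shape}")
    if photons == 0:
        return grid
    fz, zlo, zhi = _axis_mass(nz, cz, sigma_z / grid.dz)
    fy, ylo, yhi = _axis_mass(ny, cy, sigma_xy / grid.dy)
    fx, xlo, xhi = _axis_mass(nx, cx, sigma_xy / grid.dx)
    if fz.size == 0 or fy.size == 0 or fx.size == 0:
        return grid
    grid.values[zlo:zhi, ylo:yhi, xlo:xhi] += (
        photons * fz[:, None, None] * fy[None, :, None] * fx[None, None, :]
    )
    return grid


# ---------------------------------------------------------------------------
# Camera model
# ---------------------------------------------------------------------------

def apply_noise(grid: VoxelGrid, optics: OpticsModel, seed: int) -> VoxelGrid:
    """Apply the camera model: Poisson photon noise, Gaussian read noise,
    clipping at the bit-depth ceiling, and integer quantization.

    Returns a new, quantized :class:`VoxelGrid`; the input (which must be
    un-quantized) is untouched.
    """
    if grid.quantized:
        raise ConfigError("apply_noise expects an un-quantized grid")
    rng = np.random.default_rng(seed)
    values = grid.values.astype(np.float64)
    if optics.photon_noise:
        values = rng.poisson(values).astype(np.float64)
    if optics.read_noise_sd > 0:
        values = values + rng.normal(0.0, optics.read_noise_sd, size=values.shape)
    ceiling = float(2 ** grid.bit_depth - 1)
    values = np.clip(np.rint(values), 0.0, ceiling)
    dtype = np.uint16 if grid.bit_depth <= 16 else np.uint32
    return replace(grid, values=values.astype(dtype))


# ---------------------------------------------------------------------------
# Field simulation
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and coefficient of
    variation."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _field_layout(n_foci: int, nz: int, margin: int, spacing: int,
                  pair_offset: int) -> tuple[tuple[int, int, int], list[tuple[int, float, float, float]]]:
    """Deterministic cell lattice.

    Cells sit on a square lattice with ``spacing`` px pitch and ``margin`` px
    border; each cell contributes two foci displaced +-``pair_offset`` px
    along x (post-anaphase sister clusters), the last cell one focus if
    ``n_foci`` is odd.  Returns the grid shape and a list of
    (cell_id, z, y, x) nominal focus positions.
    """
    n_cells = (n_foci + 1) // 2
    ncols = max(1, math.ceil(math.sqrt(n_cells)))
    nrows = math.ceil(n_cells / ncols)
    ny = max(32, 2 * margin + (nrows - 1) * spacing)
    nx = max(32, 2 * margin + (ncols - 1) * spacing)
    z0 = nz // 2
    positions: list[tuple[int, float, float, float]] = []
    for cell in range(n_cells):
        r, c = divmod(cell, ncols)
        cy = margin + r * spacing
        cx = margin + c * spacing
        for side in (-1, +1):
            if len(positions) >= n_foci:
                break
            positions.append((cell, float(z0), float(cy), float(cx + side * pair_offset)))
    return (nz, ny, nx), positions


def simulate_arm(scenario: GenotypeScenario, arm: ArmSpec | str,
                 optics: OpticsModel | None = None, seed: int = 0,
                 n_foci: int | None = None,
                 grid_kwargs: Mapping[str, float] | None = None,
                 ) -> tuple[dict[str, VoxelGrid], pd.DataFrame]:
    """Simulate one genotype arm: one quantized stack per channel plus the
    ground-truth table.

    Brightness quantiles are drawn from a stream that depends only on
    ``seed`` (not on the arm), so arms of the same scenario simulated with
    the same seed share their standard-normal draws: each arm's brightness
    distribution is exactly its stated lognormal, while fold-change ratios
    between arms are insulated from finite-sample drift of the arm means
    (common random numbers).  Positions and camera noise use arm-specific
    independent streams.
    """
    optics = optics or OpticsModel()
    if isinstance(arm, str):
        matches = [a for a in scenario.arms if a.label == arm]
        if not matches:
            raise ConfigError(f"scenario {scenario.name!r} has no arm {arm!r}")
        arm = matches[0]
    arm_index = scenario.arms.index(arm)
    n = n_foci if n_foci is not None else scenario.n_foci
    gk = dict(grid_kwargs or {})
    dx = float(gk.get("dx", DEFAULT_PIXEL_SIZE_UM))
    dy = float(gk.get("dy", DEFAULT_PIXEL_SIZE_UM))
    dz = float(gk.get("dz", DEFAULT_Z_STEP_UM))
    nz = int(gk.get("nz", DEFAULT_NZ))
    if nz < 7:
        raise ConfigError("simulated stacks need nz >= 7 for the default ROIs")

    # Resolve the underlying physical parameters realizing the arm's folds.
    if arm.is_morphometry:
        sigma_scale, photon_scale = solve_morphometry_scaling(
            optics.sigma_xy, optics.sigma_z, dx, dy, dz,
            arm.fwhm_fold, float(arm.peakheight_fold))  # type: ignore[arg-type]
    else:
        sigma_scale, photon_scale = arm.fwhm_fold, arm.intensity_fold
    sigma_xy_arm = optics.sigma_xy * sigma_scale
    mean_photons = scenario.baseline_photons * photon_scale

    # Shared brightness quantile stream (see docstring).
    rng_q = np.random.default_rng(np.random.SeedSequence([seed, _QUANTILE_STREAM]))
    quantiles = rng_q.standard_normal(n)
    if arm.cv > 0:
        mu, sig = _lognormal_params(mean_photons, arm.cv)
        photons = np.exp(mu + sig * quantiles)
    else:
        photons = np.full(n, mean_photons)

    rng_pos = np.random.default_rng(np.random.SeedSequence([seed, _POSITION_STREAM, arm_index]))
    if arm.width_cv > 0:
        mu_w, sig_w = _lognormal_params(1.0, arm.width_cv)
        width_mult = np.exp(mu_w + sig_w * rng_pos.standard_normal(n))
    else:
        width_mult = np.ones(n)

    # pair_offset 4 px (1.6 um between sister foci, short for an anaphase
    # spindle) keeps the pair >= 7 px apart under +-0.5 px jitter, safely
    # beyond the default 5 px detection suppression radius; margin 20 px
    # leaves room for background shells out to a gap distance of ~8 px
    shape, nominal = _field_layout(n, nz, margin=20, spacing=26, pair_offset=4)
    jitter = rng_pos.uniform(-0.5, 0.5, size=(n, 3))

    channels: dict[str, VoxelGrid] = {}
    records: list[dict] = []
    for ch_index, (ch, fraction) in enumerate(arm.channels.items()):
        values = np.full(shape, float(optics.bg_level))
        if optics.bg_gradient is not None:
            gy, gx = optics.bg_gradient
            yy = np.arange(shape[1]) - (shape[1] - 1) / 2.0
            xx = np.arange(shape[2]) - (shape[2] - 1) / 2.0
            values += gy * yy[None, :, None] + gx * xx[None, None, :]
            values = np.maximum(values, 0.0)
        grid = VoxelGrid(values, dx=dx, dy=dy, dz=dz, channel=ch)
        for i, (cell, z0, y0, x0) in enumerate(nominal):
            center = (z0 + jitter[i, 0], y0 + jitter[i, 1], x0 + jitter[i, 2])
            render_focus(grid, center, photons[i] * fraction,
                         sigma_xy_arm * width_mult[i], optics.sigma_z)
            records.append({
                "focus_id": f"{arm.label}_{ch}_{i:04d}", "cell_id": cell,
                "z": center[0], "y": center[1], "x": center[2],
                "photons": photons[i] * fraction,
                "sigma_xy_um": sigma_xy_arm * width_mult[i],
                "channel": ch, "genotype": arm.label,
            })
        noise_seed = int(np.random.SeedSequence(
            [seed, _NOISE_STREAM, arm_index, ch_index]).generate_state(1)[0] & 0x7FFFFFFF)
        channels[ch] = apply_noise(grid, optics, noise_seed)
    truth = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)
    return channels, truth


def simulate_field(scenario: GenotypeScenario, optics: OpticsModel | None = None,
                   seed: int | None = None, n_foci: int | None = None,
                   ) -> dict[str, tuple[dict[str, VoxelGrid], pd.DataFrame]]:
    """Simulate every arm of a scenario.

    Returns ``{arm label: (channel grids, ground-truth table)}``.  Identical
    (scenario, optics, seed) inputs produce bit-identical output.
    """
    if seed is None:
        seed = scenario.seed if scenario.seed is not None else 0
    return {arm.label: simulate_arm(scenario, arm, optics, seed, n_foci)
            for arm in scenario.arms}


# ---------------------------------------------------------------------------
# Morphometry forward-model inversion
# ---------------------------------------------------------------------------

def _gl_offsets(n_nodes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre quadrature of the uniform(-0.5, 0.5) sub-voxel offset."""
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    return 0.5 * nodes, 0.5 * weights


def _noiseless_morphometry(sigma_xy: float, sigma_z: float,
                           dx: float, dy: float, dz: float) -> tuple[float, float]:
    """Mean fitted (FWHM px, peak height per photon) of a noiseless focus,
    averaged over the generator's uniform sub-voxel offset distribution.

    Runs the actual patch-extraction + 1D-fit pipeline on ideal renders, so
    the result includes every systematic of the measurement (voxel
    integration, border-median background, 5-point fitting).
    """
    from .morphometry import extract_patch, fit_gaussian_1d

    nodes, weights = _gl_offsets(3)
    photons = 10000.0
    nzc, nyc, nxc = 9, 15, 15
    fwhm_acc = 0.0
    height_acc = 0.0
    wsum = 0.0
    sqrt8ln2 = 2.0 * math.sqrt(2.0 * math.log(2.0))
    for oz, wz in zip(nodes, weights):
        for oy, wy in zip(nodes, weights):
            for ox, wx in zip(nodes, weights):
                grid = VoxelGrid(np.zeros((nzc, nyc, nxc)), dx=dx, dy=dy, dz=dz)
                center = (nzc // 2 + oz, nyc // 2 + oy, nxc // 2 + ox)
                render_focus(grid, center, photons, sigma_xy, sigma_z)
                peak = np.unravel_index(int(np.argmax(grid.values)), grid.shape)
                profile = extract_patch(grid, peak)
                fit_r = fit_gaussian_1d(profile.row_sums)
                fit_c = fit_gaussian_1d(profile.col_sums)
                if not (fit_r.converged and fit_c.converged):
                    raise ConfigError(
                        "noiseless calibration fit failed; PSF width outside the "
                        "range the 5-px patch can measure")
                w = wz * wy * wx
                fwhm_acc += w * 0.5 * sqrt8ln2 * (fit_r.d + fit_c.d)
                height_acc += w * 0.5 * ((fit_r.b - fit_r.a) + (fit_c.b - fit_c.a))
                wsum += w
    return fwhm_acc / wsum, (height_acc / wsum) / photons


@lru_cache(maxsize=64)
def solve_morphometry_scaling(sigma_xy: float, sigma_z: float,
                              dx: float, dy: float, dz: float,
                              fwhm_fold: float, peakheight_fold: float,
                              ) -> tuple[float, float]:
    """Solve the (PSF width scale, photon scale) that realize target folds of
    the *fitted* marginal FWHM and peak height relative to the control PSF.

    A single 3D Gaussian cannot simultaneously match independently chosen
    intensity, height and width folds, so morphometry arms are parameterized
    by the two observables the size analysis reports: the lateral PSF s.d. is
    found by root-finding (Brent) so the jitter-averaged fitted FWHM fold
    equals ``fwhm_fold``, then the amplitude is scaled linearly so the fitted
    height fold equals ``peakheight_fold``.
    """
    from scipy.optimize import brentq

    base_fwhm, base_height = _noiseless_morphometry(sigma_xy, sigma_z, dx, dy, dz)
    if math.isclose(fwhm_fold, 1.0, abs_tol=1e-12):
        scale = 1.0
        mut_height = base_height
    else:
        def objective(s: float) -> float:
            f, _ = _noiseless_morphometry(sigma_xy * s, sigma_z, dx, dy, dz)
            return f / base_fwhm - fwhm_fold

        scale = brentq(objective, 0.4, 4.0, xtol=1e-4)
        _, mut_height = _noiseless_morphometry(sigma_xy * scale, sigma_z, dx, dy, dz)
    photon_scale = peakheight_fold / (mut_height / base_height)
    return float(scale), float(photon_scale)


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

def _intensity_arms(legend: list[tuple[str, float, float]],
                    channel: str = "GFP") -> tuple[ArmSpec, ...]:
    """Arms from legend-style (label, mean, sd) triples; cv = sd / mean."""
    return tuple(
        ArmSpec(label=label, intensity_fold=mean, cv=sd / mean,
                channels={channel: 1.0})
        for label, mean, sd in legend
    )


def scenario_library() -> dict[str, GenotypeScenario]:
    """Named scenario presets.

    Effect sizes (fold-changes and population CVs) come from the source
    study's figure legends, which report control-normalized mean +- sd per
    genotype arm; each preset's ``source`` names the panel it emulates.
    """
    lib: dict[str, GenotypeScenario] = {}

    def add(s: GenotypeScenario) -> None:
        lib[s.name] = s

    add(GenotypeScenario(
        name="wt_reference",
        arms=(ArmSpec(label="wild_type", intensity_fold=1.0, cv=0.2),),
        source="control definition: all folds 1"))

    add(GenotypeScenario(
        name="fig2a_psh1del",
        arms=_intensity_arms([("wild_type", 1.00, 0.25), ("psh1del", 1.83, 0.57)]),
        source="Fig 2A: Cse4-GFP, wild type 1.00+-0.25 vs psh1del 1.83+-0.57"))

    add(GenotypeScenario(
        name="fig2c_psh1del",
        arms=_intensity_arms([("wild_type", 1.00, 0.18), ("psh1del", 1.35, 0.25)]),
        source="Fig 2C: Mif2-GFP, wild type 1.00+-0.18 vs psh1del 1.35+-0.25"))

    add(GenotypeScenario(
        name="fig3c",
        kind="morphometry",
        arms=(
            ArmSpec(label="wild_type", peakheight_fold=1.0, fwhm_fold=1.0, cv=0.22),
            ArmSpec(label="psh1del", peakheight_fold=1.71, fwhm_fold=1.16,
                    cv=0.53 / 1.71),
        ),
        source="Fig 3C: Cse4-GFP focus size; peak height 1.00+-0.22 vs 1.71+-0.53, "
               "FWHM 1.00+-0.23 vs 1.16+-0.32"))

    add(GenotypeScenario(
        name="fig4d",
        arms=_intensity_arms([
            ("wild_type", 1.00, 0.14), ("psh1del", 1.04, 0.13),
            ("ubr2del", 1.05, 0.16), ("psh1del_ubr2del", 1.28, 0.21),
        ], channel="CFP"),
        source="Fig 4D: Mtw1-CFP, wild type 1.00+-0.14, psh1del 1.04+-0.13, "
               "ubr2del 1.05+-0.16, psh1del ubr2del 1.28+-0.21"))

    add(GenotypeScenario(
        name="fig5a",
        arms=_intensity_arms([
            ("wild_type", 1.00, 0.14), ("psh1del", 1.04, 0.18),
            ("ubr2del", 1.07, 0.24), ("psh1del_ubr2del", 1.24, 0.20),
        ], channel="YFP"),
        source="Fig 5A: Mtw1-YFP, DSN1 wild-type allele; psh1del ubr2del 1.24+-0.20"))

    add(GenotypeScenario(
        name="fig5b_dsn1dd",
        arms=_intensity_arms([
            ("wild_type", 1.00, 0.15), ("psh1del", 1.08, 0.16),
            ("ubr2del", 1.19, 0.24), ("psh1del_ubr2del", 1.48, 0.27),
        ], channel="YFP"),
        source="Fig 5B: Mtw1-YFP, dsn1-S240D/S250D allele; psh1del ubr2del 1.48+-0.27"))

    add(GenotypeScenario(
        name="fig6c_meiosis1",
        arms=_intensity_arms([
            ("wild_type", 1.00, 0.15), ("psh1del", 1.05, 0.20),
            ("ubr2del", 1.19, 0.21), ("psh1del_ubr2del", 1.35, 0.26),
        ], channel="CFP"),
        source="Fig 6C: Mtw1-CFP, meiosis I; psh1del ubr2del 1.35+-0.26"))

    add(GenotypeScenario(
        name="fig6d_meiosis2",
        arms=_intensity_arms([
            ("wild_type", 1.00, 0.14), ("psh1del", 1.11, 0.16),
            ("ubr2del", 1.07, 0.20), ("psh1del_ubr2del", 1.18, 0.16),
        ], channel="CFP"),
        source="Fig 6D: Mtw1-CFP, meiosis II; psh1del ubr2del 1.18+-0.16"))

    add(GenotypeScenario(
        name="fig1b_dualtag",
        kind="dualtag",
        arms=(
            ArmSpec(label="haploid_yfp", channels={"YFP": 1.0}, cv=0.2),
            ArmSpec(label="haploid_cfp", channels={"CFP": 1.0}, cv=0.2),
            ArmSpec(label="dualtag", channels={"YFP": 0.5, "CFP": 0.5}, cv=0.2),
        ),
        source="Fig 1B: endogenous Mtw1-YFP + ectopic Mtw1-CFP compete; each tag "
               "contributes ~50% of the matching haploid single-tag signal"))

    add(GenotypeScenario(
        name="fig1d_ploidy",
        arms=(
            ArmSpec(label="haploid", intensity_fold=1.0, cv=0.2, channels={"YFP": 1.0}),
            ArmSpec(label="diploid", intensity_fold=2.0, cv=0.2, channels={"YFP": 1.0}),
        ),
        source="Fig 1D: Mtw1 focus intensity tracks chromosome number "
               "(diploid ~2x haploid; nominal ploidy scaling)"))

    return lib


def get_scenario(name: str) -> GenotypeScenario:
    """Look up a preset by name; raises :class:`ConfigError` if unknown."""
    lib = scenario_library()
    if name not in lib:
        raise ConfigError(f"unknown scenario preset {name!r}; "
                          f"known: {', '.join(sorted(lib))}")
    return lib[name]
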