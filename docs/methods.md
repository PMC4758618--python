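# Methods

## Scope and model

`kinquant` quantifies diffraction-limited kinetochore foci in 3D widefield
z-stacks of budding yeast. The pipeline has four stages — detection,
dual-ROI intensity quantitation, marginal-sum Gaussian morphometry,
population statistics — plus a synthetic-stack generator that emulates the
imaging regime the measurement was designed for and plants known effect
sizes, so recovery can be verified against ground truth. All population
results are folds versus a control arm; absolute intensities never leave
the per-focus tables.

## Imaging geometry and ROIs

Default voxel geometry: 0.205 × 0.205 µm lateral pixels, 17 z-slices at
0.4 µm (voxel volume 0.016810 µm³). The kinetochore ROI is a concentric
box of 81 voxels = 1.3616 µm³, matching the procedure's printed 1.36 µm³.
At this voxel size both 3 × 3 px × 9 slices and 9 × 9 px × 1 slice factor
the same volume; the default is 3 × 3 × 9 (0.615 × 0.615 × 3.6 µm) because
it spans the axial extent of a diffraction-limited focus across slices as a
genuinely 3D region; the flat variant is available through
`RoiGeometry(box_dims=(1, 9, 9))`.

The printed background volume, 23.51 µm³, is not an integer multiple of
the voxel volume for any concentric box, so the background region is
defined as a fixed-count shell: the N = round(23.51/0.016810) = 1399
voxels nearest the center in anisotropic Euclidean distance (µm) that lie
outside the kinetochore box dilated by the gap distance (default 2 px),
distance ties broken lexicographically by (z, y, x) offset. Its volume,
23.517 µm³, is within 0.03% of the printed figure. The shell reaches ±4
slices axially and ±9 px laterally at the default gap; the ROI
construction raises a named out-of-bounds error if either set would cross
the stack boundary. The per-focus measurement is mean(box) − mean(shell);
negative values are kept so population means stay unbiased. Offset
invariance and scale equivariance of this statistic are exact and tested.

## Detection

The original analysis used a proprietary "brightest spots" routine, which
is unspecified; the implementation here is deterministic and
oracle-verifiable: Gaussian pre-smoothing at σ = 1 voxel, candidate set =
26-neighborhood local maxima that exceed at least one neighbor (so
constant regions produce nothing), ranked by descending smoothed intensity
with lexicographic (z, y, x) tie-breaks, greedy acceptance with Euclidean
non-maximum suppression at 5 voxels, and removal of peaks within 3 voxels
of any boundary. The suite checks exact equivalence with an exhaustive
brute-force implementation on random grids. For simulated fields the
candidate count is capped at the planted focus count; for real images an
absolute threshold on smoothed intensity is exposed instead.

## Morphometry

Focus size is measured exactly as the marginal-sum procedure prescribes:
5 × 5 patch at the z-slice of the peak voxel (the source procedure does not
state the plane; the peak slice maximizes signal and is deterministic),
local background subtracted, row/column sums fit per axis with
y = a + (b − a)·exp(−(x − c)²/2d²), FWHM = 2√(2 ln 2)·d averaged over the
two axes, peak height = mean(b − a). The local background definition is
also unstated; the median of the patch's 16 border pixels is used because
it is robust and uses only in-patch data. Five points constrain four
parameters weakly, so the fit is bounded (0.3 ≤ d ≤ 5 px, c inside the
window) and any non-converged or bound-pinned fit excludes the focus from
population summaries with a logged count — exclusion over clamping avoids
silent bias. Observed failure rates in the default noisy scenarios are
below 2%.

## Synthetic data

Foci are anisotropic 3D Gaussians integrated exactly per voxel via
per-axis error-function differences (point sampling would misstate coarse
voxels by several percent at the default PSF). PSF defaults σ_xy = 0.12 µm,
σ_z = 0.35 µm approximate a diffraction-limited 1.4 NA widefield system.
Fields are laid out as a lattice of "cells" 26 px apart with a 20 px
border, two sister foci per cell 8 px (1.6 µm) apart along x — short for a
post-anaphase spindle but safely above the 5 px suppression radius under
the ±0.5-voxel uniform position jitter each focus receives. Per-focus
brightness is lognormal (intensities are positive and the legend spreads
right-skewed), with the arm mean set by the planted fold and the CV taken
from the corresponding legend's sd/mean. The camera model adds Poisson
photon noise and Gaussian read noise, clips at the 16-bit ceiling and
quantizes.

Absolute scale is arbitrary because no photon counts or gain are reported
for the original system: baseline 5000 photons/focus over a diffuse
background of 100 counts with read noise 2 counts, giving peak-voxel SNR
far above the detection floor. Every quantity the package reports is a
ratio, so this choice drops out.

Two generator design points deserve emphasis:

* **Observable parameterization of morphometry scenarios.** The real
  enlarged-focus phenotype is not a single Gaussian — intensity 1.83×,
  height 1.71× and FWHM 1.16× are mutually inconsistent for one 3D
  Gaussian — so intensity scenarios plant an intensity fold at unchanged
  width, and morphometry scenarios plant the two observables the size
  analysis reports. For the latter, the generator inverts its own forward
  model: Brent root-finding on the lateral PSF s.d. until the noiseless
  fitted FWHM fold (averaged over a Gauss–Legendre quadrature of the
  uniform sub-voxel offset distribution, running the actual patch/fit
  code) equals the target, then linear scaling of the amplitude to hit the
  fitted peak-height fold. This makes "planted fold" mean exactly what the
  pipeline measures, including voxel-integration and border-median
  systematics.
* **Common random numbers across arms.** The arms of one scenario share
  the standard-normal quantile stream behind their brightness draws (with
  arm-specific lognormal parameters), while positions and camera noise use
  arm-independent streams. Each arm's marginal distribution is exactly its
  stated lognormal; the between-arm fold estimate, however, is insulated
  from finite-sample drift of the arm means, so recovered folds measure
  pipeline bias rather than sampling luck. The induced positive
  correlation between arms makes the Welch test, if anything,
  conservative in its nominal interpretation, and the planted separations
  are large enough that significance calls are unaffected.

What the generator does **not** emulate: per-focus width variability
(arm widths are deterministic unless `width_cv` is set, so simulated FWHM
population SDs are narrower than real ones — fold-changes of means are
unaffected), cell outlines and cytoplasmic autofluorescence structure,
optical aberrations or a vectorial PSF, photobleaching, z-dependent
background, and the manual selection of post-anaphase cells (simulated
fields contain only the foci the original curation would have kept; on
real data the user supplies the curated focus list). Passing tests
therefore demonstrate correctness of the measurement procedure under the
stated statistical structure, not robustness to every real-microscopy
artifact.

## Statistics

Arms are summarized as mean ± sample sd (n − 1) of control-normalized
values, formatted to two decimals as in the source legends. The comparison
is a two-sided two-sample t test; Welch's unequal-variance form is the
default because the arm SDs differ markedly (e.g. 0.25 vs 0.57), with the
pooled Student variant behind a flag. Only "t test" is stated in the
source convention, and no multiple-testing correction is applied there, so
none is applied here; the single significance marker is *** at p < 10⁻⁴.
The degenerate zero-variance/equal-means case returns t = 0, p = 1. Tests
are per focus, matching the plotted distributions. Copy-number arithmetic
uses 6.5 MIND complexes per anaphase kinetochore (midpoint of the 6–7
estimate) and reports round(baseline × (fold − 1)) additional complexes,
half-away-from-zero.

## Problem sizes and numerics

Scenario runs default to 150 foci per arm (the scale of the per-panel
populations), which the acceptance script uses throughout; unit and
property tests use 10–100 foci and grids up to 32³ where exhaustive
oracles are feasible. Gaussian-fit tolerances are xtol = ftol = gtol =
1e-12; detection tie-breaks and shell distance ties are lexicographic;
all randomness flows from integer seeds through `numpy` `SeedSequence`
streams, so identical configurations reproduce stacks and tables
bit-exactly.

## Known limitations

Real stacks must be accompanied by curated focus lists when the
post-anaphase selection matters; the fixed-count background shell is one
reasonable reading of the printed 23.51 µm³ (whether the original volume
was voxel-count-derived is unrecoverable); sub-voxel localization is out
of scope at the detection stage (morphometry's fitted center c refines
laterally but is not fed back); and the simulator's population model is
deliberately minimal, as described above.
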