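# Methods

`petrelease` simulates a complete reference-tissue PET neurotransmitter-
release experiment and analyses it with the standard voxelwise methods.
This note records the models, the default parameters and why they were
chosen, the numerical choices, and what the synthetic data do and do not
represent.

## Kinetic model

Tissue kinetics follow the reversible two-tissue compartment model
(2TCM).  With plasma input Cp(t), free/non-specific concentration C1 and
specifically bound concentration C2:

    dC1/dt = K1 Cp - (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 - k4 C2
    C_PET  = (1 - VB)(C1 + C2) + VB C_blood

Macro-parameters: VND = K1/k2, BP_ND = k3/k4, VT = VND(1 + BP_ND),
DVR = BP_ND + 1.

The solution is evaluated in closed form: the 2x2 rate matrix is
eigen-decomposed and each exponential mode is convolved with the input
*exactly* for a piecewise-linear input (per-segment analytic integration,
no FFT, so there is no grid aliasing).  When the two eigenvalues coincide
(gap < 1e-10 min^-1) the limiting kernel `t e^{-theta t}` is used; its
per-segment weights are obtained by complex-step differentiation of the
regular weights, which is exact to machine precision.  A unit test and
the acceptance script verify the closed form against an adaptive stiff
ODE integrator (`scipy.integrate.solve_ivp`, LSODA, rtol 1e-10) to better
than 1e-6 relative error over 90 minutes for 100 random parameter sets.

**Plasma input.** Measured blood data are neither needed (the analysis is
reference-tissue only) nor modelled.  The input is an analytic
linear-rise/tri-exponential bolus,
`Cp = [A1(t-t0) - A2 - A3] e^{-l1(t-t0)} + A2 e^{-l2(t-t0)} + A3 e^{-l3(t-t0)}`,
with defaults A1 = 850 kBq mL^-1 min^-1, A2 = 21, A3 = 20 kBq mL^-1,
l1 = 4.1, l2 = 0.12, l3 = 0.01 min^-1, t0 = 0.5 min: a sharp peak ~1 min
post-injection and a slow washout, plausible for a carbon-11 ligand over
90 min.  Whole blood is taken equal to plasma; metabolites, parent
fraction and dispersion are out of scope.

## Ground-truth phantom

The phantom is procedural (no subject data): a head-scale ellipsoid
containing a grey-matter shell, a white-matter core and a distinct
inferior-posterior reference structure.  Structural constraints make the
full reference tissue model hold *exactly*:

* k3 = 0 everywhere in the reference region (and in white matter, which
  follows one-tissue kinetics);
* k4 (default 0.06 min^-1), VB (0.05) and VND = K1/k2 (2.0) constant
  across all brain voxels;
* grey-matter BP_ND is a Gaussian random field (FWHM 8 mm) with mean 1.3,
  sd 0.45, clipped to [0.3, 2.6] — the graded range of the displacement
  design; K1 (grey 0.35, white 0.18, reference 0.33 mL cm^-3 min^-1)
  carries a milder 15% texture.

`validate()` asserts these invariants on every build.  Pseudo-subjects
re-seed the random texture while sharing anatomy and regions.

**Displacement regions.** Six regions with target volumes
{2555, 2275, 1152, 493, 343, 418} mm^3, displacement fractions
{27, 27, 21, 18, 18, 18}% and graded baseline BP_ND targets
{1.39, 1.65, 0.78, 1.16, 2.02, 0.67} are grown by seeded stochastic
region growing (6-connected, per-region anisotropy jitter, growth seeds
biased toward voxels whose local BP matches the baseline target), so they
are connected, non-geometric, pairwise disjoint with a one-voxel margin,
inside cerebral grey matter and never adjacent to the reference region.
Voxel counts hit the volume targets within 2%.  Displacement scales k3 by
(1 - Delta) inside each region: with uniform k4 this lowers BP_ND by
exactly Delta while the pre/post dynamic data remain kinetically
consistent.  Composition behaves multiplicatively
(Delta then Delta' == 1-(1-Delta)(1-Delta')).

**Median filtering.** The 4 mm median filter used for outlier suppression
is implemented as a masked sliding-window median: the window sees only
brain voxels, so the zero background cannot bleed inward and the
uniformity invariants survive filtering exactly.

## Acquisition and reconstruction

**Protocol.** 23 frames (4x15 s, 4x60 s, 2x150 s, 10x300 s, 3x600 s;
90 min).  TACs are computed on a 1 s grid, multiplied by carbon-11 decay
(half-life 20.34 min) and averaged within frames (verified against a
0.1 s refined grid to 0.1%).

**Scanner model.** A stacked-2D parallel-beam ring: per slice,
`n_angles` views over 180 degrees and `n_radial` bins spanning the
transaxial FOV.  Line integrals are exact Siddon ray traces assembled
once per geometry into a sparse matrix, giving a forward/back-projector
pair whose adjoint identity holds to 1e-10 (machine precision).  Radial
bins are offset half a pixel so axis-aligned rays pass through pixel
centres rather than riding pixel boundaries.  The image-domain resolution
kernel (Gaussian, 2.5 mm FWHM default) is applied before projection and
inside the MLEM projector pair.  Full 3D oblique lines of response,
detector normalisation and dead time are not modelled.

**Noise.** The whole-scan count budget is split as (1 - f_r - f_s)
trues : f_r randoms : f_s scatter with defaults f_r = 0.20, f_s = 0.25.
Expected trues are attenuated by `exp(-int mu dl)` (synthetic
water-equivalent mu-map, 0.0096 mm^-1 inside the head mask), weighted by
frame duration and scaled to the trues budget; randoms are spatially
uniform and allocated across frames by duration; scatter is a 40 mm FWHM
radial blur of the attenuated trues.  Prompts are Poisson per bin per
frame with per-frame child seeds spawned from one master seed.

**Count budget at desk scale.**  The full-scale protocol prescribes
3x10^8 counts for an adult-brain-sized (~1.4e6 mm^3) phantom.  The
`"match_density"` option used by the desk-scale study configuration
scales the budget by the phantom brain volume, preserving the per-volume
count density — and hence the per-voxel noise regime — of the full-scale
experiment.  The plain desk default (3x10^6) is retained for quick smoke
runs.

**MLEM.**  Standard multiplicative update with the PSF-matched projector
pair, known additive (randoms + scatter) expectation in the denominator
forward model, attenuation folded into the system matrix, uniform
initialisation, and zero-sensitivity voxels masked out.  100 iterations
and 2.5 mm PSF reproduce the full-scale protocol; desk-scale runs use 30
iterations.  Verified properties: truth is a fixed point of noise-free
data; the Poisson log-likelihood is non-decreasing; total
forward-projected counts equal total prompts after every iteration (to
1e-6).  Note that MLEM's high-frequency convergence is slow: a sharp
uniform disk converges to ~0.2% *mean* error within 200 iterations but
individual voxels still carry ~7% ripple; voxelwise 2% recovery needs
~2000 iterations.  Reconstructed frames are calibrated back to
concentration units, decay-corrected with frame-integrated factors
`(1/dt) int e^{-lambda t} dt` (exact for the applied decay), and can be
resampled trilinearly between centre-aligned grids.

## Quantification

All methods consume frame-domain data (frame averages at mid-times) and a
reference-region TAC; dynamic input must be decay corrected.

* **SRTM (basis functions).**  `CT = R1 Cref + (k2 - R1 k2a) Cref (x)
  e^{-k2a t}`, BP_ND = k2/k2a - 1.  k2a is scanned over a log-spaced grid
  (default 128 points in [0.01, 1.0] min^-1; 128 keeps the grid ratio at
  1.037 so per-voxel quantisation error stays ~<2%) and the two linear
  coefficients are solved by (optionally weighted) least squares; ties
  take the smallest k2a.  Basis functions are built on a 1 s grid and
  frame-averaged — the same operator that produced the data.
* **Reference Logan.**  OLS on the transform
  `int CT / CT vs (int Cref [+ Cref/k2']) / CT` for frames with mid-time
  >= t* (default 10 min); slope = DVR.  Without k2' the simplified
  transform is used.
* **MRTM2.**  `CT(T) = b1 (int Cref + Cref(T)/k2') + b2 int CT`,
  BP_ND = -(b1/b2) - 1.  The form is exact for SRTM-consistent kinetics
  (integrate the one-tissue ODE and eliminate Cp via the reference
  region).  k2' comes from a 3-parameter MRTM fit of a high-binding
  region (k2' = b1/b2 of that fit); an ill-conditioned design (e.g. the
  reference fitted against itself) is rejected by a condition-number
  check.

Weights: uniform (default) or frame duration x decay.  The analysis mask
keeps voxels whose TAC area exceeds 5% of the reference area unless an
explicit mask is supplied; per-voxel failures are flagged, zeroed and
never abort a map.

On one-tissue-consistent TACs all three methods agree within 2% and
recover BP_ND within 1% (basis grid bracketing the truth).  On the
two-tissue phantom the graphical methods (Logan, MRTM2) sit several
percent *below* SRTM and truth at any t* inside 90 min — the asymptotic
regime of a k4 = 0.06 min^-1 tracer is not reached within the scan.  This
bias, and its noise-induced aggravation for Logan, is a property of the
estimators, not a defect; the package asserts its direction, not its
size.  Region-wise displacement (a pre/post ratio) cancels most of it:
noise-free SRTM recovers the 27/21/18% design values within ~1 point.

## Displacement detection

Displacement is a one-sided reduction (pre > post).  Available tests:

* paired t (df = n-1) on optionally smoothed difference maps; zero-
  variance voxels get t = 0 and p = 1 when the mean is zero, and a capped
  t (1e6) otherwise;
* sign-flipping permutation test with max-T FWE correction and optional
  variance smoothing (pseudo-t).  With n subjects only 2^n sign patterns
  exist; they are enumerated exactly whenever 2^n <= n_perm, making
  p-values multiples of 2^-n (for n = 5: 1/32).

The default pipeline is the classic nonparametric neuroimaging recipe:
8 mm smoothing of the dynamic data before quantification, permutation
max-T with 5 mm variance smoothing, FWE alpha 0.05.  Without variance
smoothing the low-df max-T null is dominated by small-denominator voxels
and sensitivity collapses — which is exactly what the variance smoothing
is for.  Thresholded maps are clustered
(6/18/26-connectivity, default 18) and clusters below the extent
threshold are removed.

## Scoring

Percentage RMSE `100 sqrt(mean((y - yhat)^2)) / mean(yhat)` is computed
per BP map over brain voxels (reported mean +/- sd over the 10 maps, plus
a pooled-voxel variant) and, for displacement, on voxelwise
Delta BP_ND within each region normalised by the mean simulated
displacement (a bias common to both scans cancels exactly).  Overlap is
the Jaccard index TP/(TP+FP+FN) (defined as 1 for two empty masks, with a
warning) plus the FP/TP percentage.  Voxels flagged invalid by
quantification are excluded from RMSE and counted separately.

## The replicated detection study

`challenge.detection_study` runs seeded full-pipeline replicates at desk
scale: a 32x32x22 grid at 3 mm (brain ~0.22e6 mm^3), density-matched
counts (~4.6e7), 30 MLEM iterations, 5 subjects x 2 scans, ROI volume
targets rescaled by voxel volume.  Each replicate is quantified with the
default SRTM pipeline and tested with three representative detection
pipelines (the conservative permutation/FWE variant and two parametric
uncorrected-p + cluster-extent variants), emulating the across-pipeline
variety of a multi-group comparison.  Detection = any overlap between the
final mask and a region.  Pooled over 10 replicates x 3 pipelines the
rates order as ROI 1-2 (~98%) > ROI 3 (~67%) > ROI 4-6 (~11%): the big,
strongly displaced regions are found essentially always, the mid-size
intermediate-displacement region intermittently, and the small
low-displacement regions rarely.

## What the synthetic data are not

The phantom is a geometric stand-in: it has no gyral anatomy, no
between-tissue spatial covariance beyond the smooth random field, an
ideal reference region, an exactly known attenuation map, idealised
randoms/scatter corrections handed to MLEM, and a 2D ring scanner rather
than a 3D cylindrical one.  Passing tests demonstrate the internal
consistency of the machinery and the qualitative behaviour of the
estimators under realistic count densities — not performance on real
scanner data.  Absolute desk-scale error levels (e.g. ~65% RMSE on BP
maps at 3 mm voxels) are specific to the scaled geometry's partial-volume
regime and should not be read as full-scale predictions.

## Numerical details and degenerate inputs

* Exponential-convolution segment weights switch to series expansions for
  theta*dt < 1e-6 (exact running integral at theta = 0).
* The SRTM basis search tie-breaks to the smallest k2a; all-zero TACs,
  singular MRTM2 designs and Logan fits with non-positive late-frame
  values are flagged invalid per voxel.
* MLEM guards: expectation floored at 1e-30 inside the ratio; voxels with
  sensitivity below 1e-12 of the maximum are frozen at zero.
* Double decay correction raises a state error; framing must be
  contiguous from t = 0.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning (per-subject, per-scan, per-frame
  children), so every artifact is exactly reproducible.
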