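# Methods

`plaquekit` implements a quantitative analysis chain linking carotid-plaque
composition, measured by 4-point Dixon MRI, to plaque inflammation, measured
by ^18^F-FDG PET uptake. Because patient image data of this kind are not
openly available, the package ships a digital phantom that generates every
input of the chain with known ground truth; all quantitative guarantees are
stated and tested against that truth.

## Signal model and composition fitting

Each voxel is modelled as a water compartment `W` and a fat compartment `F`
(arbitrary signal units) decaying with a single effective transverse rate
R2\* (s⁻¹). With the water–fat chemical-shift phase cycle of period 2.4 ms
at 3 T, the magnitude signal at echo time `Te` (ms) is

    S(Te) = |W + F·cos(2π·Te/2.4)| · exp(−R2*·Te/1000)

The acquisition samples `Te = 3.6, 7.2, 10.8, 14.4` ms — an out-of-phase /
in-phase / out-of-phase / in-phase scheme (cos = −1, +1, −1, +1). The 2.4 ms
period is the only unit assignment consistent with both that echo scheme and
R2\* reported on the s⁻¹ scale. Proton-density and T1 differences between
water and fat are deliberately not modelled, and no multi-peak fat spectrum
or field map is estimated.

Fat fraction is `FF = F/(W+F)`. Magnitude data cannot distinguish `(W, F)`
from `(F, W)`; voxels are resolved under the water-dominant convention
`W ≥ F` (FF ≤ 0.5), which is the regime of vessel-wall tissue. Exact
`W = F` boundary hits are flagged.

Fitting proceeds in two stages per voxel:

1. **Closed-form initialization.** The in-phase pair gives
   `R2*_in = ln(S₂/S₄)/(T₄−T₂)` and the out-of-phase pair
   `R2*_out = ln(S₁/S₃)/(T₃−T₁)` (times in seconds); the two are averaged,
   negative log-ratios (signal growing with Te, i.e. noise) clamp to 0 with a
   flag. Decay-corrected amplitudes then give `A_in = W+F` and
   `A_out = |W−F|`, hence `W = (A_in+A_out)/2`, `F = (A_in−A_out)/2`.
2. **Bounded refinement.** Trust-region least squares against the forward
   model, bounds `W, F ∈ [0, 10·max signal]`, `R2* ∈ [0, 500] s⁻¹`,
   tolerances 10⁻¹² on cost/step/gradient, analytic Jacobian. Refinement is
   skipped when the initialization already attains the cost tolerance (the
   noiseless case), which keeps full-volume fits fast without changing any
   result beyond that tolerance.

Voxels that are non-finite, all-zero, or whose initialized `W+F` falls below
1% of the volume's robust maximum (99.5th percentile) are marked invalid: FF
is numerically meaningless in air and noise voxels, and only vessel-wall
voxels are ever sampled downstream.

At zero noise the render→fit round trip recovers FF and R2\* to better than
10⁻⁶ relative error; with 2% Rician noise on a voxel at FF 0.2 and R2\*
47.6 s⁻¹, median absolute errors are ≈ 0.01 in FF and ≈ 3.6 s⁻¹ in R2\*
(500-voxel simulation; the test suite enforces < 0.05 and < 5 s⁻¹).

## Digital phantom

The phantom is a straight cylindrical vessel along the slice axis on the
Dixon grid (0.60 × 0.60 × 0.7 mm, 40 × 40 × 36 voxels): a blood-suppressed
lumen (radius 2.5 mm), a 1 mm vessel wall, and an eccentric wall thickening
— the plaque — over a configurable angular sector and slice range. The wall
protrusion defaults to 3 mm and is validated against the clinical plaque
definition (≥ 1.5 mm luminal protrusion). Inside the plaque a lipid-rich
core (FF 0.4 by default) and a hemorrhagic focus (R2\* 90 s⁻¹) occupy
disjoint sub-regions; one-sided smooth jitter fields (SD 0.04 FF,
6 s⁻¹ R2\*) create slice-to-slice heterogeneity while guaranteeing the
configured levels remain attained. The carotid bifurcation is modelled as a
marked slice index used as the landmark for cross-session slice alignment.

Rendered outputs:

* **Dixon series** — exact forward model plus complex Gaussian noise on two
  quadrature channels before the magnitude (Rician), since the fitted
  quantity is a signal magnitude and this stresses the fitter the way real
  magnitude data do.
* **T1-weighted stacks** — per-compartment contrast plus a smooth
  anatomy-fixed texture field (SD 0.06, correlation length ≈ 1 voxel),
  resampled to the stand-alone grid (0.50 × 0.50 × 1.75 mm) or, after
  displacement by a per-seed session transform (≤ 3 mm, ≤ 3°, scale
  0.98–1.02), to the PET/MR grid (0.31 × 0.31 × 2.5 mm). The texture is what
  real soft tissue looks like to an intensity metric; a uniform background
  makes histogram mutual information degenerate (any transform that piles
  background onto background scores well), so the texture is also what makes
  the registration stage well-posed.
* **PET activity** — truth activity convolved with an isotropic Gaussian
  point-spread function (FWHM 3.0 mm, the scanner's effective neck
  resolution; 0 disables the blur for exact checks), displaced into the
  session frame, resampled to the PET grid (1.2 × 1.2 × 2.78 mm), Gaussian
  noise added. Dosing metadata is 3 MBq/kg at a default 75 kg; the default
  blood activity of 3.9 kBq/mL puts true blood SUV at 1.3.

What the phantom does **not** emulate: k-space acquisition, B0/B1
inhomogeneity, flowing blood and saturation slabs, multi-peak fat spectra,
PET reconstruction (it renders post-reconstruction activity directly),
scanner decay correction (SUVs assume scanner-corrected activity), and
anatomical realism beyond a single straight vessel. Passing tests therefore
demonstrate correctness of the *analysis* under controlled truth, not
robustness to every physical confounder of patient data. One visible
consequence: the ~3 mm PSF dilutes both the 2.5 mm lumen and the 3–6 mm
plaque toward background, so rendered blood SUV reads ≈ 1.2 rather than the
true 1.3 and synthetic TBRs sit near 1 — the partial-volume underestimation
the clinical literature describes, which this chain intentionally does not
correct.

## Registration

The manual plaque segmentation lives on a T1W grid and must be carried onto
the Dixon grid; the stand-alone and PET/MR sessions are related by an
unknown nonreflective similarity transform (translation, rotation, isotropic
scale > 0, 7 parameters with rotation as extrinsic x-y-z Euler angles about
the fixed-image centre).

* **Metric** — mutual information of the 32 × 32 joint intensity histogram
  over the post-transform overlap, moving image resampled trilinearly, bin
  edges spanning each image's global range (so binning does not drift with
  the transform). An empty overlap scores −∞; masks are never interpolated
  with anything but nearest-neighbour.
* **Optimizer** — a (1+1) evolution strategy: Gaussian mutation of the
  7-vector (step scales 1 mm / 1° / 0.02 log-scale per unit radius), accept
  on MI improvement, radius × 1.05 on success and × 0.98 on failure, stop at
  radius < 10⁻⁴ or the iteration budget (default 2000 total). Deterministic
  for a fixed seed.
* **Two-level search** — a coarse pass on smoothed, in-plane 2×-downsampled
  images widens the capture range; the slice axis keeps full resolution
  because carotid stacks are thin (order 10 slices) and through-plane
  rotations are only observable if the slice sampling survives. Two
  independent coarse starts guard against wrong-basin capture, and when the
  radius collapses with budget remaining the strategy re-anneals from the
  current best at half the previous radius.
* **Metric presmoothing and axis sweeps** — at full resolution both images
  are Gaussian-presmoothed (0.75 voxel) for the metric only: histogram MI
  otherwise develops a spurious optimum at grid-aligned transforms, where
  the moving image is resampled almost without trilinear blur and so looks
  artificially sharp. After the strategy converges, deterministic 13-point
  1-D sweeps refine the scale and the two through-plane rotation
  parameters — the axes that joint 7-parameter mutation explores worst,
  because an improving step along them is usually vetoed by its
  simultaneous translation noise — followed by a short re-anneal. These
  search-policy choices are declared defaults of this implementation, all
  exposed in `RegistrationConfig`.

On the phantom, ≥ 90% of random perturbations within ± 5 mm, ± 5°, scale
0.95–1.05 are recovered within 1 voxel and 1°, and the session mask carried
onto the Dixon grid through a recovered transform overlaps the truth mask
with Dice ≥ 0.8 (typically ≈ 0.95). Where an automatic solution needs
rescue, `RegistrationConfig.initial_transform` is the non-interactive
replacement for the visual-inspection-and-correction step of a clinical
workflow.

Cross-session slice pairing anchors both stacks at the bifurcation slice and
maps each source slice to the nearest target slice centre in
millimetres-from-landmark, ties broken toward the landmark; source slices
beyond the target extent by more than half a target slice are dropped.

## ROI sampling

Before any statistic, each in-mask voxel of a quantitative map is replaced
by the mean of its *immediate neighbours within the mask*. "Immediate" is
read as the 26-connected neighbourhood including the voxel itself — the
self-inclusive reading guarantees a defined value for isolated voxels, and
26-connectivity matches the isotropic intent; both are config-switchable
(6/18/26, with/without self) because the source procedure does not pin them
down. Only per-slice means and the whole-mask mean enter the analysis. The
whole-mask mean is voxel-weighted (a plain mean over mask voxels); the
mean-of-slice-means alternative is exposed as an option since either reading
of "whole mask average" is defensible. For PET, by contrast, the
whole-plaque SUV_mean follows the published slice-first order: mean SUV per
plaque slice, then the unweighted mean over slices.

## PET quantification

`SUV = activity · body_weight / injected_dose` (kBq/mL, kg, MBq — the unit
factors cancel under the 1 g/mL tissue-density convention). Decay correction
is assumed already applied by the scanner; uptake time is carried as
metadata only. The venous blood pool is the mean of exactly six point
samples (nearest-voxel lookups; a sphere-averaging radius is available as an
option), and `TBR = plaque SUV_mean / blood-pool SUV_mean`. On the published
12-patient table, recomputing TBR from the printed plaque and blood
SUV_means reproduces every printed value within 0.02 — the residual up to
0.013 is consistent with the original ratios having been formed from
unrounded SUVs — and the group summary reproduces 1.49 ± 0.48.

## Statistics

Associations are Pearson product-moment correlations with two-sided
p-values from `t = r·√((n−2)/(1−r²))` on n−2 degrees of freedom, plus the
least-squares line. A permutation p-value (default 10⁵ permutations,
add-one corrected) is the distribution-free cross-check; at n = 12 the two
agree within Monte-Carlo error plus a 0.01 allowance for the t-vs-
permutation approximation gap. Group vectors are summarized as mean ± SD
(n−1). No multiple-testing correction is applied across the correlation
family, matching the source analysis; reports print both r and r² so either
thresholding convention can be read off. Subjects with fewer than 3 slices
keep their profiles but get no per-subject correlation.

The end-to-end null guarantee: a 12-subject synthetic cohort whose uptake
parameters are drawn independently of its composition parameters must yield
group |r| inside the n = 12 two-sided 95% null band (|r| < 0.576). The
clinical study's printed group coefficients (−0.406 and 0.259) lie inside
that band — consistent with its reported absence of significant correlation
— and the per-patient group means it reports (FF 0.17, R2\* 47.6 s⁻¹)
cannot be recomputed without its unavailable per-slice tables, so parameter
recovery is instead guaranteed on phantom truth as above.

## Problem sizes and determinism

Default problem sizes are chosen to keep any single check under a few
minutes on one core: phantom grids of 40 × 40 × 36 (Dixon), 48 × 48 × 14 /
77 × 77 × 10 (T1W) and 20 × 20 × 9 (PET) voxels; 500-voxel noise
simulations; 20-perturbation registration studies; 12-subject cohorts;
10⁵-permutation oracles; 1000-draw type-I calibrations. Every stochastic
component takes an explicit seed (NumPy `default_rng`), and all renderers
and fitters are bit-deterministic given (config, seed).

## Known limitations

* Magnitude-only Dixon: FF is capped at 0.5 by the water-dominant
  convention; a genuinely fat-dominant voxel would be reported mirrored.
* The single-R2\* assumption biases voxels containing mixed compartments
  with very different decay rates.
* The registration metric uses a full joint histogram, not B-spline Parzen
  windows; on piecewise-smooth anatomy the difference is immaterial, but
  gradients are not available and optimization is derivative-free.
* Blood-pool sampling by six points inherits the variance of point lookups;
  the sphere-averaging option trades bias for variance.
* The phantom's session transform is drawn from a bounded range
  (≤ 3 mm, ≤ 3°); pathological misalignments far outside the clinical range
  would need an initial transform.
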