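# Methods

This note records the models, parameter choices and limitations behind
`jacint`, in the order the pipeline runs them.

## The measurement model

A pair of T1-weighted volumes of one subject is related by a composition of
(i) a world affine `A` (head pose plus scanner calibration error) and (ii) a
small nonlinear deformation carrying the biology. The package separates the
two: `A` is estimated from structures that do not atrophy (the skull) and is
*excluded* from the reported volume change by default; only the nonlinear
field is integrated. A config switch (`MeasureConfig.include_affine`)
multiplies the affine determinant back in for users who consider the linear
part biological.

The volume change of a region `R` under a mapping `x → x + u(x)` is
`∫_R detJ dx` with `detJ = det(I + ∇u)`; the percent volume change reported
is the mean of `detJ` over the baseline GM mask, minus one, times 100. The
determinant is computed by central differences in millimetres (one-sided at
grid boundaries; the one-voxel boundary shell is excluded from integration
masks). Grids are axis-aligned RAS with diagonal affines; the Jacobian code
assumes this.

Annualization divides PVC by the interval in years (a compound-rate option
exists: `100·((1+PVC/100)^(1/Δt)−1)`); the difference is negligible at the
sub-percent changes this instrument targets.

## Phantoms and their ground truth

The synthetic head is a nest of ellipsoids — skull shell, subarachnoid CSF,
cortical GM ribbon, WM core, central CSF ventricle — with per-tissue
Gaussian intensities (defaults CSF 30, GM 70, WM 100, skull 90, SDs 0).
Geometry is analytic, so masks and volumes are exact and the generator
needs no external data. Defaults: 96³ voxels at 1 mm isotropic (the
high-resolution acquisition regime; thick-slice axial data are emulated by
`degrade_resolution`, box-averaging to e.g. 1×1×3 mm).

Atrophy is applied as a closed-form deformation:

- `global_scale`: uniform scale `s = (1+p/100)^(1/3)` about the head
  center; `detJ = 1+p/100` everywhere.
- `radial_gm`: in ellipsoid-normalized coordinates `z = D(x−c)`, `r = |z|`,
  a radial map `r → h(r) = r − β·w(r)` with a compact-support C¹ bump
  `w` that is zero (with zero slope) at the WM/GM boundary and at the
  skull, and peaks at the GM/CSF boundary: the WM core and skull stay
  fixed, the cortical surface moves inward, CSF expands. The determinant
  is `h'(r)·(h(r)/r)²` (invariant under the ellipsoid conjugation), and
  the amplitude `β` is calibrated by 1-D root finding so the mean analytic
  `detJ` over the GM label equals the target to < 1e-10. The follow-up
  image is generated through the *exact inverse* map (Newton solution of
  `h(r) = r'`), so no numerical field inversion enters the ground truth.

True per-tissue PVCs are recorded from the analytic determinant at voxel
centers — the same quadrature `integrate_pvc` uses, so oracle comparisons
are apples-to-apples. Corruption models: multiplicative `exp` of a
Gaussian random field low-passed at 40 mm (amplitude = SD of the log-bias);
additive Gaussian or Rician noise; non-overlapping hypointense WM spheres
(label 4) for lesions; a windowed-sinc resampled uniform scale about the
head center for scanner miscalibration.

What the phantom does *not* emulate: cortical folding (boundary curvature
is far lower than real cortex, so partial-volume and curvature-related
segmentation errors are under-represented), multi-contrast acquisitions,
motion/ghosting artifacts, and pathology-driven intensity change (T1
hypointensity evolution). Passing phantom gates therefore demonstrates the
*numerical* fidelity of the chain — registration, resampling, Jacobian
algebra, calibration — not robustness to real anatomical variability.

## Affine machinery

NMI `(H(A)+H(B))/H(A,B)` uses a 64-bin joint histogram over in-mask voxels
with bin edges frozen per registration (smoothness of the cost). The staged
search (rotations → translation → multi-start global scale {0.95, 1.0,
1.05} → scales+shears; Nelder–Mead, `xatol` 1e-4, `fatol` 1e-6, ≤400
iterations per stage) runs on a coarsened copy (≤48 voxels per axis,
Gaussian presmoothed) for speed; every stage must not worsen NMI or it is
reverted with a warning.

Coarse NMI on piecewise-constant imagery locates the scale optimum only to
~0.1%, which is an order of magnitude too coarse for a 0.1-pp volume
budget (0.1% linear ≈ 0.3% volume). The final translation/scale/shear are
therefore polished at full resolution by minimizing the mean squared
intensity difference over the evaluation region (mildly smoothed,
mean-normalized); on phantoms this lands within ~0.05% of the true scale.
The skull-constrained variant (`pairreg_like`) freezes the 6-dof rigid
stage estimated over brain NMI, then estimates global scale and
scales/shears over a dilated skull mask, and polishes on the skull region.

The subject template transform for time-point *i* is the log-Euclidean mean
(`exp` of the arithmetic mean of principal matrix logarithms) of all
pairwise transforms `{T_i→j}`; for two time-points this is the halfway
transform, and the mean matrix-log of template-corrected transforms is zero
by construction (unbiasedness). The halfway split of `a` uses the principal
matrix square root, valid because intra-subject transforms are near the
identity; the decomposition refuses matrices with negative real eigenvalues
and advises rigid pre-alignment.

Interpolation: windowed sinc (Lanczos) for image resampling in the
measurement path, linear for optimization loops, nearest for labels. The
halfway grid is isotropic at the finer of the two input spacings, cropped
to the brain bounding box plus margin (dense registration has no business
in empty background).

## Symmetric nonlinear registration

A single displacement field `v` carries half the deformation with opposite
signs: the baseline is warped by `+v`, the follow-up by `−v`, and the
demons update (symmetrized gradients, classical `diff/( |∇|² + diff²/h² )`
normalization, fluid smoothing of the update at σ=1 mm, weak elastic
smoothing of the field at σ=0.8 mm, step 1.0, 50 iterations) reduces their
midpoint mismatch. This construction is antisymmetric under swapping the
inputs by design, which is why forward and backward volume changes
reciprocate to ~0.01 pp. The full baseline→follow-up field is recovered
exactly as `T = (I−v)∘(I+v)^{-1} = I + 2·inv(v)` via fixed-point inversion
of the half-field.

Two choices matter and were set on phantom ground truth:

- *Images are presmoothed (σ = 1.5 mm) before matching.* With crisp
  piecewise-constant edges the demons force at a matched edge never
  vanishes under linear interpolation, and the field grows without bound;
  blurring makes the matched state a true fixed point. Real images carry
  acquisition blur that serves the same role.
- *Single resolution level.* After affine alignment the residual
  displacements are sub-voxel; coarse pyramid levels contributed spurious
  displacement in gradient-free regions that the fine level could not
  undo (no force there), biasing the integral. The pyramid remains
  available (`DemonsParams.levels`) for large-deformation use.

Strong elastic regularization (σ ≥ 2 mm) shrinks sub-voxel displacement
amplitudes by tens of percent — an equilibrium between force and smoothing
— so the elastic term is kept weak and stability is provided by the
presmoothing. Measured registration fidelity on noiseless 96³ phantoms:
−0.02 pp error at −0.5% truth, −0.08 pp at −2%.

A non-positive Jacobian inside the brain raises (regularization too weak
for the data); per-level mean-squared-difference traces are recorded in QC.

## Pre-processing (XPP / LPP)

*Bias surrogate.* Smooth non-uniformity is estimated as a 3rd-degree 3-D
polynomial fit to log-intensities — but fitted only after subtracting each
voxel's tissue-class mean (3-class mixture on log-intensity) and only over
low-gradient "deep tissue" voxels. Both restrictions exist because a naive
fit models the CSF/GM/WM contrast itself and imprints gradients precisely
at the boundaries where the atrophy signal lives; on phantoms the naive
version corrupted PVC by several percentage points while the restricted
fit recovers degree-≤3 biases to <2% RMS and leaves bias-free images
untouched (<1% RMS).

*Segmentation.* A 3-class spherical-covariance Gaussian mixture on in-brain
intensities (subsampled to 200k voxels), classes relabeled by ascending
mean (T1 ordering CSF < GM < WM), hard labels by maximum posterior. No
Markov-random-field smoothing or partial-volume model: integration masks
only need approximate boundaries, and the phantom is piecewise constant.
Collapsed classes (vanishing weight or coincident means) raise with
diagnostics rather than returning nonsense.

*Lesion filling* draws i.i.d. `Normal(NAWM mean, NAWM SD)` intensities —
sampled, not constant, to preserve texture statistics; NAWM is WM
excluding the lesion mask. In LPP the per-time-point lesion masks are
united through the subject template (nearest-neighbour both ways) so every
time-point is filled consistently.

*Differential intensity correction* estimates each time-point's residual
bias as a median-filtered ratio to the subject template (ratio clamped to
[0.5, 2]). The kernel default at the pipeline level is 16 mm: it must be
several times wider than the blurred edge-transition shell, otherwise the
median *captures* the longitudinal edge shift and divides the signal out
of the data (measured: an 8 mm kernel shrank recovered PVC by ~45% at
96³), while staying below the ~40 mm bias correlation scale. The bias is
evaluated on a 2× decimated grid (it is smooth by construction) and
linearly upsampled; the correction is computed in template space and the
bias mapped back natively, so the image itself is interpolated only once.
The median's robustness is what lets focal change (lesions, atrophy)
survive the correction.

*Field-of-view matching* invalidates, at every time-point, any voxel
missing from at least one time-point (nearest-neighbour round trip through
template space).

## Trial statistics

Effect size `d = τ·|mean|/SD` treats the treatment effect `τ` as a
fractional slowing of the mean atrophy rate with unchanged variance. The
per-arm `n` solves `power(n) = 0.80` for the two-sided two-sample pooled
t-test via the noncentral-t distribution (`df = 2n−2`, noncentrality
`d√(n/2)`), vectorized bisection on real `n`, reported rounded to the
nearest integer (ceiling available; published tables are consistent with
either to ±1 because the input means/SDs are themselves printed rounded).
For very large `df` where scipy's noncentral t overflows, the asymptotic
normal form takes over — only relevant far beyond the 10,000 censoring
threshold. Cells above 10,000 render as "> 10,000".

The outlier rule flags (never deletes) subjects with annualized rates
strictly greater than 10 %/yr in magnitude. Confidence intervals are
percentile bootstrap (2.5/97.5) over resampled subjects, recomputing mean,
SD and `n` per replicate; unbounded upper ends are censored. BCa was not
used — the published convention is plain percentile. No normal-aging
correction is applied anywhere: the sample sizes answer "detect a change
from this cohort's rate", not "from disease-specific excess rate".

The Monte-Carlo simulator (`simulate_trial_power`) is the solver's
independent oracle: two arms of `Normal` rates, pooled t-test per
replicate, rejection fraction at the analytic `n` lands in 0.80 ± 0.02 at
20,000 replicates.

## Problem sizes and tolerances in the test suite

End-to-end recovery runs four 96³ pairs (noise SD 2% of the WM mean, bias
amplitude 0.05, 1% miscalibration) through full LPP, asserting ±0.3 pp and
strict monotonicity across true PVCs {−0.25, −0.5, −1, −2}% — measured
errors are {−0.02, −0.01, +0.05, +0.14} pp. The null (scan-rescan
analogue) and Jacobian-oracle checks run at 96³; antisymmetry at 64³; the
LPP-vs-XPP comparison at 48³ over four seeds. Oracle tolerances: voxelwise
`|detJ − analytic| < 1e-3` (second-order finite differences at 1 mm on
fields whose support spans ≳10 voxels), integral agreement 0.05 pp,
halfway recomposition 1e-10, matrix-average unbiasedness 1e-6.

## Known limitations

- Ellipsoid phantoms under-stress segmentation and partial-volume effects;
  accuracy numbers here will not transfer unchanged to folded cortex.
- The demons surrogate has a small amplitude bias that grows with
  deformation size (+0.14 pp at −2%); for larger deformations the
  plug-in interface for externally computed fields is the intended path.
- Jacobian and field code assume axis-aligned diagonal-affine grids;
  oblique acquisitions must be resampled first.
- The affine polish minimizes intensity MSD and therefore assumes the two
  time-points have comparable contrast after bias correction; gross
  contrast change would need the NMI-only path
  (`hierarchical_affine(..., refine=False)`).
- `run_pipeline` measures the first pair of a series; multi-time-point
  series are conditioned jointly (template, lesion union, FOV) but
  pairwise measurement across all combinations is left to the caller.
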