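# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `segmoco`. It is written for users who want to understand
what the package computes and how far its synthetic experiments carry.

## Problem setting

A 3D multishot Cartesian acquisition measures k-space line by line: each
shot excites the spins once and acquires a fixed number of phase-encode
lines (the TFE factor) at all readout positions. Subject motion between
shots makes the measured data inconsistent with a single still image and
produces ghosting and blurring. With a *distributed, incoherent* sampling
order, every small group of consecutive shots — a **segment** — samples
frequencies all over k-space, so a segment both (a) supports a crude but
complete image of the moving anatomy and (b) covers so little of k-space
that motion within it can be neglected. The package estimates one rigid
transform per segment and reconstructs an image whose forward model
includes that motion.

## Forward model

The acquisition operator is `A = M F S C_θ`:

* `C_θ` — rigid resampling with trilinear interpolation. Convention,
  fixed everywhere (including all JSON artifacts): extrinsic rotations
  about the volume center applied in x→y→z order (`R = R_z R_y R_x`),
  rotation before translation; translations in mm, rotations in degrees.
  The volume center is the geometric grid center `(n-1)/2 · spacing`.
* `S` — static complex coil sensitivities, root-sum-of-squares
  normalized so `Σ_c |S_c|² = 1` on the support.
* `F` — centered orthonormal 3D FFT (DC at index `n//2` via pre/post
  shifts).
* `M` — selection of the segment's (ky,kz) lines; the readout axis kx is
  always fully sampled.

The adjoint uses the exact transpose of the trilinear weights (scatter-add
of the same interpolation coefficients), so `⟨Ax,y⟩ = ⟨x,Aᴴy⟩` holds to
machine precision and conjugate-gradient theory applies. The cheaper
approximation `C_{θ⁻¹}` is available behind a flag. B0 changes,
spin-history effects and motion-dependent coil maps are deliberately not
modeled.

## Sampling order

The random-checkered generator tiles the phase-encode plane into
`tfe_factor` near-equal contiguous rectangles (divisor pairs that tile the
plane evenly are preferred; the aspect ratio closest to the plane's wins).
Every shot samples exactly one seeded-random location per tile, and visits
tiles in a seeded-random order, so each shot spans low and high
frequencies. Segments are whole numbers of consecutive shots; their masks
partition the sampled set. Retrospective acceleration discards a seeded
uniform subset of whole shots, rounded to keep segments whole.

## Motion model and simulated trajectories

Motion is piecewise constant: one rigid state per segment (or per shot for
intrasegment studies), shots of one state contiguous in time. Random
trajectories draw each of the six parameters i.i.d. from zero-mean normals
— per-axis stds of 2 mm / 1° ("medium") and 12 mm / 6° ("extreme") give
mean pairwise center displacements of 4.5 mm and 27.1 mm, because the
center displacement of a state is exactly its translation and
`E‖t_a−t_b‖ = 4σ/√π` for 3-D Gaussians. Intrasegment refinement composes
each state with per-shot perturbations at a configurable severity fraction
(default study: 1/16). Scripted shapes emulate instructed volunteer
motion: gradual piecewise-linear drift, jittery piecewise-constant jumps
at a fixed period, and a monotone stepwise sweep from −A to +A.

## Synthetic data

The phantom is a deterministic brain-like object: nested ellipsoids
(scalp/brain/one-sided ventricle) with ≥ 20 seeded ellipsoidal lesions of
1–4 voxel scale placed asymmetrically, values in [0,1], background zero,
isotropic 1 mm spacing. The volume is band-limited with a Gaussian of
σ = 0.9 voxel: measured MR images carry no step edges, and sharp digital
edges measurably bias interpolation-based registration (≈ 1° at this
grid scale). Coil maps are broad Gaussian lobes on a ring around the
volume with gentle linear phase ramps, RSS-normalized; SVD compression
projects onto the top-k left singular vectors of the coil-by-voxel
matrix and renormalizes.

What the generator does **not** emulate: realistic MR contrast and noise
statistics, anatomical variability, B0/eddy-current effects, receive-coil
geometry of real arrays, and realistic spectra (the phantom is exactly
piecewise-smooth, which flatters total-variation reconstruction). Passing
tests demonstrate internal consistency of the method under the stated
simulation conditions, not clinical performance.

## Segment reconstruction

A segment holds a few percent of k-space; the reconstruction only needs to
support rigid registration. Three interchangeable reconstructors:

* `zero_filled` — magnitude of `Sᴴ F⁻¹ Mᴴ y`;
* `cg_tikhonov` — CG on `(AᴴA + λI)x = Aᴴy` (default λ = 0.05, 10
  iterations, chosen by a phantom sweep: smaller λ overfits aliasing,
  larger λ only shrinks the image);
* `tv_cs` — the default: FISTA with a total-variation proximal step
  (Chambolle) on `‖MFSx−y‖² + w·TV(x)` (default w = 0.01, 40 iterations,
  single precision, real-valued constraint since the object's phase lives
  in the coil maps; data and maps are projected onto the 4 dominant SVD
  virtual coils for speed). Quadratic penalties cannot fill unmeasured
  low frequencies, which made `cg_tikhonov` segments unregistrable at
  1/16 sampling; the TV prior recovers piecewise-smooth anatomy well for
  segments whose sampling covers the k-space center.

A *learned* reconstructor is a pluggable callable mapping the zero-filled
volume to an improved volume. `KSpaceFilterModel` is a worked example
trained in closed form (per-frequency ridge regression on synthetic
corrupted/clean pairs); heavier learned models can be dropped in behind
the same interface.

Fundamental caveat: a segment whose checkered pattern happens to miss the
central one or two k-space cells cannot recover the image bulk with *any*
unlearned prior; at 6% uniform-density sampling roughly half the segments
are affected. This drives the estimation architecture below.

## Groupwise registration

All segment volumes are aligned to an evolving mean template by
minimizing the masked sum of squared differences plus an optional
quadratic penalty `w·(‖t‖² + (c·rot)²)` on the distance from identity
(c = 1 mm/°). For fixed transforms the template update is the exact
closed-form minimizer (voxelwise mean of the warped volumes). Transform
updates are bounded Powell minimizations per volume on a Gaussian pyramid
(smooth σ=1, decimate ×2 per level), coarse to fine; the SSD is evaluated
on at most 24 000 deterministically strided mask voxels. Registration
resampling uses cubic splines: trilinear warping biases the SSD optimum
by a sizeable fraction of a degree. The mean template leaves a global
pose undetermined; the gauge is fixed by left-composing all transforms
with the inverse of their Fréchet mean (chordal rotation average,
arithmetic translation mean) after each pyramid level. Inputs are
normalized to unit RMS over the mask.

On registration-grade inputs (clean warped copies of one volume at 64³)
the recovered transforms match the generator within 0.2 voxel / 0.2°
(asserted by the test suite). On real few-percent-sampled segment
reconstructions the quality is bimodal (see above), and the registration
estimate is treated as an initializer for the data-consistency stage.

## Data-consistency refinement

Each segment's six parameters are fitted directly to its measured k-space
lines, `min_θ ‖M_s F S C_θ x̂ − y_s‖²`, with a reference image `x̂`
reconstructed from the data. Four details decide whether this works:

1. **Leave-one-out references.** A reference containing segment `s`'s own
   data reproduces those lines at the *current* estimate's pose, placing a
   spurious minimum there; alternating optimization stalls. Fitting
   against `x̂ − A_sᴴ(y_s − A_s x̂)` (the first-order leave-one-out
   solution) removes the trap for one encode/adjoint per segment.
2. **Schedule.** Early references are consensus-blurred; their
   high-frequency content misleads rotation fits. Translation-only sweeps
   run first; rotations then move only within a ±1.5° trust region per
   sweep, with mild over-relaxation of each update (the sweep errors
   contract geometrically, and extrapolating along the update direction
   cancels part of the reference-induced bias).
3. **Within-sweep reference updates.** After each segment is fitted it is
   re-inserted into the reference at its new pose (the same first-order
   correction in reverse), so later fits in the sweep see it correctly —
   Gauss–Seidel rather than Jacobi sweeps, which roughly triples the
   contraction rate.
4. **Optimizers by phase.** Exploratory sweeps use bounded Powell (its
   large initial direction steps step over the small-scale ruggedness of
   ghosted references); polish sweeps use bounded trust-region-reflective
   least squares (Gauss–Newton with finite-difference Jacobians), which
   reaches interpolation-limited precision in a few iterations once the
   landscape is smooth. Sweeps stop early when a pass improves the
   residual by less than 8%.

The residual uses the 4 dominant SVD virtual coils in single precision
with the reference constrained to the reals (the simulated object is
real); the reference is refreshed by warm-started CG after every sweep.
Against an accurately reconstructed reference the per-segment fit is
limited only by interpolation accuracy, so the accuracy of the pipeline
estimate is set by how close the alternation can bring the reference,
not by the fit itself; the acceptance suite verifies sub-0.2-voxel and
sub-0.2-degree mean recovery on the default experiment.

## Motion-corrected reconstruction

Basic CG on the normal equations `AᴴA x = Aᴴ y` with the per-segment
transforms in `A`; no explicit regularizer by default (Tikhonov behind a
flag), start `x₀ = Aᴴy` or a supplied warm start. Defaults of 10
iterations for clean simulations and 3 for noisy data are exposed in the
experiment config; with noise, over-iteration amplifies it, and the tests
assert the non-monotone quality curve this produces. Lines are grouped
into constant-transform blocks, so an all-identity trajectory costs a
single FFT pass per CG iteration.

## Alternating baseline

The comparison baseline alternates warm-started CG image updates with
per-segment derivative-free pattern search (shrinking coordinate steps,
seeded visiting order) on the data-consistency residual. Both half-steps
are monotone in the global residual by construction. It is a deliberate
simplification of published joint optimizers — comparisons are
qualitative, and its stopping rule is residual-based (stagnation
tolerance 1e-6).

## Metrics

SSIM: mean local structural similarity, Gaussian windows σ = 1.5,
population covariances, standard constants, data range fixed to the
reference maximum (SSIM is range-sensitive); optional evaluation mask.
PSNR uses the reference maximum as peak; `a = b` reports `inf`. NMSE is
`‖a−b‖²/‖b‖²`. The trajectory error resamples the estimate to the
reference state grid (nearest shot), removes the best global rigid offset
(closed-form translation, chordal-mean-initialized iterative rotation),
and averages translation and geodesic rotation distances — so it is
invariant to the gauge freedom of groupwise estimation, mirroring
evaluation that first registers the corrected image to the target.

## Desk-scale study conditions

The default experiment uses a 64³ phantom, 8 coils, 64 shots × 64 lines
(full coverage of the 64×64 phase-encode plane) in 16 segments of 4
shots, intersegment motion with per-axis stds 2 mm / 2°, no noise, fixed
seeds. This scales down the reference protocol (240³, 320 shots × 180
lines, 64 segments of 5 shots) while preserving the segment fraction
regime (6.25% per segment here vs 1.56% there) and the
several-shots-per-segment structure. Problem sizes throughout the test
suite (16³–64³) were chosen so the full simulation-estimation-correction
cycle runs in minutes on a single CPU.

## Numerical choices

* FFTs via `scipy.fft` (preserves single precision; `numpy.fft` upcasts).
* Exact trilinear transpose for all adjoint operators; dot-test verified
  at 1e-8 relative.
* CG stops on iteration count or relative residual; a NaN or negative
  curvature flags the result rather than raising.
* Segment-reconstruction and refinement hot paths run in complex64; all
  public reconstruction operators run in complex128.
* Angles are wrapped to (−180°, 180°]; gauge means use chordal rotation
  averaging with a Procrustes projection.
* Degenerate inputs: empty masks encode to empty arrays; all-zero k-space
  reconstructs to an exact zero volume; identity transforms bypass
  resampling entirely.

## Known limitations

* With classical segment reconstructions, image-domain registration
  alone carries reliable rotations only for segments whose sampling
  covers the k-space center; final accuracy therefore depends on the
  data-consistency refinement, whose scheduled sweeps dominate the
  pipeline's runtime (about ten minutes for the default experiment on
  one CPU). Rotations converge more slowly than translations because the
  k-space residual is dominated by low frequencies, which rotations
  barely move.
* The learned-reconstruction route that the estimation quality of the
  original method rests on is represented only by its interface and a
  linear worked example.
* Motion within a shot, non-rigid motion, and motion-dependent coil or
  field effects are outside the model.
* The refinement assumes a real-valued object when evaluating its fit
  residuals; data with substantial intrinsic image phase would need that
  constraint relaxed.
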