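# segmoco

Retrospective rigid-motion correction for 3D multishot Cartesian brain
MRI, built around segment-wise motion estimation.

Head motion between the shots of a multishot acquisition makes the
measured k-space inconsistent with a single still image and produces
ghosting and blur. When the sampling order is *distributed and
incoherent* — every few consecutive shots (a **segment**) sample lines
all over k-space — each segment supports a crude image of the moving head
while covering so little of the scan that motion within it is negligible.
`segmoco` simulates such acquisitions, estimates one rigid transform per
segment, and reconstructs a motion-corrected image. It is aimed at
researchers studying motion-correction algorithms who need a fully
synthetic, reproducible test bed with known ground truth.

## Model

The acquisition of segment *s* is

```
y_s = M_s F S C_{θ_s} x + ε
```

with `x` the still volume, `C_θ` rigid motion (trilinear resampling;
rotation about the volume center before translation), `S` RSS-normalized
coil sensitivities, `F` the centered orthonormal 3D FFT and `M_s` the
segment's phase-encode line selection. Motion correction solves

```
x̂ = argmin_x Σ_s ‖M_s F S C_{θ̂_s} x − y_s‖²
```

by conjugate gradients, given per-segment motion estimates
`θ̂_1 … θ̂_N`. Estimates come from a three-stage pipeline:

1. **Segment reconstruction** — each heavily undersampled segment is
   reconstructed alone (default: total-variation compressed sensing);
2. **Groupwise registration** — all segment volumes are rigidly aligned
   to an evolving mean template (sum-of-squared-differences, multiscale
   pyramid, gauge fixed to a mean pose of identity);
3. **Data-consistency refinement** — each segment's six parameters are
   polished directly against its measured k-space lines using
   leave-one-out reference images (see `docs/methods.md` for why the
   leave-one-out detail is essential).

An alternating image/motion optimizer (`alternating_moco`) serves as the
classical joint-optimization baseline, and per-shot simulated
trajectories, shot-discarding acceleration, and scripted motion shapes
(gradual / jittery / stepwise) cover the surrounding study designs.

## Worked example

```python
import segmoco as sm

# synthetic study: 64³ phantom, 8 coils, 64 shots x 64 lines in 16
# segments, random intersegment motion with 2 mm / 2° per-axis std
report = sm.run_experiment(sm.default_config(seed=0), outdir="run0")
print(f"SSIM corrected   {report['ssim_corrected']:.3f}")
print(f"SSIM uncorrected {report['ssim_uncorrected']:.3f}")
print(f"motion error     {report['motion_error_mm']:.2f} mm "
      f"{report['motion_error_deg']:.2f} deg")
```

prints (deterministic for a given seed; the run takes on the order of ten
minutes on one CPU)

```
SSIM corrected   0.991
SSIM uncorrected 0.541
motion error     0.08 mm 0.13 deg
```

meaning: against the known still phantom, the motion-corrected
reconstruction is nearly exact (SSIM 0.99) while the uncorrected one is
heavily ghosted (SSIM 0.54), and the estimated 16-state trajectory
matches the simulated one to a twelfth of a voxel and about an eighth of
a degree after removing the global pose offset that groupwise estimation
cannot observe. The `run0/` directory holds every artifact (phantom,
coil maps, k-space, both trajectories, both reconstructions, config,
report).

The same flow is scriptable from the shell:

```
moco sample --ny 64 --nz 64 --shots 64 --tfe 64 --shots-per-segment 4 \
     --seed 3 --out scheme.json
moco run --seed 0 --outdir run0
moco evaluate --recon run0/corrected.nii.gz --ref run0/phantom.nii.gz \
     --out report.json
```

Smaller building blocks (`simulate`, `segment-recon`, `register`,
`reconstruct`, `sweep`) expose the intermediate stages; the library API
mirrors them one-to-one.

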