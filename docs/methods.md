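# Methods

flow4d implements a complete, desk-scale version of a CFD-informed
machine-learning paradigm for cerebrovascular 4D flow phase-contrast MRI:
high-resolution "CFD-like" velocity fields are synthesized, corrupted with
a physics-based model of the PC-MRI measurement, a residual 3D CNN is
trained to invert the corruption, and the result is quantified with
standard hemodynamic metrics.  This note documents the models, the
numerical choices, and what the synthetic setting does and does not show.

## Vessel geometry bank

A vessel is one flow path: an ordered centerline with per-point radius,
flat end caps cut normal to the path, optionally a spherical aneurysm sac
blended on by a smooth union of distance fields, and (for bifurcations)
branch paths carrying a fixed fraction of the volumetric flow.  The default
bank holds 30 geometries: 5 idealized shapes (straight, bend, helix, taper,
bifurcation; diameters 1–8 mm), 5 procedural "patient-like" vessels, and 4
systematic modifications of each patient-like base (inlet-angle tilt,
diameter scaling, sac-size and sac-shape changes), so that 6 inflow
waveforms per geometry give 180 time-varying fields.

Patient-like vessels are curvature-bounded smoothed random walks
(~48 mm long, radii 1.15–1.4 mm) with one sac (radius 1.8–3 mm) attached
perpendicular to the mid-vessel tangent.  A build-time assertion guarantees
no self-intersection: non-adjacent centerline points must stay farther
apart than the sum of their local radii.  These are statistical surrogates
for angiography-derived anatomy: they reproduce tortuosity and sac
geometry, not any real patient's vasculature.

Voxelization evaluates the signed distance field on an isotropic grid
(coordinates in mm; voxel centers at `origin + (i + 0.5) * spacing`,
arrays ordered `[z, y, x]`).  Boundary voxels get partial-volume fractions
from a stratified, jittered 3^3 subsample per voxel.  The jitter
(deterministic per call) matters: with a fixed sub-grid the quadrature
error is coherent along grid-aligned surfaces — a straight tube's entire
length shares one cross-section error — and total volume stops converging.
With jitter the error decorrelates between voxels and the volume error
falls roughly as the square of the spacing.

## Flow synthesis

The finite-volume solver of the original pipeline is not re-implemented.
The surrogate sweeps analytic rigid-tube profiles along each path: the
inflow waveform (truncated 3-harmonic Fourier series around a base flow of
1.8–2.6 mL/s, period 1 s, samples every 0.02 s, positivity and peak factor
bounded) is decomposed into harmonics; harmonic 0 contributes a parabolic
Poiseuille profile, harmonics k >= 1 the Womersley solution
`u_k(y) ∝ 1 − J0(β y)/J0(β)` with `β = i^{3/2} α_k`,
`α_k = R sqrt(k ω ρ/μ)`, each flux-normalized; below α = 1 the profile
degrades to quasi-steady Poiseuille.  Blood is ρ = 1060 kg/m³,
μ = 0.004 Ns/m² throughout; velocities are cm/s everywhere, converted to
SI only inside the physical formulas.  Waveform amplitudes are sized so the
peak Reynolds number ρUD/μ across the default bank stays inside the
physiological 100–800 window.

The swept field is then projected onto the discretely divergence-free
space.  The discrete divergence is the wide central difference
(equivalently, two-point-average face fluxes).  Zero divergence is
enforced at every vessel voxel and its one-voxel exterior shell —
excluding a 2.5-voxel buffer around each cap plane, where through-flow
must enter and leave — by the minimum-L2-norm correction supported inside
the vessel, obtained from a direct factorization of `A Aᵀ` (reused across
frames and inflow profiles).  Restricting the correction's support keeps
the no-slip property exact: velocity is identically zero outside the
lumen.  After projection each frame is rescaled so the face-flux through a
full grid cross-section equals the instantaneous inlet flow rate; because
the projected field is solenoidal, that flux is plane-independent between
the caps, so the scaling is well defined.

What the surrogate does not model: convective acceleration, secondary
(Dean) flows in bends, genuine sac recirculation (the projection induces
only a weak sac flow), wall compliance, and outlet pressure physiology.
Tests passing on these fields show that the measurement model, the
training machinery and the metrics behave correctly on smooth,
mass-conserving pulsatile vessel flow — not that the network would enhance
flows whose physics the surrogate lacks.

## PC-MRI measurement model

Per training draw: (1) optional uniform SO(3) rotation of the volume
(cubic-spline resampling of each velocity component and linear resampling
of the mask, followed by vector rotation of the components); (2) synthetic
static tissue: a 5×5×5 complex standard-normal k-space block embedded in
an empty spectrum, inverse-transformed, magnitude-detected and
soft-thresholded at half its median — producing flat exactly-zero regions
with sharp edges — then combined with the vessel partial-volume mask at a
background-to-vessel ratio drawn from [0, 2]; (3) simple 4-point PC
encoding, reference plus one encoding per axis with phase π v_k / Venc,
Venc drawn as a fraction (default 0.1–0.9) of the frame's peak speed —
phase wraps naturally above Venc and no unwrapping is attempted; (4)
complex white Gaussian k-space noise calibrated so that mean vessel
magnitude over full-resolution image-domain noise std equals the SNR draw
(log-uniform over [10, 10000]; vessel-mean convention); (5) central
k-space crop to 0.25 of the resolution per axis, zero-filled back to the
truth grid so the network needs no learned upsampler; (6) standard
phase-difference reconstruction.  The phase of a numerically vanishing
signal is undefined; decoding therefore zeroes velocities where the
phase-difference product falls below 1e-8 of the peak reference magnitude
(squared).  Noise-level signals sit far above this floor and keep their
physical random phase.

## Network and training

Training pairs are made on the fly — a fresh corruption every time a field
is visited.  32³ blocks are drawn uniformly from the volume and kept only
if the clean velocity conserves mass across the block boundary (two-point
average face fluxes; accept iff |net| <= tol × Σ|face flux|, vacuous accept
when no flow crosses the boundary).  `continuity_check` defaults to
tol = 1e-3, appropriate for un-resampled solver output; the training loop
samples at 2e-2 because spline-rotated truth carries an interpolation
divergence floor of about 1e-2, while blocks containing cap through-flow
or volume-edge clipping sit at O(1) and are still rejected by a two-decade
margin.  Rotations that clip the vessel so severely that almost no block
conserves mass are redrawn.  Each accepted block is augmented by
independent axis flips that reverse the spatial axis and negate the
corresponding velocity component (an involution; magnitude flips
spatially only).

The network maps 4 channels (3 velocity components normalized by a fixed
100 cm/s scale, plus the decoded magnitude) to 3 velocity channels.  It is
a block-wise residual design: pointwise head, depthwise 3-tap spatial
filter, then residual blocks of (depthwise filter → pointwise → ReLU →
pointwise) with skip connections, and a zero-initialized pointwise tail
whose output is added to the input velocity — so the untrained network is
exactly the identity ("do no harm" start).  Spatial mixing uses
depthwise-separable 3-tap filters per axis with per-block dilations
(default 1,2,3,1 over 4 blocks of 16 channels), giving a receptive field
of about ±8 voxels, enough to invert the ~4-voxel blur of the 0.25
k-space crop.  This separable design is chosen for CPU efficiency: channel
mixing is a single BLAS matrix product and the spatial taps are fused
numba kernels; dense 3³ convolutions cost ~27× more memory traffic and
were the bottleneck on one core.  Forward and backward passes are written
explicitly and validated against finite differences.

Whole volumes are enhanced by sliding 32³ tiles blended under a cosine
window; `enhance_averaged` additionally averages the eight
flip-conjugated predictions (the corruption statistics are exactly
flip-symmetric but a finitely trained network is not, so the averaging
cancels part of the network's own residual error at 8× inference cost).

Loss is magnitude-weighted least squares, `Σ w ||pred − truth||² / (3 Σ w)`
with `w = magnitude²` per voxel, reflecting the inverse relation between
signal magnitude and velocity noise.  Batches of 8 blocks, 32 blocks per
simulation (4 optimizer steps per corruption draw), Adam with cosine decay
and global gradient-norm clipping at 1.  The default peak learning rate is
3e-3 (1e-2 in the reference experiment): with only hundreds of optimizer
steps available on one CPU, the conservative 1e-4 typical of long GPU
training schedules cannot leave the identity initialization.  Fields are
split 80/20 into train/validation by field label; validation corruptions
are drawn from fixed seeds so the curve is comparable across epochs.

## Evaluation metrics

RMSE is `sqrt(Σ(â−v)²/n)` over masked voxels and components.  PC-MRA is
the time-mean of magnitude × speed (the sum-of-squares variant exists; the
mean form is used here).  Wall shear stress: wall-adjacent voxels are
those with a face-adjacent exterior neighbor; the inward normal comes from
the gradient of a Gaussian-smoothed (σ = 1.2 voxels) distance transform;
the sub-voxel wall position uses the partial-volume fraction (a planar
wall cutting fraction f of a voxel passes (f − 0.5) voxels inside its
center); tangential speed is sampled at 2h and 3h inward — far enough
that trilinear interpolation never touches exterior zeros — and
differentiated with the one-sided second-order stencil
`du/dn = (9u(2h) − 4u(3h))/(6h)`, exact for quadratic profiles with u = 0
at the wall.  On a Poiseuille tube this converges monotonically and is
within 10% of τ = 2μV₀/R at spacing R/10.  Vorticity is the central
curl with one-sided differences at the mask boundary (plane summaries use
|curl|, the magnitude rather than the through-plane component).  Kinetic
energy is ½ρ|v|² summed over the lumen, in mJ.  Plane probes resample a
cut plane at voxel resolution (cubic for velocity, linear for the mask;
points with interpolated fraction >= 0.5 contribute) and report flow in
mL/s, peak speed, and mean |curl|.  Eddy-current correction fits all ten
3D monomials up to degree 2 to each component over background voxels
(magnitude above threshold, outside the vessel) and subtracts the fit,
skipping with a warning when background voxels number fewer than 10× the
coefficient count.  Agreement summaries report Pearson r and Bland–Altman
bias ± 1.96 sd of paired differences, with bias = mean(a − b).

## Reference experiment (desk scale)

`flow4d.experiments.denoise_benchmark` reproduces the corrupt-then-enhance
experiment in miniature: 8 training fields from 4 idealized geometries × 2
pulsatile inflows at 0.3 mm spacing (~14 voxels across the ~4 mm lumens),
and one held-out field from a new geometry and a new inflow.  Training
corruptions draw SNR in [35, 80], background ratio in [0.3, 1.6], crop
0.25, Venc at the peak speed, no rotation; evaluation fixes SNR 50, ratio
0.5, crop 0.25, Venc = peak.  Venc below the peak speed makes a handful
of voxels wrap by ±2·Venc; those unfixable outliers dominate both the
error metric and the training gradients, so the desk-scale experiment
operates wrap-free (aliasing is a documented non-goal), while the general
training default keeps the 0.1–0.9 draw.  Rotation augmentation is
likewise disabled here: it triples simulation cost and injects
spline-interpolation error into the ground truth, which a few hundred
optimizer steps cannot average away (the full-scale defaults keep it).
Reported are the mean in-vessel relative velocity error (mean vector-error
magnitude over mean speed) of corrupted and enhanced fields against clean
truth, and the percent reduction in background velocity-noise standard
deviation, over three seeded corruption draws of the held-out case,
using flip-averaged inference.  The 55-epoch schedule (~1300 optimizer
steps) targets about ten minutes of training on one CPU core.

Two structural properties of this setting are worth knowing.  First, a
0.25 k-space crop leaves a hard "linear recoverability" floor: the part
of the truth's spectrum outside the retained window must be hallucinated
from the smooth-flow prior, and an L2-trained network converges toward
the posterior-mean (low-pass-like) answer before it starts synthesizing
high-frequency detail.  Second, the background velocity-noise std is
dominated by voxels whose signal magnitude is essentially zero — exactly
the voxels where the magnitude-squared loss weight vanishes — so the
network suppresses that noise only insofar as its low-magnitude damping
behaviour generalizes; at desk scale this saturates well below what
full-scale (days-long) training can reach.

## Known limitations

- The flow surrogate omits convective physics; networks trained on it
  will not have seen Dean vortices or genuine sac recirculation.
- The architecture is a CPU-sized separable residual network (~10⁴
  parameters), far smaller than GPU-scale super-resolution models; its
  accuracy ceiling at fixed compute, not the paradigm, limits the
  reported enhancement.  In particular the background-noise reduction of
  the reference experiment saturates near 55%: most of the remaining
  background variance sits in zero-weight (zero-magnitude) voxels the
  training loss cannot see.
- Radial (PC-VIPR) trajectories, eddy-current/Maxwell physics,
  intravoxel dephasing and scan-time subsampling are not simulated;
  the eddy-current *correction* is provided, the corruption is not.
- Venc aliasing is produced faithfully by the encoder but never
  corrected.
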