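# Methods

## Problem and model

Real-time cardiac cine MR trades sampling density for temporal
resolution: acquiring each frame from only 14 radial k-space spokes —
where 182 uniformly spaced spokes would be needed to satisfy the
radial Nyquist criterion for a 192 matrix — gives a 36.4 ms frame but
leaves strong streak/alias artifacts in the regridded images.  This
package implements two reconstructions of such data and the machinery
to compare them:

1. **Deep artifact suppression.** A 3D (2D+time) residual U-Net maps
   the artifact-contaminated magnitude cine to a clean one.  Every
   convolution is 3x3x3 with a ReLU, weighting the two spatial axes
   and time identically so no direction is favoured; the network
   output is `ReLU(input + residual)`, which enforces non-negative
   magnitudes and makes the identity the natural starting point (the
   final layer is zero-initialized).  Training minimizes the l2 loss
   (l1 optional) with Adam (lr 1e-3, beta1 0.9, beta2 0.999, eps
   1e-8).
2. **Temporal-total-variation compressed sensing** (the comparator):
   `argmin_x 1/2||Ax - y||^2 + lambda ||D_t x||_1` solved by ADMM with
   split `z = D_t x`, magnitude soft-thresholding for `z`, conjugate
   gradients on the normal equations for `x`, and a fixed 50
   iterations at lambda = 0.025.

## Radial sampling schemes

Four spoke orderings are generated (angles in degrees, 0 = +kx,
counter-clockwise):

| scheme | within-frame spacing | between frames |
|---|---|---|
| `reg_no_rot` | 180/14 ~ 12.86 | none |
| `reg_rot` | 180/14 | rotation by (180/14)/13 ~ 0.989, so 13 consecutive frames pool to the uniform 182-spoke set |
| `tga_no_rot` | tiny golden angle | none |
| `tga_rot` | tiny golden angle | continuous accumulation |

The tiny golden angle is psi_7 = 180/(tau + 6) = 23.628... deg (tau
the golden ratio); successive spokes at this increment cover angle
space near-uniformly at every truncation while keeping consecutive
gradient axes close.  tGA angles accumulate mod 360 (spoke direction
alternates); for sampling-density arguments angles are reduced mod
180, where direction is irrelevant.  The non-rotating schemes produce
aliases that are identical in every frame of a static scene; the
rotating schemes make the alias pattern decorrelate across frames,
which is exactly what a spatio-temporal denoiser can exploit.

## Encoding operators

The forward operator evaluates the 2D DFT of each frame at the spoke
coordinates (readout 2x oversampled: 2N samples per spoke spanning
[-0.5, 0.5) cycles/pixel).  Two backends:

- **Kaiser-Bessel gridding** (default): 2x oversampled FFT grid,
  width-4 kernel with the Beatty beta, analytic sinh deapodization.
  Forward interpolation and adjoint spreading share one interpolation
  plan, so the pair passes the inner-product adjoint test to machine
  precision independently of kernel accuracy; absolute accuracy
  against the exact DFT is ~5e-4 (relative, max) at width 4 and
  improves monotonically with width.
- **Direct evaluation**: exact chunked DFT summation, used as the
  reference in tests and wherever exactness matters more than speed.

Density compensation for the direct (non-iterative) reconstruction is
the analytic ramp: each sample weighted by its annular area
`|k| * dk * pi/spokes`, the DC sample by the shared central disc
`pi dk^2/(4 spokes)`.  Simulation is single-coil with identity
sensitivity throughout; multi-coil combination is out of scope.

Noise for robustness sweeps is added in image space: white Gaussian
with sigma = rms(signal)/10^(SNR/20), clipped at zero to preserve
magnitude semantics.

## Synthetic cine phantom

The phantom stands in for a library of retrospectively gated
breath-hold bSSFP short-axis cines.  Each subject/slice is an analytic
scene rasterized with ~1-pixel anti-aliased edges: a torso ellipse
with a fat rim, a left-ventricular annulus (bright pool 0.9, darker
myocardium 0.25) contracting periodically with an asymmetric systolic
waveform (endocardial radius r0(1 - cf*w(t)), myocardial area
conserved), 2-3 papillary discs riding on the endocardium, and a
right-ventricular crescent.  Defaults: 240 matrix, 1.3 mm pixels, 40
phases, R-R 900 ms.  Per-subject variation draws R-R from [600, 1200]
ms, geometry within +-15-20% and contrast within a few percent from a
single master seed; slices shrink 8% per step toward the apex.
Optional respiratory translation exists but defaults off.

What the phantom does **not** emulate: coil sensitivities and coil
combination, bSSFP banding, through-plane motion, trabecular texture,
gradient delays/trajectory errors, and respiratory motion during
acquisition.  Passing benchmarks on it demonstrates that the pipeline
and learning machinery behave as designed — not clinical image
quality.

## Gated-to-real-time conversion

A gated cine is converted to training material by: bilinear spatial
resampling to the 192 acquisition matrix; linear temporal resampling
onto points 36.4 ms apart (frame count = floor(RR/36.4), so 16-32
frames for R-R 600-1200 ms); radial undersampling and regridding of
the magnitude truth to create the aliased branch (no synthetic phase —
training data is magnitude-only); centre-crop to 128 (the phantom
heart is centred; the crop offset is exposed for the shift sweep);
linear interpolation through time to a fixed 20 frames with endpoints
pinned to the first/last source frames; min-max normalization to
[0, 1] per 3D volume, with constant volumes mapping to zeros.

## CS solver numerics

`lambda = 0.025` is interpreted on fully normalized data: the sampling
operator is rescaled to unit spectral norm (12 power iterations from a
fixed-seed start) and the k-space so the density-compensated adjoint
image has unit maximum.  Without operator normalization the data term
outweighs the penalty by the squared operator norm (~6e4 at a 48
matrix) and the stated lambda would be meaningless; any published
lambda for this objective is only defined relative to such a
convention.  Temporal differences are one-sided (N-1 differences for N
frames; circular option off by default, since the 20-frame resampled
cine is not periodic).  ADMM uses rho = 1, 10 inner CG iterations
warm-started from the previous iterate, x and dual initialized at
zero: the reconstruction is deterministic.  Early stopping is off by
default to mirror the fixed-50-iteration protocol.

## Metrics

RMSE is over all voxels of [0, 1]-normalized volumes.  SSIM uses the
Wang constants (K1 0.01, K2 0.03), Gaussian window sigma 1.5, data
range 1, computed per frame and averaged; the constants are recorded
in every report.  Edge sharpness samples an intensity profile across
the septal border by bilinear interpolation (64 samples), min-max
normalizes it, fits a degree-10 polynomial on a [-1, 1]-rescaled
coordinate (numerically well-conditioned), differentiates
analytically, and reports the maximum |gradient| in 1/mm, averaged
over six canonical septal segments and all frames; constant profiles
are excluded with a warning.  Bland-Altman reports bias = mean(test -
ref) with +-2 SD limits of agreement.

## Benchmark profile and problem sizes

All learning-level experiments run a reduced profile chosen as the
package's benchmark: protocol 48 matrix / 320 mm FOV, crop 32, 8
fixed frames, 6 spokes per frame against the ~78-spoke radial Nyquist
of a 48 matrix — preserving the 13x undersampling severity of the
full-size 182/14 geometry (keeping 14 spokes at a small matrix would
only be ~5x undersampled and would change the aliasing regime being
studied); phantom rendered at 60 matrix; network with 2 scales, 8
base channels; training 40 pairs (20 subjects x 2 slices) for 30
epochs, batch 4; evaluation on 10 held-out pairs from a disjoint seed
stream.  The network implementation is pure numpy (im2col
convolutions with hand-derived backpropagation, verified against
central differences in double precision), so this size keeps the full
four-scheme comparison in the minutes range on one CPU core.  The
full-size regime of the protocol (128 crop, 20 frames, 3 scales with
32/64/128 channels, 350 epochs, batch 8) is expressed by the same
configuration objects and documented as the full profile.

The robustness sweeps follow the protocol's conditions: SNR at
{clean, 20, 15, 10} dB; acceleration 10x-16x by rounding 182/acc
spokes per frame (with a logged warning when inexact) under the fixed
13x-trained network; crop shifts over a 7x7 offset grid (48 non-zero
shifts), step 2 px at the benchmark crop (4 px at full size).

## Known limitations

- Training on one CPU bounds the benchmark size; orderings and trends
  are reproduced, absolute RMSE/SSIM levels are specific to the
  phantom and profile.
- The analytic phantom's aliases are cleaner than in vivo artifacts
  (no coil weighting, no motion corruption); the scheme ordering is
  expected to transfer, per-case magnitudes are not.
- Gridding accuracy at kernel width 4 (~5e-4) is ample for image
  work but the exact backend should be used for operator-level
  verification.
- Float32 network arithmetic: training is deterministic for a fixed
  seed and single-threaded BLAS; exact bitwise reproducibility across
  BLAS builds is not guaranteed.
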