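# Methods

This note documents the models, the numerical choices, and the limits of the
synthetic benchmark. All symbols are in object-space micrometres unless said
otherwise.

## Optical model and simulator

The imaging system is characterized by wavelength λ = 0.488 µm,
magnification 55, camera pitch 5.5 µm (object-space pixel 0.1 µm), NA = 0.5
(theoretical lateral resolution 0.82 λ/NA ≈ 0.8 µm), and 30 frames/s. The
forward simulator is deliberately minimal: a straight-ray (projection)
phase model — phase = (2π/λ) Σ Δn · voxel — with no diffraction inside the
sample, no objective MTF and no partial coherence. Off-axis recording is
modelled as interference with a tilted plane wave,
H = |U + a·exp(−2πi f₀·r)|², with the sign convention placing the object
order (correct phase sign) at +f₀ in the spectrum. The default carrier has
magnitude 0.25 cycles/pixel along the diagonal, comfortably separating the
+1 order from the autocorrelation term for resolution-scale objects; a
separation guard compares the carrier against twice an (intentionally
noise-robust, 80%-energy) estimate of the object bandwidth.

A rolling acquisition places the phantom's phase projection at angle
k·Δθ_frame in a camera frame, rotated by the channel tilt (45°) and
translated along the tilt direction by k·Δx_frame; additive Gaussian phase
noise (σ = 0.08 rad by default, a typical residual after off-axis
demodulation of a quiet system) is applied before interference. The default
kinematics, 10°/frame and 0.8 µm/frame over ~36 frames per turn, mirror the
system's measured average of ~35 projections per full rotation at 30 fps;
the rotation-to-translation ratio is constant, which is exactly the
assumption the angle-recovery formula needs.

## Phantom

The phantom emulates a reconstructed tomogram of a suspended cell: white
Gaussian noise on the grid, low-pass filtered with a Gaussian kernel of
width `correlation_length` (default 0.8 µm — organelle-scale blobs without
recognizable structure), affinely rescaled inside the (spherical by
default) support into the physiological RI window [1.334, 1.410] over a
medium of n₀ = 1.334. The support edge is blended linearly over
`edge_voxels` (default 1) to avoid aliasing in projections; the hologram
round-trip tests use wider (resolution-scale) edges because a sub-resolution
hard edge is not something the optical system could deliver in the first
place. Generation is a pure function of the spec (including seed).
Isosurface thresholds at fractions f of the maximum are interpreted on the
contrast scale (f · max Δn); the literal absolute-RI reading (f · max n)
would select the entire volume for any f ≲ 0.95 and is exposed only as an
explicit option.

## Hologram processing

Processing follows standard off-axis practice; the non-obvious choices:

- **Demodulation.** The +1 order is located (auto mode: strongest off-DC
  peak in the upper half-plane, parabolic sub-bin refinement) or supplied,
  cropped with a disc of radius half the carrier magnitude, re-centred to
  the nearest FFT bin, and the sub-bin carrier residue removed by an
  explicit spatial ramp, so a pure carrier demodulates to a constant phase.
- **Autofocus.** Tamura coefficient TC = σ/µ of the amplitude, minimized
  over a candidate z grid; ties break towards the smallest |z|. The metric
  is evaluated as σ/µ (the √ variant is a monotone transform with the same
  argmin and is available as a flag). z̄ is estimated once, on the first
  frame of a sequence, and frozen.
- **Reference compensation** is complex division by an identically processed
  cell-free frame (which also cancels any common demodulation residue);
  phase subtraction would be equivalent on phase but would not flatten the
  amplitude. Because apodization drives the border amplitude to zero, a
  border margin (taper width + demodulation smear) is cropped before the
  division.
- **Unwrapping** uses a quality-guided 2D unwrapper with the usual
  congruence contract (output ≡ input mod 2π; smooth surfaces recovered up
  to one global 2πk). The specific graph-cut unwrapper used on the original
  instrument is a commodity step; only the contract matters downstream.
- **Windowed-Fourier denoising**: overlapping Hann-windowed patches,
  hard-thresholding of coefficients below `threshold` × RMS coefficient
  magnitude, overlap-add with exact window normalization (threshold 0 is
  the identity to machine precision). Borders are padded by odd reflection
  so smooth phase ramps continue linearly across the frame edge.

## Rolling-angle recovery

The Tamura Similarity Index is implemented as the Tamura coefficient of the
absolute frame-difference map after mean-offset removal, compared on
Otsu-masked, cell-centred crops. Two practical notes. First, σ/µ is
scale-invariant: at *exactly* zero noise the difference map at the full-turn
frame is a sparse interpolation residue whose contrast does not dip, and the
search degenerates; any realistic noise level regularizes it (the noise
floor dominates the difference map precisely when the cell returns to its
initial orientation). Second, the centroid used for the crops must be
computed on the segmented cell, not the raw frame — background noise
otherwise biases the centroid towards the frame centre by an amount that
grows with the cell's distance from it. A minimum-lag guard (default 10
frames, ~1/3 of an expected turn) excludes the trivial minimum at small
lags.

Angles follow θ_k = 360 · l_k / L360 with l_k the Euclidean centroid
displacement from frame 1; the assignment depends only on distances and is
therefore invariant to the channel tilt. Frames beyond the full-turn frame
are discarded from the tomographic set.

## Tomography

**Geometry.** After de-tilting, the flow runs along y and the cell rolls
about x: each x-column of the cropped QPM stack is an independent 2D
tomography problem in the (z, y) plane. The projector is a sparse
pixel-driven matrix (linear splitting of each pixel's footprint between the
two neighbouring detector bins, detector coordinate
t = y·cosθ + z·sinθ about the (n−1)/2 centre), so the exact transpose is
the matching back-projector and all adjoint identities hold to rounding.
FBP is implemented natively on this projector (band-limited Ram-Lak kernel,
optionally windowed; per-angle quadrature weights supporting non-uniform
angle lists over the full circle); its amplitude normalization was verified
against an independent reference implementation on uniform discs. Keeping
back projection on the same grid convention as the forward model avoids the
half-pixel centre offsets that mixing conventions produces.

**HOTV solver.** The objective min_x µ/2‖Ax−b‖² + ‖PA_k x‖₁ (x ≥ 0) is
solved with split-Bregman/ADMM: a conjugate-gradient x-update (the inner
loop, warm-started from the FBP reconstruction), soft shrinkage of the
difference coefficients, Bregman updates, and projection onto the
non-negative orthant, with 30/30 inner/outer iterations and a relative
objective-change stop at 1e−6. A monotone safeguard reports the
best-objective iterate, so the logged objective trace is non-increasing by
construction. All slices share one projection matrix and are solved jointly
as a block-diagonal system.

**DF mapping.** The published data-fidelity settings DF = 24/48/96/192 for
orders 1–4 refer to an external solver whose internal scaling is not
public. Here both operators are normalized to unit spectral norm, the data
weight is µ = df_scale·DF with df_scale a single calibrated constant, and
the ℓ1 term carries a per-order weight base^(−k). The calibration (constant
across all benchmarks and frozen in `HOTVConfig`) reproduces the published
relative behaviour of the four orders: TV operating deep in its
piecewise-constant regime, order 2 near its fidelity optimum, orders 3–4
progressively trusting the data (hence noise) more. The splitting weight is
λ = lambda_factor·µ; λ affects only the path taken in 30 outer iterations,
not the objective.

## The phantom benchmark and its calibration

The benchmark projects seeded phantoms at θ_j = j·Δθ for
j = 0…⌊360/Δθ⌋−1 — exactly 60 views at Δθ = 6° and 22 at Δθ = 16° — adds
Gaussian phase noise, reconstructs with FBP and HOTV-1…4, and scores 3D
SSIM (Gaussian window, σ = 1.5, standard constants; dynamic range = truth
max−min) against the truth over the entire volume. Projections for the
benchmark are generated by rotate-and-sum interpolation, a different
discretization from the reconstruction operator, to avoid an inverse crime.

Desk scale: the benchmark phantom is an 8 µm cell on a 48³ grid at 0.25 µm
voxels (texture correlation length 0.8 µm, one-voxel edge), and the
reported numbers average ten seeds; this keeps a full five-solver, ten-seed
run within minutes on one CPU core. The projection noise level is a
declared study condition (the physical counterpart — the residual phase
noise of the instrument — is not independently known); it was calibrated
once, together with the DF mapping, against the published SSIM table, and
frozen: σ = 0.0275 rad (`flowdht.tomo.BENCHMARK_NOISE_SIGMA`),
df_scale = 0.02, per-order weight base 10, λ = 2µ (`HOTVConfig` defaults).
In this configuration the mean SSIMs preserve the published solver ranking
(HOTV-2 ≥ HOTV-3 ≥ HOTV-4 > HOTV-1 > FBP); at noise levels below about
0.023 rad the order-2/order-3 margin closes, so the calibrated
neighbourhood is roughly σ ∈ [0.025, 0.035].

What the benchmark does *not* show: performance on RI textures unlike the
smoothed-Gaussian phantom family (sharp organelle boundaries, high-contrast
lipid droplets), robustness to angle-recovery errors (it uses exact uniform
schedules), or diffraction effects absent from the straight-ray model.

## Repeatability experiment

Five acquisitions of the same phantom are simulated with independent noise,
each processed end-to-end (holograms → QPMs → angles → HOTV-2 tomogram),
and compared by pairwise Pearson correlation after centring each tomogram
on its contrast centroid. Principal-axes re-orientation is available but
off by default: repeated simulated observations share a starting
orientation, and the sign ambiguity of eigenvector alignment can worsen
already-aligned volumes. Correlations are computed on full volumes (not
cell crops).

## Degenerate inputs and numerical tie-breaks

- Degenerate RI range (lo = hi): interior contrast is constant
  (lo − medium); with lo = medium the phantom is uniform background.
- Autofocus ties within 1e−12 of the minimum resolve to the smallest |z|.
- Full-rotation search ties resolve to the earliest frame.
- A zero sinogram reconstructs to exactly zero contrast (FBP) and the HOTV
  amplitude normalization guards against division by zero.
- Slices with empty support cost nothing extra: the joint block solve keeps
  them at zero.
- Hologram intensities must be finite and non-negative; phase maps finite.

## Known limitations

- The straight-ray model ignores diffraction within the cell; at NA 0.5 and
  8–10 µm cells this is the standard projection approximation, but it
  overstates resolution along z.
- The TSI-based full-rotation search can be off by one frame (it often is,
  by construction, when the true full turn falls between frames); at the
  system's ~10°/frame this bounds angle errors to about one angular step,
  which the reconstruction tolerates.
- SSIM against a randomly textured truth saturates differently from SSIM on
  real cells; absolute values of the benchmark depend on the declared noise
  level and texture scale, and only the full declared configuration is
  comparable across runs.
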