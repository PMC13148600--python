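# Methods

## Problem setting

In-line (Gabor) X-ray holographic microscopy records a single intensity
image — the interference of the unscattered reference beam with the wave
scattered by a weakly refracting object.  Recovering the object's phase
shift and absorbance from that one image is an ill-posed inverse
problem, and it becomes markedly harder under weak illumination, where
Poisson photon-counting (shot) noise dominates: the mean photon count
per pixel μ in the regimes treated here is 100–1000, i.e. a per-pixel
relative noise of 3–10%.

`holofield` implements a physics-driven neural-field reconstructor for
this regime, together with the classical Gerchberg–Saxton (GS) baseline,
a self-supervised residual U-Net baseline, a phantom/noise simulator
and a region-based evaluation harness.

## Forward optics

The scalar field on an L×M lattice with pixel pitch (Δx, Δy) propagates
between parallel planes with the angular spectrum method (ASM):

    U(z+d) = F⁻¹{ F{U(z)} · exp[ i 2π (n/λ) d √(1 − (λf_x/n)² − (λf_y/n)²) ] }

with evanescent components (negative radicand) hard-zeroed.  The
frequency lattice is the standard unshifted FFT lattice; no zero padding
is applied by default (the boundary-condition losses below take the role
padding would otherwise play, and the synthetic holograms are generated
on the same periodic lattice, so forward and inverse models match).

A 3-D object is a stack of N thin slices with per-voxel occupancy
arrays o_φ, o_A ∈ [0,1] and global coefficients φ (rad, negative for a
refractive-index decrement n = 1 − δ + iκ with δ > 0) and A ≥ 0.  A unit
incident beam enters at the source-side slice z_N (U_N = 1); each slice
multiplies the field by exp(i φ o_φ − A o_A) followed by a free-space
ASM step of Δz, and the final slice is followed by a single ASM jump
over the object-free gap z₁ → detector.  The detector records |U₀|².
φ and A are interpreted as total per-voxel-column values for a
one-slice-thick object (φ = −2πδt/λ, A = 2πκt/λ with t the physical
thickness); synthetic phantoms occupy exactly one slice at the object
depth z′.

All training gradients flow through this model via explicitly coded
Wirtinger adjoints: the adjoint of the ASM step is the ASM step with
conjugated kernel, and the per-slice cotangents give closed-form
gradients for o_φ, o_A, φ and A.  The reverse-mode chain (including the
coordinate MLP) is verified against central finite differences to 1e−4
relative error in the test suite.

## Synthetic data

The reference phantom places three objects (α, β, γ) with phase shifts
−0.3, −0.2, −0.1 rad and absorbances 0.03, 0.02, 0.01 on a 128×128 grid
with 10 nm pixels; the wavefield is propagated 100 µm at λ = 0.1327 nm
(9.344 keV) to form the noise-free hologram.  Glyph-shaped objects are
rasterized at run time from the bundled DejaVu Sans outlines (the exact
glyph geometry is font-dependent; all quantitative evaluation is
region-mean based and therefore glyph-shape robust).  A parametric disc
phantom with the same optical constants serves geometry-exact tests.

Shot-noise-limited holograms: per pixel the expected count is
λ_pq = μ·H_pq/H̄ (H̄ the spatial mean of H), a Poisson count C_pq is
drawn from a seeded `numpy.random.Generator` in row-major order, and the
hologram is rescaled as H′ = C/μ.  E[H′] = H/H̄ and Var[H′] = λ/μ²; both
are Monte-Carlo-verified.  No clipping or hot-pixel processing is
applied.

What the generator does *not* emulate: detector read noise, dark
current, flat-field error, partial coherence, cone-beam geometry and
polychromaticity.  Passing tests therefore demonstrate correctness of
the reconstruction machinery under ideal plane-wave, shot-noise-limited
conditions, not robustness to every artifact of a real beamline.

## Neural-field reconstructor

A coordinate MLP maps normalized voxel coordinates (x̃, ỹ, z̃) ∈ [0,1]³
to two occupancies (o_φ, o_A) ∈ (0,1): a fixed Gaussian Fourier-feature
projection (64 frequencies, scale σ) to a width-128 encoding, three
width-128 swish dense layers, and a 2-channel sigmoid output.  In-plane
coordinates are x/(LΔx); the axial coordinate is affine over the slice
stack [z₁, z_N] = z′ ± 40Δz (81 slices at reference scale).

Training is two-stage, full-batch (the forward model couples every
voxel to every detector pixel, so pixel mini-batching has no physical
meaning), with Adam:

1. **Pre-training** (default 300 epochs, lr 1e−3): MSE of both channels
   against a binary object-mask label replicated on the 2w_z+1 slices of
   the window z′ ± w_zΔz (w_z ∈ [5,10]), zero labels on all other
   slices.  The loss is averaged over the *full* slice stack, which
   simultaneously seeds the candidate region and suppresses occupancy
   far from z′.
2. **Physics training** (default 3000 epochs, lr 1e−4 synthetic; 2000 at
   1e−5 with trainable φ, A for experimental data): minimizes
   MSE(|U₀|², H) plus boundary losses — the MSE of both channels against
   zero on each of the three face pairs (x, y, z) of the volume, summed.
   The boundary losses suppress the wrap-around fringe artifacts that
   periodic propagation would otherwise reconstruct near the frame
   edges.

The object mask is obtained from the hologram back-propagated to z′.
Two segmenters are provided: the edge-based chain (Sobel gradient →
Otsu threshold → closing radius 2 → hole fill → minimum area 0.1%,
optional denoising and final erosion; every step parameterized) and a
contrast-based segmenter that thresholds the combined signal
−arg(t) + 5·(−ln|t|) of the back-propagated complex transmission at 20%
of its 99.5th percentile, after referencing the phase to the
unscattered background.  The contrast segmenter is the pipeline default
because on shot-noise-limited holograms the gradient image is
noise-flooded and the edge-based chain segments the twin-image fringes
along with the objects; the edge-based chain remains the default of
`segment_object_mask` itself.

**Early stopping.**  Fitting past the noise level makes the field absorb
shot noise (visible first in the absorbance channel).  When μ is known,
training stops once the 10-epoch-smoothed data loss falls below
0.8 · mean(H′)/μ — a discrepancy-principle stop at the expected
shot-noise variance floor, with the factor 0.8 accounting for the
fraction of noise variance the field has typically absorbed by the
reconstruction optimum of the loss-vs-error diagnostic curves.  A
patience rule (200 epochs on the smoothed data loss) covers the
unknown-μ case.

**Illumination normalization.**  The shot-noise generator rescales the
hologram by its spatial mean (λ = μH/H̄, H′ = C/μ), so a noisy
hologram's background sits at 1/H̄, slightly above 1.  A
unit-illumination model absorbs that offset as a systematic absorbance
deficit — sizeable relative to the 2A = 2–6% absorption contrast.  The
optional mean-normalized data loss MSE(I/mean I, H/mean H) removes the
sensitivity to the global illumination scale; it is part of the
experimental-mode protocol, where the flat-field division of a real
hologram makes the scale genuinely unknown and where trainable-A
recovery is badly corrupted without it.  On the
three-object synthetic benchmark it is left off: there the DC intensity
constraint helps the absorbance channel converge, and a same-seed
trajectory comparison showed the normalized loss slows it down.

**Coefficients.**  One global (φ, A) pair serves all objects; objects
with smaller optical constants are represented by fractional occupancy
(the three-object phantom converges to occupancies ≈ 1, 2/3, 1/3 with
φ = −0.3).  For experimental-style data φ and A are trainable,
initialized from literature values.  Final maps are extracted as
φ·Σo_φ and A·Σo_A summed over the pre-training window, so a one-slice
object reproduces its coefficient exactly.

## Gerchberg–Saxton baseline

Alternating projections between the detector plane (amplitude fixed to
√H, zero initial phase) and the object plane with transmission
constraints |t| ≤ 1 and arg(t) ≤ 0; kernels inside GS are divided by
their DC phase so the phase constraint acts relative to the unscattered
beam.  Default 500 iterations with early exit when the detector
residual stops changing (1e−8).

A single in-line hologram carries almost no low-frequency phase
contrast (phase CTF ∝ sin(πλd f²) → 0 as f → 0), so the plain
alternation converges to a slightly biased fixed point on noise-free
data, independent of iteration count.  The optional *support
refinement* mode closes this gap the way
the in-line-holography/CDI literature does: between rounds, an object
support is re-thresholded from the current reconstruction (20% of the
99.5th percentile of −arg(t) + 5·(−ln|t|), closed, filled, dilated
2 px) and transmission outside it is pinned to 1.  With six rounds the
noise-free phantom is recovered to below 0.01 rad phase MAE and 0.001
absorbance MAE (the acceptance thresholds the test suite checks).  The
plain variant remains the default and is
what the noisy-hologram benchmark and the acceptance script use; the
two variants bracket the behavior reported for GS implementations in
this setting.

## ResUNet baseline

A residual encoder–decoder (three 2× downsampling stages, symmetric
nearest-neighbor upsampling, skip connections, swish activations;
default widths 32/64/128 — free parameters, as channel widths are not
standardized for this baseline).  The phase head is a 1×1 convolution
with sigmoid scaled by 0.3 (magnitude of the largest expected phase);
the absorbance head feeds the phase map through one extra residual
block and a 1×1 convolution with leaky-ReLU scaled by 0.03.  The maps
are propagated to the detector with the same ASM operator and trained
against the same single hologram (default 3×10⁴ epochs at lr 1e−6) — no
training dataset.  The phase head produces a magnitude; the physical
negative sign is applied inside the forward model and in the returned
map.

## Evaluation

Maps are scored in five regions (entire frame, α, β, γ, background):
mean ± std, MAE against the reference, SSIM (Gaussian window σ = 1.5,
K1/K2 = 0.01/0.03, data range fixed to the reference span so methods
are comparable) with a horizontal-centerline profile, and the average
percentage error — the unweighted mean over the three object regions of
100·|mean_recon − truth|/|truth|.

## Desk-scale study conditions

The reference-scale benchmark (128×128×81, thousands of epochs) is a
GPU-scale computation.  The test suite reproduces the noise-robustness
study at a desk scale chosen once: 48×48 frame at 20 nm pixels, 13
slices at Δz = 20 nm, three parametric disc objects with the reference
optical constants, Fourier scale σ = 6 (the reference σ = 15 is
calibrated to a 128-pixel frame; the encoding bandwidth scales with the
grid so features stay resolvable — at σ = 15 on a 13-slice stack the
axial encoding aliases at roughly one cycle per slice), pre-training
40 epochs at lr 1e−3 (long pre-training saturates the sigmoid
occupancies and prolongs the subsequent collapse toward physical column
sums), physics training at lr 1e−3 capped at 450 epochs under the
discrepancy stop, three noise seeds per μ ∈ {1000, 300, 100}.

Noise levels are matched by *photon flux density*, not per-pixel count:
μ values are quoted per reference-scale 10 nm pixel, and the desk
grid's 20 nm pixels each collect 4× that.  This keeps the photons per
object region — and hence the attainable region-mean accuracy —
comparable to the reference-scale study; quoting μ per desk pixel would
double the relative noise and emulate a different experiment.

The experimental-mode surrogate runs at the experimental pixel pitch
(34.3 nm, Δz = 80 nm, 11 slices, σ = 10) on an 80×80 frame with a
digit-'1' glyph (φ = −0.278 rad, A = 0.023), shot-noise-limited at
μ = 600 (≈ the beamline's 60 photons px⁻¹ s⁻¹ × 10 s exposure), with
trainable coefficients initialized 10–30% off the truth and the
mean-normalized data loss.  Recovery is judged on the object-region
map means — the φ·occupancy product is the identifiable quantity, and
map means are also how experimental results are reported.  The GS
baseline and the acceptance script run at the full 128×128 reference
scale (GS iterations are cheap).

Even with flux-matched noise, smaller frames have fewer pixels per
object region, so desk-scale region means are intrinsically noisier
than reference-scale ones; the absorbance channel (10× weaker signal
than phase) is the first casualty, and its desk-scale errors run about
twice the reference-scale report.

## Numerical choices and degenerate inputs

- Evanescent frequencies are zeroed, not decayed; all propagation
  distances used are ≫ λ, where the difference is below float noise.
- The network and optimizer run in float32 (the optics in complex128);
  the gradient-check path supports float64 end to end.
- Sigmoid/swish use the saturating `1/(1+exp(−x))` form; overflow in the
  far tail saturates to the correct limit.
- A constant in-focus image segments to an empty mask (not an error);
  an empty mask yields an all-zero label stack, which drives the field
  to zero occupancy.
- GS returns its best iterate (by detector residual) with a warning if
  the residual oscillates.
- Training raises a `TrainingError` on NaN/Inf losses rather than
  continuing.
- Depth grids require an odd slice count so the object depth z′ is a
  lattice slice; the axial label window must fit inside the stack.

## Known limitations

- Plane-wave geometry only: cone-beam (Fresnel-scaling) propagation,
  partial coherence and detector PSF are out of scope; experimental
  geometries must be reduced to an effective propagation distance
  before use.
- The reconstructor targets thin (one-slice) objects; 3-D morphology of
  thick objects is not validated.
- The exact GS variant used in prior reports of "perfect noise-free
  reconstruction" is not published; this package documents two explicit
  variants instead (see above).
- Desk-scale hyperparameters (σ, learning rate, stop factor) were
  selected on μ = 1000 loss-vs-error diagnostics of the disc phantom and
  are not tuned per noise level.
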