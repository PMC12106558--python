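# Methods

## The reconstruction problem

Low-dose (LD) PET trades radiation exposure for signal-to-noise: reducing
the administered tracer dose (or scan time) by a dose reduction factor
(DRF) leaves fewer coincidence counts, and the reconstructed image is
correspondingly noisier. The package learns a mapping `f_θ` from an LD
slice to its full-dose (FD) counterpart from paired training data, and —
the point of the exercise — quantifies *how much to trust* each pixel of
the prediction, because a clinical reading needs to know where the network
is guessing.

## Posterior sampling with noisy-gradient training

Instead of a single maximum-likelihood weight vector, the trainer draws an
approximate sample from the posterior over network weights using stochastic
gradient Langevin dynamics (SGLD): at every epoch `t` the loss gradient
`g_t = ∇_θ L` is replaced by `g_t + e_t` with `e_t ~ N(0, s_t²)` i.i.d. per
component, and the Adam update is applied to the noisy gradient. The noise
scale `s_t` is tied to the current Adam learning rate, so when the plateau
scheduler cuts the rate by 10× the exploration noise shrinks with it. After
the loss curve has converged, the weight vectors of the last `N` epochs are
kept in a snapshot buffer; they are treated as an empirical posterior
sample.

At inference, one LD image is pushed through all `N` snapshots. The
pixel-wise arithmetic mean of the `N` reconstructions is the estimate, and
the pixel-wise population standard deviation (the `1/N` convention,
matching the mean) is the uncertainty map, reported in original intensity
units. Because the mean is a convex combination, `MSE(mean, FD)` never
exceeds the average per-sample MSE — the test suite asserts this exactly.

Decisions a reimplementer must make, and what this package chose:

- **Noise insertion point.** The Gaussian noise is added to the raw loss
  gradient *before* Adam's moment updates; weight decay (1e-10, coupled L2)
  is applied inside the optimizer afterwards and does not receive noise.
- **`s_t` tracks the current learning rate**, not the initial one
  (config-switchable, `noise.track_lr: current|initial`).
- **Snapshot cadence** is one snapshot per epoch at epoch end; "iteration"
  and "epoch" are used interchangeably throughout.
- **Scheduler input** is the mean total loss on the validation split
  (factor 0.1, patience 10, relative improvement threshold 1e-4).
- **Seeding.** The batch-shuffle stream, the gradient-noise stream and the
  dropout stream are independent children of the run seed, so disabling
  noise does not perturb the batch order and the SGLD and dropout runs see
  identical batches under a shared seed.

With noise disabled the loop is a plain Adam trainer; the test suite pins
this equivalence against a hand-coded Adam recursion to 1e-10 on a
two-parameter toy problem.

## Network

A residual U-Net in NHWC layout: a three-level encoder of 3×3 convolutions
with leaky ReLU (negative slope 0.01) at widths (32, 64, 128), 2×2 max
pooling between levels, one 3×3 bottleneck block at width 128, and a
symmetric decoder whose level input is the channel concatenation of the
nearest-neighbour-upsampled previous output with the matching encoder
feature map. A final 1×1 convolution with tanh activation produces a
bounded residual that is added to the input. Choices where the topology was
open: one conv + activation per level (the minimal reading of the
three-layer encoder), nearest-neighbour upsampling followed by convolution
(avoids transposed-conv checkerboard artifacts), reflective padding inside
convolutions, and a single bottleneck block. Inputs whose sides are not
multiples of 8 are symmetrically zero-padded and cropped back; the smallest
processable side is 16 (a 2×2 bottleneck).

**Normalization.** The tanh head bounds residuals to ±1, so images are
scaled into a ~[0, 1] working range by one dataset-level constant: the
99.9th percentile of the training FD intensities. The same scale
de-normalizes predictions, so metrics (lesion MAE in particular) are in
original activity units.

**The dropout benchmark** is the same backbone with channel-wise (spatial)
dropout of p = 0.2 after each encoder and decoder level activation, trained
by the identical loop with gradient noise off, keeping only the final
epoch's weights; its ensemble comes from `N` stochastic forward passes with
dropout active.

## Loss

`L = L1(pred, FD) + λ_gm · L1(‖∇pred‖₂, ‖∇FD‖₂)` with `λ_gm = 1.0` by
default (the mixing weight is not pinned by any reference value; 1.0 makes
the two terms comparable in the normalized domain and is config-exposed).
The gradient magnitude uses forward differences with a replicate boundary
(last row/column gradient is zero along its axis), which makes a linear
ramp's magnitude exactly constant; the loss is computed in the normalized
intensity domain so `λ_gm` is scale-free.

## Synthetic data

No clinical data ships with the package; a phantom generator stands in for
paired FD/LD whole-body slices.

- **Full-dose phantoms**: an elliptical body of low background activity
  (base uniform in 800–1500 count-like units with smooth Gaussian-filtered
  texture), 2–5 elliptical Gaussian "organ" bumps (amplitudes 1500–6500),
  and focal hot lesion disks (radius 2–4 px). The overall range, roughly
  [0, 10⁴], mimics quantitative PET units so lesion MAE values land on a
  clinically familiar scale (hundreds).
- **Lesion ROIs**: each lesion's paired background is a 2-pixel-dilated
  annulus around it, excluding the lesion. Lesion pixels are set to
  `bg_mean · (1 + c)` with `c` drawn from the requested contrast interval,
  so the measured Weber contrast is exact by construction.
- **Dose model**: `ld = DRF · Poisson(fd / DRF)`. This preserves the mean
  (`E[ld] = fd`) and scales the variance linearly (`Var[ld] = DRF · fd`),
  which is the count-statistics behaviour the uncertainty-vs-DRF analysis
  depends on. It is a surrogate for list-mode rebinning; there is no
  projection-space physics (attenuation, scatter, randoms), no 3-D
  structure, and no scanner point-spread function. Passing tests therefore
  demonstrate the *mechanism* — posterior spread tracking input noise — not
  clinical image quality on scanner data.

## Evaluation protocol

- **Global fidelity** per image against the FD reference: SSIM (11×11
  Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03 — the original SSIM
  constants), PSNR, and RMSE normalized by the reference dynamic range
  (`data_range = max(FD) − min(FD)` per pair). Identical images report
  PSNR = +inf.
- **Lesion level**: MAE over lesion pixels in original units, and Weber
  contrast `(mean_lesion − mean_bg)/mean_bg`; contrast is recorded as NaN
  when a reconstruction's background mean is non-positive (undefined).
- **Uncertainty scores**: per image, the 95th percentile (linear
  interpolation between order statistics) and the mean of the std map; per
  DRF, the median across images of each score; the headline number is the
  r² of an ordinary least-squares fit of the per-DRF median against DRF.
- **Significance**: two-sided paired t-tests per metric and DRF between
  methods. DRFs are tested separately with no multiple-testing correction —
  five DRFs mean five uncorrected tests per metric, a deliberate reporting
  caveat.

## Problem sizes and numerical choices

The shipped study trains on 60 phantoms of 64×64 pixels with pairs at
DRF ∈ {4, 10, 20, 50, 100} (train/val/eval split 0.6/0.2/0.2), 30 epochs
with N = 10 snapshots, batch size 64, learning rate 5e-4 — a desk-scale
version of the protocol (full-scale training uses 200 epochs and N = 50 on
tens of thousands of clinical slices). Stochastic end-to-end checks run up
to three pre-registered seeds and require a majority.

The network core is a compact reverse-mode autodiff engine over NumPy:
convolutions lower to per-tap BLAS matmuls on contiguous NHWC slabs, large
intermediates come from a slot-pooled scratch allocator that recycles
buffers across fixed-structure training steps, and the default working
precision is float32 (float64 is used where tests demand 1e-10 agreement).
Every operator's adjoint is verified against central finite differences.
Statistical unit checks use multiplicity-aware bounds: a per-pixel
"3 standard errors" criterion applied to thousands of pixels is required to
hold for ≥ 99.5% of pixels with all z-scores under 6, and pooled-variance
checks (which are strictly sharper) are applied at 3 SE.

## Known limitations

- The dose model ignores acquisition physics; absolute uncertainty
  magnitudes on real scanner data will differ.
- At desk scale (~90 gradient steps) the network is far from converged;
  reconstruction quality numbers are qualitative, not comparable to
  full-scale training.
- The plateau scheduler's improvement threshold (1e-4 relative) is a fixed
  convention; other defaults shift when reductions fire.
- Uncertainty maps are raw ensemble standard deviations; no calibration
  (e.g. temperature scaling) is applied, so they are rank-informative
  rather than calibrated confidence intervals.
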