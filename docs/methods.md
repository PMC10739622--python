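# Methods

This note records the models implemented in `petdenoise`, the assumptions and
numerical conventions behind them, and the design decisions taken where the
method family leaves choices open.

## Simulation model

**Acquisition.** The default protocol is a 60-minute, 21-frame dynamic brain
acquisition (6×30 s, 3×1 min, 2×2 min, 10×5 min), the standard framing for a
¹¹C-labelled synaptic-density tracer. All times are minutes, activity is
Bq/mL, and dynamic arrays are indexed `(x, y, z, frame)`.

**Input function.** `feng_aif` produces a Feng-style arterial plasma curve: a
linear rise from zero to the peak at `peak_time` (default 1 min) followed by a
tri-exponential washout `Σ Aᵢ e^(−λᵢ(t−t_peak))`. Defaults
(A = 6000/1500/800 Bq/mL, λ = 4/0.25/0.015 min⁻¹) give a sharp bolus peak, a
fast distribution phase, and a slow tail, qualitatively matching
metabolite-corrected plasma curves. The curve lives on a uniform 1-s grid
whose step divides every frame boundary.

**Tissue kinetics.** Each region follows the one-tissue compartment model
C_T(t) = K₁ · (C_p ⊗ e^(−k₂t)). The convolution is evaluated on the 1-s grid
by trapezoidal quadrature and frame values are exact trapezoidal time-averages
over each frame interval; against the closed form for an exponential input the
frame-averaged error is below 0.1%.

**Phantom geometry.** The label volume (default 64×64×48, 2 mm isotropic)
holds six regions inside an ellipsoidal head: a thick cortical gray shell, a
white-matter core, a central deep-gray blob, left/right putamen-like blobs,
and a cerebellum. Structures are deliberately large — several times the 8 mm
patch/filter scale — so that gray-matter ROI means are interior-dominated.
This mirrors the surface-to-volume regime of the lobar structural ROIs used
for regional quantification in human studies; ROI means of few-voxel ribbons
are dominated by partial-volume flux under *any* smoother, which would probe
the ROI geometry rather than the denoiser. Regional quantification uses the
gray-matter structures only (human structural ROI sets contain no white-matter
ROI); white matter stays in the phantom to provide kinetic contrast.

**Within-region heterogeneity.** Real gray matter is not kinetically uniform:
uptake varies on the order of 10–20% at a few-mm scale. `texture_field`
multiplies voxel-wise K₁ by a smooth Gaussian random field (σ = 6 mm,
amplitude 0.15, mean 1, clipped at 0.1). Without it a piecewise-constant
phantom gives a patch-based denoiser no in-region structure to learn and every
spatial method degenerates toward its mean-filter limit. Ground-truth kinetic
parameters per region span K₁ 0.10–0.30 mL·cm⁻³·min⁻¹ and k₂
0.05–0.11 min⁻¹ (V_T 0.9–5.6).

**Resolution and counts.** An isotropic 3 mm FWHM Gaussian emulates the
reconstructed scanner resolution. Counts are modelled at the image level:
expected counts per voxel/frame are activity × sensitivity × frame duration,
with the scalar sensitivity calibrated so full-count 5-min frames average a
configurable 50 counts/voxel — placing the 1/10-count frames in the tens-of-
percent ensemble-noise regime typical of 1/10-dose dynamic imaging.
Radioactive decay is ignored (reconstructed images are decay-corrected); no
sinogram, attenuation, scatter, randoms, or motion modelling is attempted.

**Dose reduction by thinning.** One full-count Poisson draw is partitioned
into 10 disjoint subsets by multinomial thinning with equal probabilities —
the count-level analogue of redistributing list-mode events into subsets. The
partition conserves total counts exactly, each subset is marginally Poisson at
one tenth of the mean, and the subsets carry the same mild negative
cross-realization correlation as disjoint list-mode subsets. Independent
draws are available via `partition=False`. All randomness descends from one
seed through a `numpy.random.SeedSequence` spawn (count stream, training
stream, texture stream).

## The patch ANN

**Training data.** The reduced-count training frame is normalized to [0, 1] by
its maximum; the full-count label frame is divided by the same constant
(activity units agree across dose levels, and a shared constant preserves the
identity mapping's scale — normalizing the label frame by its own maximum is
available via `shared_norm=False`). Every stride-1 4×4×4 patch yields an
input vector (its own mean removed) and a label — the central 2×2×2 of the
co-located full-count patch.

**Label baseline.** The label's subtracted baseline is the mean of the
co-located 4×4×4 full-count patch (`label_mean="patch"`, default). The
network then predicts the center-versus-neighborhood offset, and the
test-time reconstruction — which adds the 4×4×4 *test*-patch mean back —
preserves local means up to the network's prediction error. The alternative
(`label_mean="central"`: subtracting the central patch's own mean) silently
couples every reconstructed voxel's local mean to its 4×4×4 box mean,
i.e. builds an irreducible patch-sized box smoother into the method; on
brain-like geometry we measured ROI-mean biases of −10…−45% from that
coupling alone, which is why the offset-predicting convention is the default.

**Patch selection.** Of all extracted pairs, the `high_variance_count` with
the largest label variance (edges, boundaries, strong texture) are kept and
the rest of the K pairs are drawn uniformly without replacement (seeded) from
the remainder — K = 100 000 with a 50/50 split at full scale.

**Scaling.** Each of the 64 input and 8 label features is min-max scaled to
[−1, 1] using extrema over the K training pairs. Test-time features outside
the training extrema are mapped by the same affine map without clipping
(clipping would bias hot voxels). Degenerate features (max = min) scale to 0
forward and recover the stored constant backward.

**Optimization.** Mini-batch SGD (batch 64, "iteration" = one parameter
update, seeded reshuffle each epoch) on the mean squared recovery loss;
learning rate lr_t = 0.01·(1 + 10⁻⁴t)^(−0.75) (the conventional inverse-decay
defaults); 150 000 iterations at full scale; symmetric uniform fan-in
initialization; offsets start at zero. Training is bitwise reproducible for a
fixed seed, and a non-finite loss aborts with a diagnostic. The per-batch
loss trace is kept on the model for convergence checks.

**Testing.** Per cascade pass the frame is normalized by its own maximum,
replicate-padded by one voxel (so border voxels are covered; interior voxels
receive exactly 8 overlapping outputs), every patch is pushed through the
network with the *training* scaling records, outputs are inverse-scaled, the
test-patch mean is added back, the 8 contributions per voxel are averaged,
and the frame is un-normalized. Three passes are the default; pass count is
the method's smoothing dial.

## HYPR and comparators

The composite is the duration-weighted mean of **all** frames. The box filter
uses replicate padding (as does every border in the package). Where the
box-filtered composite is below 10⁻⁹ × max(C), the ratio weight is set to 1 so
empty background falls back to the composite instead of amplifying noise.

Gaussian filtering is specified in mm FWHM (σ = FWHM/(2√(2 ln 2)) per axis in
voxel units). The matched-noise protocol (`match_gaussian_fwhm`) bisects the
FWHM until the filtered ensemble noise matches a target — how a smoothing
comparator is put at equal noise reduction before comparing bias.

NLM-ST weights are w = exp(−d²/h²), with d² the mean squared difference of
two 4D neighborhood blocks (spatial borders replicate-clamped, temporal
neighbors clamped at the first/last frame) and the center voxel weighted like
any other. Because the intensity scale of the data is arbitrary, h is
specified as a multiple of a robust noise estimate:
σ̂_f = 1.4826 · median|∂₁I_f|/√2 per frame, restricted to nonzero-support
differences (empty background would drive the median to zero), averaged over
the target frame's temporal window. The temporal search window is a 7-frame
block centered on the target frame and clamped at the scan ends
(`centered-sliding`); the `fixed-range` policy reproduces a fixed mid-scan
block (frames 9–15) for all targets. No spatial taper is applied inside the
neighborhood distance.

## Kinetic fitting

100 log-spaced k₂ bases on [0.01, 1.0] min⁻¹ (log spacing follows standard
basis-function practice; count configurable). For each basis,
K₁ⱼ = Σwᵢ Bᵢⱼ yᵢ / Σwᵢ Bᵢⱼ², clipped at zero because negative uptake is
unphysical; the basis minimising the weighted residual sum of squares wins,
and V_T = K₁/k₂ holds identically over the maps. An all-zero TAC returns
(K₁, k₂, V_T) = (0, k₂_min, 0) by convention. Frame weights are
wᵢ ∝ Δtᵢ²/Cᵢ with Cᵢ the total image counts of frame i — an image-level
surrogate for noise-equivalent-count weighting (true NEC requires randoms and
scatter rates that do not exist at image level); uniform weighting is the
fallback when counts are unknown. No blood-volume term is modelled.

With the true k₂ on the grid, recovery is exact to solver tolerance; off-grid
truth lands on a bracketing grid point, bounding parameter errors by the grid
step (<2% at 100 bases).

## Evaluation

EnNSD uses the sample standard deviation across realizations (divisor J−1)
divided by the across-realization mean per voxel, averaged over ROI voxels;
voxels with |mean| below 10⁻⁶ × the image maximum are excluded and counted.
RE averages, over realizations, the relative difference of the ROI mean
against the full-count reference. NR is the percent EnNSD reduction against
the raw reduced-count stack, and the dose-equivalence factor 1/(1 − NR)²
follows from σ ∝ 1/√dose under Poisson statistics. For dynamic series the
EnNSD/RE pool voxel-frames, matching table-style "all frames" summaries;
per-frame rows are available from the sweep table.

## Problem sizes

Two profiles drive the end-to-end study (`DemoProfile`):

* **demo** (default; used by the test suite): 48×48×32 phantom, 10
  realizations, K = 30 000 training pairs (≈59 000 available at this frame
  size), 20 000 SGD iterations, NLM windows 3×3×3×3 / 3×3×3×3, h sweep
  0.5/1.0/1.5 via a shared-distance multi-h pass. Chosen as the smallest
  scale at which the gray ROIs remain interior-dominated at the patch scale.
* **full_scale**: 64×64×48, K = 100 000, 150 000 iterations, NLM
  11×11×11×7 / 7×7×7×7.

The noise-matched Gaussian bisection runs 12 iterations on [0.05, 10] mm.

## What the phantom does and does not show

The generator reproduces the *statistical* structure of the problem — 1T
kinetics driven by a shared input function, scanner-resolution blur, Poisson
counting noise at a calibrated level, disjoint thinned realizations — so the
package's ordering results (cascade monotonicity; the chained spatiotemporal
method dominating each comparator's noise reduction at small regional bias;
temporal filtering translating poorly into parametric noise reduction) are
properties of the methods, not of one dataset. It does **not** contain
reconstruction artifacts, anatomical fine structure at sub-patch scale,
inter-subject variability, motion, or plasma-measurement error; passing tests
therefore demonstrate correctness and qualitative behavior, not clinical
performance on human data.

## Known limitations

* Image-level count model: no sinogram physics, randoms/scatter, or decay.
* A single scalar sensitivity; no axial sensitivity profile.
* The ANN is the single-hidden-layer patch architecture by design;
  convolutional or autoencoder variants are out of scope, as is cascade
  *training* (only cascade testing is implemented).
* NLM-ST's h convention is σ̂-relative; absolute-h comparisons with other
  implementations require rescaling.
* HYPR uses the full-scan composite; windowed composites are not implemented.
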