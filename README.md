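# petdenoise

Spatiotemporal denoising and kinetic analysis for **reduced-count dynamic PET**.

Lowering the injected dose of a PET tracer raises the Poisson noise in every
reconstructed time frame, and that noise propagates — amplified — into the
parametric images computed by voxel-wise kinetic modelling. `petdenoise`
implements a denoising chain built for this problem, the reference methods it
is compared against, the kinetic fitting that turns frames into parameter
maps, and the ensemble evaluation machinery that quantifies the noise-vs-bias
tradeoff. Because clinical dynamic scans are rarely shareable, the package
also ships a synthetic dynamic brain phantom with count-accurate Poisson
thinning, so the whole study runs end-to-end from a single seed.

It is written for imaging-methods researchers: everything is importable from
Python (see `examples/`), and a thin `petdenoise` CLI wraps the common steps
(`simulate`, `train`, `denoise`, `hypr`, `annhypr`, `gauss`, `nlmst`, `fit`,
`evaluate`, `demo`).

## The method

**Cascade patch ANN.** A single-hidden-layer fully connected network
(64 → 128 ReLU → 8) is trained on *one* pair of frames — a 1/10-count frame
and its full-count counterpart — by mapping each mean-removed 4×4×4 patch
x̃ ∈ ℝ⁶⁴ to the central 2×2×2 of the co-located full-count patch:

    β = W₂ · ReLU(W₁ x̃_scaled + b₁) + b₂,

minimising (1/K) Σₖ ‖βᵏ − x_scaledᵏ‖² by mini-batch SGD with an inverse-decay
learning rate. Patches are min-max scaled per feature to [−1, 1]; of all
stride-1 patches, the half with the largest label variance (edges, texture)
plus a random half of the remainder form the K training pairs. At test time
every voxel is covered by 8 overlapping output patches, which are averaged;
feeding the output back through the network ("cascade", default ×3) increases
noise reduction at slowly growing bias.

**HYPR composite-ratio filtering.** Each frame Iᵢ is replaced by

    Hᵢ = C · F(Iᵢ) / F(C),     C = Σᵢ Δtᵢ Iᵢ / Σᵢ Δtᵢ,

where F is a cubic box filter (default 7×7×7) and C the duration-weighted
composite of all 21 frames: voxel noise is inherited from the high-SNR
composite while the ratio weighting preserves each frame's kinetics. The
headline chain **ANN+HYPR** applies HYPR to the cascade-ANN-denoised series.

**Comparators.** Frame-wise Gaussian smoothing at noise-matched FWHM
(bisection on ensemble noise) and a 4D spatiotemporal non-local means
(NLM-ST, search/neighborhood windows up to 11×11×11×7 / 7×7×7×7).

**Kinetics.** The one-tissue compartment model
C_T(t) = K₁ · (C_p ⊗ e^(−k₂t)) is fitted voxel-wise by the basis function
method: 100 log-spaced k₂ values on [0.01, 1.0] min⁻¹, a weighted
least-squares K₁ per basis, frame weights ∝ Δt²/counts, and V_T = K₁/k₂.

**Evaluation.** Across J = 10 disjoint 1/10-count realizations:
EnNSD (per-voxel coefficient of variation across realizations, ROI-averaged),
RE (regional mean error vs the full-count reference), NR (percent EnNSD
reduction vs raw), and the Poisson dose-equivalence factor 1/(1 − NR)².

## Worked example

`python examples/04_kinetic_fit.py` — parameter recovery on the noise-free
phantom (grid quantization is the only error source):

```
region          K1 true   K1 fit  VT true   VT fit
cortex            0.250    0.252     4.55     4.51
white_matter      0.100    0.101     0.91     0.90
thalamus          0.300    0.304     5.00     4.95
putamen_l         0.280    0.283     5.60     5.55
putamen_r         0.260    0.258     4.00     4.02
cerebellum        0.220    0.218     2.93     2.95

max VT error over brain voxels: 1.01% (bounded by the log-spaced k2 grid step)
```

`python examples/03_hypr_chain.py` — the denoising chain on a 1/10-count
series (RMS residual against the noise-free truth, brain voxels):

```
  raw 1/10-count :   1669.3
  HYPR box 7     :    288.1
  ANN+HYPR       :    242.8
```

`python examples/05_noise_bias_study.py` runs the full comparison (ANN ×1/2/3,
ANN+HYPR, HYPR box 3/5/7, noise-matched Gaussian, NLM-ST) and prints the
EnNSD/RE/NR table; on the seeded study the chained ANN+HYPR attains the
largest noise reduction on frames and on the K₁/V_T maps while keeping the
regional bias at a few percent, e.g. frames 91.7% NR at −3.5% RE versus
82.9% / −0.0% for HYPR alone and 71.1% / −5.7% for noise-matched Gaussian.

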