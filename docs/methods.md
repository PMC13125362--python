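# Methods

This note documents the models, defaults and numerical choices behind
`pdscribe`, and what its synthetic experiments do and do not demonstrate.

## The drawing simulator

Each subject is a `MotorProfile` drawn around a class-level profile with
seeded Gaussian spread (truncated to valid ranges), so subject-independent
splits are meaningful: two drawings by the same simulated subject share a
motor signature. Base curves:

* **spiral** — Archimedean r(θ) = aθ over 6 revolutions, a chosen so the
  outermost turn fills 42% of the canvas half-width;
* **meander** — a triangle-wave sweep in x with linear advance in y over 6
  folds (a square-wave folded path after rasterization);
* **wave** — a sinusoid over 5 cycles spanning the canvas.

Three distortion channels map one-to-one onto the clinical signs they
emulate, with units in canvas pixels:

| parameter | meaning | control | PD mild / moderate / strong |
|---|---|---|---|
| `tremor_amplitude` | peak of a sinusoidal displacement, radial for spirals, normal-to-path otherwise | 0 | 1.5 / 3.0 / 5.0 px |
| `tremor_frequency` | tremor cycles per radian of the parameter sweep | 1.2 | 1.2 |
| `jitter_sd` | white positional noise | 0.5 | 1.0 / 1.5 / 2.0 px |
| `micrographia_factor` | per-revolution amplitude multiplier | 1.0 | 0.97 / 0.93 / 0.88 |
| `drift_sd` | total s.d. of a slow random-walk drift | 1 | 2 / 3 / 4 px |

The tremor frequency of 1.2 cycles/radian corresponds to roughly 45 tremor
cycles over a 6-turn spiral — a 4–6 Hz physiological tremor at a ~10 s
drawing time. The tremor phase is a seeded uniform draw, so the deviation
of a noise-free-except-tremor spiral from r = aθ is exactly a sinusoid of
the configured amplitude (RMS A/√2), which the tests exploit as a
closed-form calibration oracle. Rasterization uses Bresenham lines with
optional disk dilation and **no anti-aliasing**, keeping inked-pixel counts
exactly enumerable. The default stroke width is 2 px on a 512-px canvas so
strokes survive the 3×3 median denoise and downsampling to 64 px.

What the simulator does **not** emulate: pen kinematics (velocity,
pressure, in-air movement), paper texture, scanner artifacts, template
guidelines, or the heterogeneity of real clinical populations. A model that
separates these synthetic cohorts has learned that high-frequency stroke
oscillation and amplitude decay are class-discriminative — the intended
sanity check — but that says nothing quantitative about performance on real
patient drawings.

## Preprocessing

Denoising is a 3×3 median filter followed by removal of connected ink
components under 5 px (8-connectivity); this kills impulse specks while
preserving strokes at least ~3 px wide. Ink segmentation is Otsu's
between-class-variance threshold (256 bins); a constant image raises
`NoInkError`. Cropping uses half-open, 0-based boxes. Geometry
normalization rotates the ink's principal second-moment axis to horizontal
**only** when the eigenvalue ratio exceeds 1.2 — spirals are nearly
isotropic and have no meaningful axis — then isotropically rescales the
content so its longer side fills 90% of the canvas and centres it with the
floor((size − content)/2) convention. Resampling is bilinear throughout.
Single-pixel content skips scaling and is centred only.

Channel fusion supports the two readings of a three-channel drawing input:
`multitask` stacks (spiral, meander, wave) in that fixed order, and
`single_filtered` stacks (raw, Sobel edge-enhanced, Gaussian σ=1 smoothed)
views of one drawing. `multitask` is the default for cohorts that have all
three tasks; the synthetic benchmark uses `single_filtered` on spirals so
the cohort only needs one task per subject.

## Network

Input H×W×3 (default 256). Each of the five stages applies two convolution
blocks (conv → batch norm → ReLU) and a max-pool; stages 1–2 are fully
depthwise-separable, stages 3–5 open with one standard convolution and stay
separable after it. Kernel size 3, He-normal initialization, stride-2
pooling per stage by default. The three attention branches tap stages 3–5;
each projection is one pointwise convolution to depth d = 192 followed by
adaptive average pooling to 7×7 (PyTorch-style window bounds
[⌊iS/7⌋, ⌈(i+1)S/7⌉)). Attention uses H = 4 heads by default (H must
divide d), scaled dot-product per head, concatenation, output projection
and a residual connection; deliberately **no layer normalization** and no
positional encoding, which keeps two exact algebraic properties testable:
uniform softmax under zero query/key weights, and permutation equivariance
of the token sequence. The gating network is shared across branches:
score_b = w_gᵀ ReLU(W_g u_b + b_g) on the spatially averaged descriptor
u_b, hidden width 48 (= d/4), softmax over the three scores. Fusion
concatenates the α-scaled branch maps (7×7×576), reduces to 32 channels
with one pointwise convolution, global-average-pools, applies dropout
(rate 0.3, training only), and classifies with a dense 32→2 softmax head.
Class index 0 is PD, 1 is healthy; cohort labels use 1 = PD, so the label
to class-index map is `1 - label`.

The backward pass is hand-wired for this fixed graph. A finite-difference
check (central differences, ε = 1e-7) on a sampled subset of parameters of
a tiny configuration agrees with backpropagation to <1e-4 relative error;
ε much larger than 1e-7 sits on ReLU-kink plateaus and is not a valid
comparison. Conv biases behind batch norm have analytically zero gradients
(the mean subtraction absorbs them); they are retained for the
batch-norm-free configuration.

The width-reduced benchmark configuration divides the stage filters by 8
(8, 16, 32, 64, 64) at 64×64 inputs and switches stages 4–5 to stride-1
pooling so every branch keeps at least a 7×7 grid — the projection
contract requires source maps no smaller than the projected size.

## Training

Adam (β₁ = 0.9, β₂ = 0.999) with **decoupled** weight decay 1e-4 applied
to weight matrices only (not biases or batch-norm parameters) — the
standard reading of "L2 weight decay with Adam". Cosine annealing
η(t) = η_min + (η₀ − η_min)(1 + cos(πt/T))/2 with η₀ = 1e-3, η_min = 1e-6,
batch size 32, at most 150 epochs. Early stopping monitors validation F1
with patience 15; only a strictly greater F1 counts as improvement, and
the returned model is the best-F1 checkpoint (parameters and batch-norm
running statistics). Train/validation subject overlap is a hard
`LeakageError`, and augmentation is applied to the training stream only
(asserted by call tracing in the tests). The stratified test reservation
rounds per class by largest remainder, anchored so a 38 + 37 cohort at 20%
reserves 8 + 7 subjects. Elastic augmentation uses a smoothed (σ = 8 px)
random field rescaled to a 4 px peak displacement; parameters are sampled
once per image per epoch.

## Hyperparameter search

Search space defaults: η₀ ∈ [1e-4, 5e-3] (log), B ∈ {16, 32, 64}, dropout
∈ [0, 0.5], weight decay ∈ [1e-6, 1e-3] (log), heads ∈ {2, 4, 6, 8},
attention dim ∈ {96, 192}. Continuous genes live in transformed (log10)
coordinates; mutation is Gaussian with σ = 10% of the transformed range,
tournament size 2, crossover rate 0.9, per-gene mutation rate 0.2,
population 10 with elitism. Each generation evaluates P − 1 GA offspring
plus one Gaussian-process expected-improvement proposal (Matérn ν = 2.5
surrogate on [0,1]-encoded coordinates, acquisition maximized over a
256-candidate seeded pool; categorical genes are ordinal-encoded — crude
but adequate for the small spaces used here). β defaults to 0.1 (mild cost
pressure; with β = 0 the ranking reduces to M alone). C_max is the running
maximum of observed costs; all stored J values are re-normalized against
the final C_max so records are mutually comparable, which preserves the
non-increasing best-so-far property. Failed evaluations are recorded with
J = +inf and flagged; the search continues.

## Clinical evaluation

AUC follows the tie-as-half concordance convention; AUPRC uses
step-interpolated average precision (linear interpolation inflates PR
areas) with precision 1 at the recall-0 endpoint. The "70% bootstrap
subset" is implemented as subsampling **without** replacement — a reduced
cohort — with the classical with-replacement bootstrap behind a flag;
resamples missing a class are redrawn (capped and counted). Triage assigns
the closed interval [0.30, 0.70] to the gray zone: boundary scores get the
conservative referral, a deliberate screening choice. Dichotomization for
PPV/NPV is `p > threshold`; empty predicted classes yield NaN with an
explicit flag rather than a silent zero.

## Explanations

Superpixels come from SLIC (k-means in (x, y, intensity), compactness 10,
connectivity enforced, ids relabelled to 0..S−1). The attribution target is
the PD posterior (not the logit), against a blank-paper (all-zero) baseline
by default; a mean-intensity baseline is available. Exact mode enumerates
all 2^S coalitions (S ≤ 14). Sampled mode draws coalition sizes from the
normalized SHAP kernel (s−1)/(C(S,s)·s·(S−s)), always includes the empty
and full coalitions at effectively infinite weight (1e7) — pinning the
regression to the efficiency constraint — and solves the weighted least
squares in closed form. On additive toy games the 2000-sample estimate is
within 0.01 of the exact values.

## Problem sizes used in the shipped experiments

The synthetic benchmark trains the reduced configuration on 40 + 40
subjects (spiral task, strong effect, single_filtered fusion at 64 px)
under a subject-independent 80/20 split for up to 30 epochs, batch 16,
returning the best-validation-F1 checkpoint; five seeds are run and at
least four must reach ≥ 0.90 held-out accuracy. The tuner's recovery check
uses a deterministic 2-gene toy objective with a brute-force grid scan as
the oracle at budget 60. These sizes were chosen as the smallest at which
the class-separation and optimizer-recovery claims are meaningfully tested.

## Known limitations

* The NumPy implementation is CPU-only and unsuited to full-scale training
  of the 256-px, full-width model; the full configuration is exercised for
  shape/parameter contracts and single forward passes.
* Categorical ordinal encoding in the GP surrogate imposes an artificial
  order on unordered choices.
* The simulator's distortions are stylized; no claim is made about
  transfer to real clinical drawings, online pen kinematics, or scanner
  artifacts.
* Calibration of the posterior (relevant to the triage thresholds) is not
  analysed; thresholds are treated as frozen inputs.
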