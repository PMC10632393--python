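# Methods

This note documents the models, parameter choices and numerical decisions
behind melanopt, stage by stage, including what the synthetic-data
generator does and does not emulate.

## Synthetic dermoscopy generator

The generator exists so that every stage — and the end-to-end pipeline —
can be exercised and benchmarked without external image collections. A
sample is built in this order, all randomness from one seeded generator:

1. **Background**: a base skin tone (0.72) modulated by a low-frequency
   multiplicative cosine gradient (2–6% amplitude), then tinted to RGB with
   fixed channel weights (1.0, 0.8, 0.72). This mimics smooth illumination
   and skin-tone variation without external texture assets.
2. **Lesion**: an ellipse (default radii 20×14 px in a 96×96 frame) whose
   boundary radius is perturbed by two random sinusoids scaled by a jitter
   fraction; the support is recorded as the ground-truth mask *before* any
   overlay. The fill is darkened by 0.35, with optional darker concentric
   core tones.
3. **Class rules**: melanoma draws jitter from [0.15, 0.30] and 2–3 fill
   tones; benign from [0, 0.05] and a single tone. Boundary irregularity
   and multi-tone fill are the standard dermoscopic cues (asymmetry, color
   variegation), encoded in a controllable, learnable form.
4. **Overlays**: quadratic Bézier hair strands 1–3 px thick (strictly
   below the 10-px closing size), Gaussian blur (σ = 0.8 px) and additive
   Gaussian noise (σ = 0.02).

What it does **not** emulate: specular reflections, ruler/gel artifacts,
color constancy shifts, multi-lesion frames, and the fine texture of real
skin. Tests passing on these images therefore demonstrate the mechanics
and the relative behavior of the stages, not clinical performance.

Feature-space datasets (for optimizer/classifier tests) are two isotropic
Gaussian clouds in 100 dimensions, means `separation` apart along a random
unit direction — an idealization of the CNN's 100-d embedding.

## Preprocessing

The hair/vessel remover is a grey closing with a cross-shaped structuring
element: the union of a vertical (90°) and a horizontal (180°) line arm
through each pixel, symmetrized to odd support (11×11 for the default
`se_len = 10`). A dark structure survives only where a full arm fits
inside it, so strands under 10 px across are raised to the surrounding
skin level regardless of orientation, while lesion interiors (wider than
the arms in both axes) are untouched. Using one composite closing rather
than a chain of directional dilations/erosions keeps the operator a true
morphological closing — idempotent and extensive — which the test suite
asserts exactly. RGB images are closed per channel (standard hair-removal
practice); borders are edge-replicated everywhere to avoid dark halos.

Sharpening subtracts a Laplacian-of-Gaussian response from the **closed**
image: `P = Î − Î * K`. The kernel uses the standard negative Gaussian
exponent and is renormalized to sum exactly to zero after discretization,
so flat regions are exact fixed points of the whole chain. Subtracting
from the closed image (rather than the raw input) is what makes the output
hair-free: the closed image carries no strands, and its LoG response
cannot reintroduce them. Defaults: δ = 1.5 px, kernel radius ⌈4δ⌉ = 6
(4σ support is a standard truncation); output clipped to [0, 1].

## Segmentation

The Kohonen network is a single competitive layer of scalar intensity
prototypes (default 2×2 grid = 4 units) trained winner-take-all on a
strided pixel subsample (stride 4, 2 epochs): the closest unit moves by
`w ← (1−α)w + αx`, others are unchanged, with α decaying linearly from 0.5
to 0 over the training steps. No neighborhood function is used — the
update is pure winner-take-all; the codebook is initialized as a linear
ramp over the observed intensity range, which makes the α = 0 schedule an
exact identity (a tested property). Ties in winner selection and all
nearest-coefficient lookups break toward the lowest index for determinism.

The initial mask is the darkest cluster's pixel set, cleaned by removing
any foreground component touching the frame border (the outer region is
background by construction) and filling holes in the largest remaining
component. Greedy refinement then iterates

    u' = u + [(X − K(I_out))² − (X − K(I_in))²] · |∇u|,   u ← (u' > 0)

with the inside/outside means recomputed every iteration and matched to
their nearest codebook coefficients. The gradient factor (central
differences, edge-replicated) confines changes to the current boundary, so
the mask moves at most one pixel per iteration; iteration stops at the
first fixed point or after `max_iter = 100`. A mask that empties or floods
mid-refinement keeps its last valid state; empty/full inputs are rejected.
The literal "repeat until u ≠ u′" convergence phrasing is read as "repeat
while the mask changes".

On the default synthetic conditions (10 seeds) the refined masks reach a
median Dice around 0.9 and refinement does not degrade the SOM seed. The
darkest-cluster rule can occasionally latch onto a spurious dark patch
when the 4-unit codebook splits the lesion across two clusters; the
pipeline falls back to the full frame as ROI when segmentation
degenerates, and the failure rate on the default conditions is about 1 in
100 images.

The ROI is the mask's tight bounding box, padded to square by edge
replication and resized bilinearly to the CNN input side (150 px full
scale, 64 px reduced).

## CNN feature extractor

Architecture: conv(64 @ 7×7) → ReLU → maxpool 2×2/2 → conv(64 @ 5×5) →
ReLU → maxpool → FC 500 → ReLU → FC 250 → ReLU → FC 100 (linear). The
100-d linear embedding is the feature vector; a softmax 2-class head is
attached only during training (the embedding itself has no natural
training signal, and the head's cross-entropy is the obvious surrogate)
and removed afterwards. Convolutions are "same"-padded with odd kernels;
no framework is used — forward/backward passes are im2col + matmul in
float32 with Adam (lr 10⁻³, β = 0.9/0.999).

The **reduced profile** (64×64 input, 16 filters per conv, FC 256/128/100,
25 epochs, weight decay 10⁻³ on weight matrices) is the default for the
pipeline and tests; it trains on 100 images in well under a minute on one
CPU. Weight decay is needed at this scale because ~70 training images are
easily memorized; the full-scale profile (150×150, 64 filters, no decay)
matches the architecture above and is intended for real datasets. Filter
counts above 64 are rejected by the config (documented overfitting
boundary of the architecture).

## Optimizer (GWO / IGWO)

The genome is fixed-length: gene 0 is the hidden-layer size, decoded by
round-half-up and clipped to [5, 30]; the remaining
`H_max(X+1) + C(H_max+1)` genes hold weights in [−2, 2], of which the
leading `H(X+1) + C(H+1)` are active (hidden weights row-major, hidden
biases, output weights, output biases). Fixed dimensionality keeps the
arithmetic of the pack moves well-defined; inactive genes are inert.

Moves use the canonical three-leader form: for each leader L,
`D = |2 r₂ L − P|`, `X_l = L − (2 a r₁ − a) D` with fresh uniform vectors
r₁, r₂ per leader, and the new position is the mean of the three X_l,
clamped to the bounds. Leaders α, β, δ are the current population's best
three (stable sort); `a` decays linearly 2 → 0 over the iteration budget.
Termination: budget T reached, best fitness exactly 0, or m iterations
without strict improvement of the best-so-far (the counter resets on any
improvement). Full-scale defaults: population 250, T = 300, m = 100;
reduced runs use 30/60/30.

The archive S (capacity 50, worst-fitness eviction, duplicate tolerance
10⁻⁹ Euclidean) receives each iteration's top three solutions when they
are new and better than S's mean fitness; probabilities
`z_i = (1 − Fit_i)/Σ(1 − Fit_j)` drive per-wolf roulette selection of
three members that replace α/β/δ for the second half of the population
(indices ≥ ⌈n/2⌉, fixed). With an empty archive those wolves fall back to
the leaders, which makes a zero-capacity archive reproduce plain GWO
bitwise under a shared seed — a tested equivalence, alongside a
trajectory-exact comparison against an independently coded textbook GWO.

**Known limitation.** At reduced scale (population 30, 60 iterations) on
the hard synthetic feature task, the archive mechanism does not improve —
and typically worsens — the median final training fitness relative to
plain GWO. The mechanism is exploration-oriented: archive members are
frozen historical elites, and in MLP weight space the mean of distinct
good solutions is usually a poor solution, so diverting half the pack away
from the current leaders mostly removes exploitation capacity. The effect
shrinks to parity in our experiments when the budget grows (population 50,
200 iterations), which is the regime the full-scale defaults target.
Several alternative readings of the archive move (sequential single-leader
updates, shared per-iteration selection, leaders extended by archive
picks, α-only insertion, capacities 3–50) were evaluated and none
outperformed plain GWO at the reduced budget; the documented variant
follows the archive design as specified.

## Classifier

`forward` computes softmax(W_o tanh(W_h x + b_h) + b_o); prediction is the
argmax with exact ties resolved to the non-melanoma class (deterministic
and conservative). The softmax output layer is a package choice — only the
hidden activation (tansig) is fixed by the design — and gives ROC curves a
natural score. Fitness is the raw training misclassification rate F/N;
there is no internal validation split, so overfitting is bounded only by
H ≤ 30 and the weight box, as in the original design. The pipeline
z-scores features with training-set statistics before classification:
the hidden layer's inputs are box-bounded weighted sums of 100 features,
so unscaled CNN activations would saturate every tanh unit.

At reduced scale the zero-fitness termination rule interacts with small
training sets: ~70 samples in 100 dimensions are often perfectly separable,
so the optimizer stops at the first genome with zero training error rather
than refining further. This is faithful to the termination rules and is
one reason held-out accuracy varies by a few samples across seeds.

## Metrics

All ratios are computed in exact rational arithmetic and converted to
float at the end; percentages are reported to 4 decimals. Precision,
recall and F-measure are exposed both per-class (melanoma) and
macro-averaged (unweighted two-class mean, the convention of the reference
result tables — verified numerically: the published table values match the
macro forms, not the melanoma-only forms). MCC uses the standard
four-marginal symmetric formula. The ROC sweeps thresholds over the unique
scores (predict positive at score ≥ t) with (0,0)/(1,1) endpoints and
trapezoid AUC; it agrees with the pairwise-concordance definition to
1e-9 in tests. Undefined metrics (zero denominators) raise a dedicated
error naming the metric; the pipeline reports them as null rather than
failing a whole run.

## Pipeline and reproducibility

One global seed is expanded via `SeedSequence` into independent child
seeds for simulation, splitting, segmentation, CNN and optimizer, so any
stage can be rerun in isolation while the end-to-end confusion matrix is
bit-reproducible. Stage artifacts are plain files (PNG masks, CSV
features, JSON model/report). The default study conditions used by the
acceptance checks: 100 simulated images (50% melanoma), stratified 70/30
split, reduced CNN profile, optimizer 30/60/30. On these conditions the
held-out accuracy at the pinned default seed is 0.90; across seeds it
ranges roughly 0.77–0.97, dominated by the 30-sample test split and the
zero-fitness termination noted above.
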