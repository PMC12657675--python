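# Methods

`adgrade` implements a four-stage severity-grading pipeline for ordered,
heavily imbalanced grayscale image classes: (1) synthetic data generation
and preprocessing, (2) GAN-based minority-class balancing with structural
quality logging, (3) evolutionary search over CNN hyperparameters with
class-weighted fitness, and (4) class-weighted CNN training, evaluation and
Shapley-value attribution. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Synthetic phantoms

Each phantom is a single-channel image in [0, 1]: an elliptical "brain"
(semi-axes 0.42 and 0.36 of the image side) on a dark background, a bright
outer "cortex" band, and a central dark "ventricle" disk. The four ordered
severity classes — ND, VMD, MD, MOD — are encoded purely geometrically:

| severity | ventricle radius (fraction of brain radius) | cortex thickness |
|---|---|---|
| 0 (ND)  | 0.10 | 0.18 |
| 1 (VMD) | 0.16 | 0.15 |
| 2 (MD)  | 0.24 | 0.11 |
| 3 (MOD) | 0.34 | 0.07 |

The radius table increases and the thickness table decreases strictly with
severity, emulating ventricular enlargement and cortical thinning. A
per-image uniform jitter of ±2% on all geometric parameters and additive
Gaussian noise (sd 0.03 on the [0, 1] scale) turn each class into a
distribution. The geometric defaults were chosen once so that (a) a
depth-2 decision rule on two hand-computed features (dark-disk area,
bright-band width) separates the classes at ≥95% accuracy — the pipeline
has real signal to find — and (b) adjacent classes still overlap enough at
32×32 that a trivial classifier does not saturate after one epoch.

Per-image random streams derive from `SeedSequence(master, class, index)`,
so enlarging one class never reshuffles another, and any subset is
reproducible in isolation.

What the phantoms deliberately do not emulate: anatomical texture,
acquisition physics (bias fields, motion), inter-subject variability
beyond geometric jitter, or 3-D structure. Passing tests therefore
demonstrate that each algorithmic stage behaves correctly on
class-structured grayscale images, not that the pipeline reaches any
particular accuracy on clinical MRI.

## Preprocessing

Grayscaling uses ITU-R BT.601 luminance weights (0.299, 0.587, 0.114);
min–max normalization maps to [0, 1] with the declared convention that a
constant image maps to all zeros. Augmentation applies an affine family in
the fixed order rotation → shift → shear → zoom → horizontal flip, each
parameter drawn uniformly from a signed range (defaults ±30° and ±30% for
the geometric factors, Bernoulli-½ flip). The order and the
nearest-edge fill rule for out-of-frame pixels are fixed for determinism;
bilinear interpolation keeps outputs inside the input's intensity range. An
optional additive brightness jitter (±10% when enabled) is off by default.
Augmentation is train-time only; the test set is never augmented.

The stratified split gives the training side floor(train_fraction · N_c)
of each class (default 0.8), membership chosen by a seeded in-class
shuffle. With the reference class sizes (3200, 2240, 896, 64 + 700
synthetic) this floor rule reproduces the 5679/1421 accounting exactly,
including the 716.8 → 716 case. A three-way 70/15/15 split is available by
composing two splits; the two-way 80/20 dialect is the default because the
dataset-accounting checks are defined over it. Balancing runs before the
split, so synthetic images appear in both sides (MOD 764 → 611/153); the
GAN itself only ever sees real minority images.

## GAN balancing

The generator maps a 100-d latent vector through a dense projection to a
(size/4, size/4, 128) feature map, two stride-2 transposed-convolution
blocks (128 → 64 → 64 filters, 4×4 kernels, batch normalization,
leaky-ReLU 0.2) and a final 3×3 convolution with tanh output, so samples
live in [−1, 1]. The discriminator is two stride-2 3×3 convolutions
(32, 64 filters, leaky-ReLU) and a dense head producing one raw score. The
least-squares objective acts on raw scores:

    d_loss = ½·E[(D(x) − 1)²] + ½·E[D(G(z))²],   g_loss = ½·E[(D(G(z)) − 1)²].

Both networks train with Adam (β₁ = 0.5) at a configurable rate (default
2·10⁻⁴, batch 32). Real images must arrive in the [−1, 1] convention; the
caller rescales with x → 2x − 1 and `balance_class` rescales samples back
to the dataset convention, appending them with provenance `"synthetic"` so
conservation of real images stays checkable. Batch normalization in the
generator is our addition beyond the minimal block list: without it the
generator does not converge within desk-scale step budgets.

Quality control is logged, not gated: the mean SSIM of each synthetic
image against its nearest real class image (headline number) and against
the real class mean, plus the histogram-overlap coefficient
Σ min(p_bin, q_bin) of the real and synthetic pixel pools on [−1, 1]. SSIM
uses the standard Gaussian 11×11 window (σ 1.5), K₁ = 0.01, K₂ = 0.03. An
optional `min_ssim` resampling gate exists but is off by default, because
no principled threshold is available. For calibration: at 16×16 the mean
nearest-real SSIM *among real phantoms themselves* is ≈ 0.89, and a
desk-scale training run (64 images, 150 epochs, rate 10⁻³) reaches ≈ 0.80.

## Evolutionary hyperparameter search

A genome is the tuple (learning rate, conv-layer count, per-layer filter
list, dropout). Default domains: lr ∈ {10⁻⁵, 5·10⁻⁵, …, 10⁻²} (1–5
ladder), layers ∈ {2, 3, 4, 5}, filters ∈ {16, 32, 64, 128, 256},
dropout ∈ [0.1, 0.6]. All operators are closed over the domains.

- **Fitness**: validation accuracy of the candidate CNN trained briefly
  with class-weighted loss; or the multi-objective blend
  0.7·accuracy + 0.3·(1 − normalized parameter count), where the count is
  min–max normalized over the exact extremes achievable inside the domain
  (computed by enumeration and cached).
- **Selection**: roulette wheel, p_i = f_i / Σf (uniform when Σf = 0); one
  uniform draw against the cumulative distribution per parent, parents
  drawn with replacement, self-mating allowed.
- **Crossover**: each scalar gene from either parent with probability ½;
  filter j from the chooser parent, reusing that parent's last filter when
  it is shorter than the child's layer count. Applied per mating with
  probability `crossover_rate` (default 0.7), otherwise the fitter parent
  is cloned.
- **Mutation**: each gene independently resampled from its domain with
  probability `p_mut`; a mutated layer count regenerates the whole filter
  list at the new length.
- **Elitism**: the single best individual is copied unchanged, making the
  best-so-far fitness non-decreasing — asserted per generation.

Class weights follow w_c = N_total/(N_c·K) and satisfy Σ w_c·N_c = N_total
identically; N_total is always computed from the data at hand.

`p_mut` defaults to 0.5. For the known-optimum recovery experiment (can
the GA re-find a hidden target genome from similarity feedback alone with
N = 20, T = 15?) we run on the desk-scale search domain (layers {2, 3},
filters {8, 16, 32}, full lr ladder) at the lighter mutation rate 0.2:
with ~300 evaluations, 50% per-gene disruption destroys assembled
solutions faster than roulette selection can rebuild them, while 0.2
recovers the target in ≈ 98% of runs (197/200 measured). The surrogate
similarity counts four gene slots — exact lr match, exact layer match,
positionwise filter match fraction, and dropout within ±0.05 of the
target — averaged equally; the dropout window makes the optimum reachable
(a continuous gene can never be matched exactly by resampling). The same
desk-scale domain backs the GA-over-real-CNN pipeline runs, keeping every
candidate architecture proportionate to 32×32 phantoms.

## CNN classifier

A genome expands to n_layers blocks of (3×3 conv, leaky-ReLU 0.2, 2×2 max
pool), then flatten, dropout at the genome's rate, and a dense softmax
head. Kernel size is a builder setting, not a gene; a mixed (3×3, 5×5)
preset is available. The exact parameter count (per conv layer
k²·C_in·C_out + C_out; dense F·n_classes + n_classes) feeds the GA's
multi-objective term and is cross-checked in tests against an independent
shape-walking recount and against the materialized network.

Training minimizes class-weighted categorical cross-entropy (sample weight
= w_label; the sparse integer-label formulation, mathematically identical
to one-hot) with Adam at the genome's rate, batch 32. Early stopping
watches validation loss with patience k: training stops after k epochs
without improvement (k = 0 behaves as k = 1, i.e. stops at the first
stagnant epoch). The validation set for early stopping and GA fitness is a
stratified 15% carve-out of the training split.

Evaluation reports the confusion matrix (rows = true), per-class
precision/recall/F1/support (0 where undefined), accuracy, macro and
support-weighted aggregates, and one-vs-rest ROC-AUC per class from the
softmax scores. Printed 2-dp values use round-half-up (0.955 → 0.96), the
convention of printed metric tables.

## Shapley attribution

For a coalitional game with M players and value function f, the attribution
of player i is

    φ_i = Σ_{S ⊆ N∖{i}} |S|!·(M−|S|−1)!/M! · (f(S ∪ {i}) − f(S)).

`exact_shapley` enumerates all subsets (M ≤ 20); `sampled_shapley`
averages marginal contributions over seeded random orderings, reporting
per-feature standard errors. Because each ordering's marginals telescope,
efficiency (Σφ = f(full) − f(∅)) holds to machine precision at any sample
size; the four axioms (efficiency, symmetry, null player, linearity) are
verified against the exact oracle on random games. We chose the
model-agnostic permutation estimator over a network-specific explainer
because it satisfies the defining equation in expectation and is directly
testable against enumeration.

For images, pixels are grouped into g×g superpixel tiles (default 8; a
pixel-level game at 128² would have M = 16 384 players). The game value
f(S) is the model's target-class probability with out-of-coalition tiles
replaced by background pixels, averaged over `background_draws` (default
10) images drawn from a background set (desk default 100 training images).
Group values are broadcast to pixels (φ_g/|group|), giving a map whose sum
plus the base value f(∅) reproduces the model's score. `roi_fraction`
reports Σ_mask |φ| / Σ |φ|; the phantom ventricle and cortex masks stand
in for anatomical ROI masks (hippocampus, amygdala) on real scans.
`summary_ranking` orders groups by mean |φ| across maps, retaining
per-map signed values for summary plots.

## Pipeline and reproducibility

`run_pipeline` executes generate → balance → split → optimize → train →
explain under one master seed; each stage's seed is derived as
`SeedSequence(master, crc32(stage_name)) mod 2³¹`, so stages re-run
independently yet reproducibly. The run report carries per-stage counts,
the GA history, the evaluation report, GAN quality statistics, ROI
fractions, the seed and a SHA-256 config hash; re-running the same config
and seed yields an identical report. Stage prefixes are allowed (e.g.
accounting-only runs stop after the split).

The numeric core is a compact numpy layer library (`adgrade._nn`) with
manual backpropagation: dense, conv, transposed conv, batch norm, max
pool, dropout, leaky-ReLU/tanh, Adam, and weighted softmax cross-entropy.
Convolutions run as im2col + BLAS matmuls in both directions (the input
gradient of a strided conv and the forward pass of a transposed conv are
stride-1 correlations of zero-dilated counterparts with rotated kernels);
working precision is float32; ties in max-pool break toward the first
maximum; every weight initialization draws from a caller-supplied
generator, making whole training runs bit-reproducible. Gradients were
verified against central finite differences for every layer type.

## Problem sizes used by tests and the acceptance script

Chosen as the package's desk-scale defaults: dataset accounting runs the
real stages at 16×16 (counts are size-independent); GAN quality runs 64
minority images at 16×16 for 150 epochs at rate 10⁻³; the
GA-over-real-CNN pipeline run uses 4×200 phantoms at 32×32, 3 epochs per
candidate, N = 8, T = 3, then 12 final epochs; Shapley checks use M = 5–6
games with 10⁴ permutations. On these conditions the phantom test accuracy
is a property check (≥ 90%), not a claim about clinical data.

## Known limitations

- Phantom realism is intentionally minimal (see above); transfer of any
  measured accuracy to real MRI is out of scope.
- The GAN logs quality but does not enforce it; mode collapse at very
  small step budgets is possible and visible in the SSIM log.
- The full-scale configuration (128×128 images, 5000-image Shapley
  background) is config-reachable but not exercised by the test suite.
- The permutation estimator's variance grows with group count; for g ≫ 16
  tiles per side, increase `n_permutations`.
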