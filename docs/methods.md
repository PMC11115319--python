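# Methods

## Model

An encoding model predicts a neuron's spike count for an image in three
stages.

**Frozen core.** A fixed function maps the image to a stack of feature maps
`l(x) ∈ R^{w×h×c}`.  The core's parameters never change during fitting; the
package ships two desk-scale cores — a Gabor filter bank (orientations ×
spatial frequencies × phases, zero-mean kernels) and a small seeded random
convnet (conv + rectify stages) standing in for an untrained baseline — and
an adapter for any external feature extractor (e.g. a wrapper around a
pretrained network; no pretrained weights are bundled).

**Feature head.**  Per-channel batch normalization with trainable scale γ and
shift β, followed by rectification:

    Φ(x) = max(γ·(l(x) − μ)/σ + β, 0)

Train mode normalizes with batch statistics and updates running statistics
by exponential blending (momentum 0.1, configurable); evaluation freezes the
running statistics, making the head a pure function.  Normalizing every
channel to zero mean / unit variance before rectification is what lets a
single L1 penalty act evenly on all readout weights.

**Gaussian point readout.**  Per neuron n: a 2D position mean μ_n in relative
coordinates ([−1, 1]² with (0, 0) at the map center), an isotropic sampling
variance σ_n², a weight vector w_n ∈ R^c and a bias b_n — c + 4 parameters.
The predicted rate is

    r̂_n(x) = ELU(Φ_{p_n}(x)·w_n + b_n) + 1,

with Φ_{p}(x) the feature vector bilinearly interpolated at location p over
its 2×2 grid neighborhood.  During training p_n is a reparameterized draw
from N(μ_n, σ_n² I), clamped to the map (clamped coordinates receive zero
gradient); at evaluation p_n = μ_n exactly.  σ_n² is kept positive through a
softplus parameterization and shrinks by gradient descent as the position
estimate sharpens.  The single-point restriction is deliberate: all spatial
nonlinear integration must come from the core, so model comparisons speak
about the core's features and not about the readout's extra capacity.

## Objective and training

All readouts and the head are fitted jointly by minimizing the summed
Poisson loss plus an L1 penalty on the readout weights (bias excluded):

    L = Σ_{i,n} (r̂_n(x_i) − r_n(x_i)·log r̂_n(x_i)) + λ Σ_{n,k} |w_{nk}|

The log argument is guarded with ε = 1e−8 against underflow of ELU + 1.
Sessions contribute different images and disjoint neuron sets; each training
step cycles through all sessions, draws one without-replacement batch per
session (default 64), sums the gradients across the cycle and applies one
Adam update.  An epoch ends when the longest session's pool is exhausted;
shorter sessions restart from their full pool.  When a session's remaining
pool is smaller than the batch size, the remainder is used as a (smaller)
final batch before the pool refills — the choice is immaterial at the batch
sizes used and keeps every sample visited exactly once per pass.

The schedule: Adam at learning rate 3e−4 (first-moment coefficient 0.1,
configurable), validation Poisson loss (single-trial, L1 excluded — model
selection should reflect predictive fit) evaluated each epoch with frozen
normalization statistics; when validation fails to improve for 5 consecutive
epochs the best weights are restored and the learning rate is multiplied by
0.3; fitting stops after 4 such events and returns the best weights.

Because the core is frozen, gradients never traverse a convolution; the
backward pass is written analytically in NumPy.  The loss reaches the
feature tensor only through each neuron's four interpolation corner pixels,
so the γ/β gradients are sparse gather-reductions; position gradients use
the closed-form derivative of bilinear interpolation; σ_n² gradients come
from the reparameterized draw.  Analytic gradients are verified against
central finite differences (relative tolerance 1e−4) in the test suite.

### Desk-scale optimization choices

Two initialization choices differ from a naive translation of the
large-data regime, and both were forced by measurement:

- **Position initialization.**  Starting all μ_n at the map center leaves
  any neuron whose true position lies more than ~0.3 relative units away
  with no usable gradient: the expected position gradient under the sampling
  distribution decays with the feature maps' spatial correlation length, and
  wide sampling merely flattens the landscape.  Positions are therefore
  initialized at the peak of each neuron's correlation receptive-field map —
  the grid location maximizing Σ_c corr²(count, Φ_c) over the train set — a
  cheap, standard receptive-field estimate.  `TrainSchedule.position_init =
  "none"` disables this (used when warm-starting joint readouts, whose
  positions come from fitted single models).
- **Initial sampling width.**  σ_n is initialized at 0.1 (5% of the map
  width): wide enough for gradient flow around the initialized position,
  narrow enough that training samples stay within the feature maps' spatial
  correlation length.  With correlation-map initialization plus σ = 0.1,
  matched-core fits recover positions to ~0.01–0.02 relative units; with
  center initialization plus σ = 0.5, fits land in a local optimum with
  position errors ~0.7 and near-zero weight recovery.
- **Learning rate at desk scale.**  The default 3e−4 suits regimes with
  thousands of updates per fit.  The recovery scenarios use 3e−3 because
  their epochs contain ~30× fewer updates; the parameter travel budget
  (learning rate × steps) must be preserved, not the learning rate itself.
- One position is drawn per neuron **and per batch element**; averaging B
  independent reparameterized samples per step keeps the position-gradient
  variance manageable.

## Reliability and performance estimators

With repeated test presentations (r_{tj} = count on trial t of image j):

- noise variance  σ²_noise = E_j[Var_t(r_{tj})]  (unbiased within-image
  variance, averaged over images);
- explainable variance  Var_exp = Var[r] − σ²_noise, with Var[r] the
  unbiased variance over all single trials;
- EV = Var_exp / Var[r]; neurons with EV *strictly below* 0.15 are excluded
  from model evaluation (a neuron exactly at threshold is retained);
- FEVE = 1 − Var_res/Var_exp, where Var_res averages squared single-trial
  residuals over repeats and images before subtracting σ²_noise.  The
  residual is computed on single trials grouped by image; when repeats are
  collapsed this reduces to the per-image form.  FEVE is undefined
  (reported as NaN, never silently dropped) when Var_exp ≤ 0.
- test correlation: Pearson r between predictions and across-repeat mean
  responses, averaged over neurons.

Sparseness uses the selectivity index SI = 1 − 2A: the fraction of images
whose mean response strictly exceeds each of 100 evenly spaced thresholds
between the minimum and maximum response is averaged over thresholds
(rectangle rule) to give A.  A dense uniform response grid gives A → 0.5
(SI → 0); a single responsive image gives SI → 1.  SI is invariant to
positive affine rescaling of the responses because thresholds are anchored
to the response range.

## Joint multi-core readouts

Two (or three) frozen cores receive the identical input; their head outputs
are concatenated along channels and one point readout per neuron (a single
shared position) acts on the concatenation, so a single-core model is
exactly the pair model with the other block zeroed.  Five training
strategies: scratch; initialize block 1 (2) from its fitted single model
with the other block zeroed and tune only the other block's weights; same
initializations tuning all weights.  When one block is tuned, the frozen
block's weight columns and head scale/shift are masked out of the Adam
update and verified bit-identical after fitting.  Warm starts copy the
initialized block's readout position; positions remain trainable whenever
any readout weights are trainable.  λ for joint models is re-validated over
the same grid used for singles.  Triplets warm-start two blocks from a
fitted pair and tune everything.

## Experiment statistics

- Model selection maximizes validation score over scale × layer × λ with
  seeds averaged; ties break toward the smaller λ, then the earlier layer.
  Default λ grids per layer: conv1 {0.33, 1, 3}, layer1.0 {3},
  layer2.0 {3, 6}, layer3.0 {3, 9}, layer4.0 {6, 12}.
- Cluster contrasts: pairwise Wilcoxon signed-rank tests on per-neuron
  score differences (paired design), Holm–Bonferroni corrected over the
  pairs.
- Specialization: the variance across task models of normalized
  performance, by default the increment over the untrained baseline divided
  by its mean (the baseline itself excluded); the plain mean-normalized
  variant is available by flag.  Between-area variance equality is reported
  with *both* Bartlett's test (optionally after Fisher z-transforming
  correlation scores) and Levene's test — the two tests answer the same
  question with different robustness; neither is privileged.

## Synthetic data

Images are 1/f-filtered Gaussian noise plus randomly oriented Gabor
patches, affinely mapped to [0, 255] and quantized to 8 bits — broadband
statistics that drive both the Gabor-bank and convnet cores.  Ground-truth
neurons are point readouts over a core's feature maps passed through a
fixed per-channel standardization (estimated once from the image pool) and
rectification: rate = gain · (ELU(w·Φ(p) + b) + 1), with positions uniform
in [−1, 1]², sparse zero-mean Gaussian weights normalized to a common
Euclidean norm (default 2.0), and gain (default 2.0) chosen so median
counts land in the 0–10 per-presentation regime; the resulting EV
distribution (median ~0.3–0.4 at 45 repeats) matches cortical test-set
reliability.  Counts are independent Poisson draws per repeat.  Each
simulated session receives its own neurons and its own unique
train/validation images (default 80/20 split); all sessions share one test
set of 75 images repeated 45 times (midpoint of the 40–50 range used for
repeated test presentations).

What the generator does *not* emulate: natural-scene semantics or category
structure, trial-history and adaptation effects, correlated (non-Poisson)
noise, and eye-movement jitter.  Passing recovery tests therefore show that
the estimation machinery is correct under the model's own assumptions, not
that the model family suffices for real cortical data.

## Reproducing the analytic limits

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch, the area under the 100-threshold
fraction-above-threshold curve for a dense uniform response grid (100,000
values) and the corresponding selectivity index.  The expected limits are
A = 0.5 and SI = 0 up to O(1/n) discretization.

## Problem sizes

The test suite and recovery scenarios run on one CPU: 64×64 images, Gabor
banks of 2–16 channels on 8×8–16×16 maps, sessions of 120–1,000 images,
8–40 neurons.  The flagship recovery scenario (`matched_gabor`) fits 40
neurons across two sessions of 1,000 images each (1,600 train / 400
validation after the split) and completes in about a minute.

## Known limitations

- No GPU path, no mixed precision; everything is float64 NumPy.
- The external-core adapter is an interface only; reproducing results that
  depend on specific pretrained networks requires supplying those features.
- The correlation-map position initialization assumes the train set is
  informative about position (true for stimulus-driven simulations; a
  pathological zero-signal dataset falls back to an arbitrary argmax, which
  is harmless because such neurons are removed by the EV filter).
- Bilinear interpolation and clamped sampling make the position likelihood
  piecewise smooth; positions exactly on the map edge have one-sided
  gradients.
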