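# Methods

This note documents the models and procedures implemented in `dtocrop`, the
defaults chosen where the method family leaves them open, and what the
synthetic benchmarks do and do not demonstrate.

## Problem setting

Crop classification from remote-sensing imagery, posed as supervised patch
classification: the input is a set of small multi-band image tiles with one
crop label each; the output is a per-class and macro-averaged evaluation
report.  The pipeline has four stages — stratified split, extractor tuning,
classifier tuning, final fit and evaluation — and every tunable choice is
made by minimizing held-out classifier error, never by hand.

## Synthetic data generator

Each class is described by a per-band mean intensity *signature* in [0, 1].
A patch of class *k* is

    signature_k  +  texture_scale_k · smooth(white noise)  +  N(0, noise_sd²)

clipped to [0, 1], where `smooth` is an isotropic Gaussian filter (σ = 2 px)
applied per band, giving spatially correlated within-patch texture.  This is
deliberately the simplest statistical model under which extractor
hyperparameters matter at all; it emulates the *class-count structure* and
*spectral separability* of a real drone collection, not its optics.  The
shipped emulation profile uses six classes with counts
2,075 / 1,661 / 1,270 / 750 / 363 / 331 (total 6,450) scaled by a user
factor (default 1/10) so test runs stay fast.  Patch geometry defaults to 3
bands at 32×32 px — declared, not inferred, since the emulated collection's
geometry is unpublished.

What passing tests on this generator show: the pipeline's plumbing,
optimizers, decoders and metrics behave correctly, and tuning recovers
informative configurations when an informative one exists.  What they do
not show: performance on real imagery, robustness to registration errors,
illumination variation, within-class spectral diversity or label noise —
none of which the generator models.

A feature-space counterpart (`generate_feature_table`) draws class-
conditional Gaussian clusters whose centroids sit at `class_sep` times a
seeded random unit direction; it exists for classifier-level tests.

All randomness flows through one explicit seeded `numpy.random.Generator`;
identical parameters and seed give bit-identical datasets.

## Feature extraction: the random convolutional bank

The default extractor is a small stack (1–3 stages) of *fixed random*
convolutions: filters are drawn once from N(0, 1/fan_in) given a seed and
never trained.  Each stage is valid-mode convolution, optional ReLU, and
max-pooling; the final maps are collapsed by global mean and standard
deviation per filter, so the feature dimension is `2 · n_filters` regardless
of depth.  Random convolutional features are a well-understood baseline for
small-image classification and make the extractor a pure function of
(patches, architecture, seed) — which is exactly what a hyperparameter
search over architectures requires.  External extractors (e.g. a pretrained
deep network) attach through a name registry with a row-count contract
check.

The stage-1 search space is 6-dimensional: filter count [2, 64], kernel
size {3, 5, 7}, pool size {2, 4}, pool stride {1..4}, depth [1, 3],
ReLU on/off.  Continuous positions decode by clipping into the box and
flooring onto each grid; decoding is total (any in-range real vector is
legal) and piecewise constant, so optimizer candidates that differ below
the grid granularity share one fitness evaluation (memoized).
Architectures whose maps shrink below the kernel are infeasible; inside the
tuning loop they receive the worst possible fitness (100 % error) so the
swarm routes around them, while direct use raises a configuration error
naming the offending stage.  The pipeline's default box caps filters at 16
(`compact_search_space`) to keep desk-scale runs fast; the full box is
available as `default_search_space`.

## The three optimizers

All are bounded minimizers over a box, elitist (the recorded global best is
never overwritten by a worse value, making best-fitness histories
non-increasing), with clipping after every move, uniform initialization,
zero initial velocities, and exactly `m·(T+1)` objective evaluations (plus
retries for non-finite values: one re-evaluation, then a logged reset to a
random in-bounds position, then a +inf penalty).

**DTO.**  Per individual and iteration, draw r1, r2, r3 ~ U(0,1) and
K1, K2, K3 ~ U(0, 2), then

    X  = P_best − K1·|K2·P_best − P|
    V' = K3·V + K4·r1·(P_best − P) + K5·r2·(P_Gbest − P)
    Y  = P + V'

taking X when r3 < 0.5 and Y otherwise.  K4 = 1.7 and K5 = 1.8 are the
method's stated constants.  Sampling K1–K3 i.i.d. uniform per step is the
simplest reading of "dynamically nominated in [0, 2]".

**SCA.**  Per coordinate, r2 ~ U(0, 2π), r3 ~ U(0, 2), r4 ~ U(0, 1), and

    X' = X + r1·sin(r2)·|r3·P_Gbest − X|    (r4 < 0.5; cos otherwise)

with amplitude r1 = a·(1 − t/T), a = 2 — the standard linear decay from the
SCA literature, adopted because the hybrid's source leaves the schedule
unstated; it is config-overridable.

**MSCA.**  Each solution draws φ ~ U(0,1) per iteration.  When at least
`activation_fraction` (default 1/3) of the budget has elapsed *and*
φ > 0.5, the solution takes the firefly move toward the global best,

    x' = x + β0·exp(−γ·r²)·(x_gbest − x) + αᵗ·(κ − 0.5),

with r the Euclidean distance, κ a standard-Gaussian draw per coordinate
and αᵗ = α0·decayᵗ (defaults β0 = 1, γ = 1, α0 = 0.2, decay = 0.97);
otherwise it takes the SCA move.  Moving toward the global best is the
cheapest faithful partner choice; full sequential pairwise attraction is
available via `fa_partner="pairwise"`.  The seed is split into independent
init / move / firefly streams, so an MSCA run in which the firefly branch
never fires is bit-identical to pure SCA with the same seed — a property
the tests assert directly.

On the 5-D sphere benchmark (m = 20, T = 100) all three reach median best
fitness well below 1e-2 over 10 seeds.  The firefly jitter can leave MSCA
slightly behind pure SCA on such a unimodal surface; since no quantitative
improvement bound is claimed for the hybrid, the MSCA-vs-SCA comparison is
a warn-only check.

## Extreme learning machine

A single-hidden-layer network whose hidden layer is random and fixed:
w, b ~ U(−1, 1) seeded, H[j,i] = g(⟨w_i, x_j⟩ + b_i) with g ∈ {sigmoid,
relu, tanh}, targets one-hot in {0, 1}, and output weights

    β = H⁺Y                      (ridge λ = 0)
    β = (HᵀH + λI)⁻¹ HᵀY         (λ > 0)

The pseudoinverse route uses the minimum-norm least-squares solve with
singular values below `max(N, L)·eps·σ_max` treated as zero.  Prediction is
the argmax of Hβ, ties to the lowest class index.  U(−1, 1) hidden weights
and the ridge extension are standard ELM practice; λ defaults to 0.  Note
that argmax decoding is scale-invariant, so large λ shrinks ‖β‖ without
necessarily degrading accuracy on separable data — the ridge limit
manifests as weight collapse, not automatically as chance-level prediction.
`n_hidden > N` is permitted with an underdetermined-system warning.

## Two-stage tuning protocol

The outer split is stratified with largest-remainder rounding (an 80:20
split of the 6,450-count profile puts exactly 1,290 samples on the test
side) and deterministic under its seed.  Both tuning stages carve an inner
validation set (default 20 %) out of the training side, because the fitness
— classifier error rate, `(misclassified/total)·100` — must be held-out:
with L = N an ELM interpolates and training error is uninformative.  The
test side is never touched before the final evaluation; a corruption test
asserts this.

Stage 1 (DTO) scores each decoded architecture by the inner-validation
error of a quick ELM (50 sigmoid nodes, λ = 1e-3).  Stage 2 (MSCA) searches
(hidden size on an integer grid [10, 200], ridge on a log10 scale
[1e-6, 1e2], activation by index) on the stage-1 winner's features.  The
final ELM is refit on the full training side with the stage-2 settings.

## Evaluation

Per-class metrics are one-vs-rest on the confusion matrix; per-class
"accuracy" is (TP+TN)/N, which is the only reading consistent with
per-class accuracies near 98 % in a six-class problem.  Averages are
unweighted macro means (micro available separately); display rounding is
half-up to two decimals with raw values retained.  Zero-denominator ratios
are reported as 0 with a flag rather than raised, so degenerate candidates
inside the optimizer receive finite fitness.

## Numerical and design choices

- Equation-level tie-breaks: branch conditions use strict `< 0.5`; argmax
  ties go to the lowest index; largest-remainder ties go to the lower class
  index.
- `T = 0` is allowed at the `optimize` level (returns the best of the
  initial population); the SCA step itself requires T > 0 since its
  amplitude divides by T.
- φ-threshold 0 and 1 are legal boundary settings (always / never firefly,
  once active).
- Problem sizes in tests and the acceptance script — the 60-patch-per-class
  smoke profile with m = 6, T = 8 for both stages, the m = 20, T = 100
  sphere runs, 20×5 ELM interpolation instances — are the package's chosen
  desk-scale study conditions.
- Reports list classes in generator order (the emulation profile uses the
  reference six-class order); re-labeling classes permutes predictions
  consistently.

## Known limitations

- The synthetic generator's Gaussian signature model makes spectral means
  nearly sufficient statistics, so most feasible extractor architectures
  separate the smoke profile; architecture tuning shows its value mainly in
  the planted-candidate benchmark, where exactly one of four extractors
  carries signal.
- The random conv bank is a stand-in extractor by design; with a pretrained
  network registered, stage 1 would tune whatever knobs its wrapper
  exposes.
- No constraint handling beyond box clipping; no parallel objective
  evaluation; no online/kernel ELM variants; no georeferencing or sensor
  physics.
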