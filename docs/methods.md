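# Methods

This note documents the models, algorithms and numerical choices behind
`gliorl`: what is computed, under which assumptions, with which defaults,
and what the synthetic benchmarks do and do not demonstrate.

## Data model

The pipeline's universal currency is the `SampleTable`: one row per sample
(an original patient scan or an augmented copy), an ordered feature
namespace shared by all rows, and reserved metadata columns `sample_id`,
`group_id`, `modality`, `label`, `survival_days`, `age`. The `group_id`
is the origin patient and is the unit of leakage control: augmented copies
inherit it, and every split operation is group-atomic, so no patient's
augmented versions can straddle a train/test boundary.

The packaged feature manifest describes a standard 105-feature whole-tumour
radiomics extraction in seven categories (14 shape, 18 first-order, 24
GLCM, 13 GLDM, 16 GLRLM, 15 GLSZM, 5 NGTDM). Feature names follow
pyradiomics conventions with category prefixes to keep the namespace
globally unique. The manifest is descriptive only — no image processing
happens in this package.

**Survival binning.** Overall-survival days map to classes with inclusive
upper bounds: class 0 for days ≤ 250, class 1 for 251–500, class 2 for
501–1800; days above the last edge are a range error, not silently
clamped. The phrasing of the band definitions ("0–250", "251–500") forces
the inclusive-upper-bound convention.

**Grouped stratified split.** The train size is round(fraction·n),
apportioned across classes by largest remainder, then filled group-by-group
in seeded random order subject to group atomicity. For singleton groups
this reproduces the canonical cohort sizes exactly (595 → 476/119 at 80:20;
705 → 564/141). With multi-sample groups the realized sizes can deviate by
up to one group per class — the price of leakage control; a group larger
than the whole train fraction degrades stratification and triggers a
warning rather than an error. K-fold splitting delegates to scikit-learn's
`StratifiedGroupKFold` (shuffled, seeded) behind the same table interface.

**Normalization** is per-feature z-scoring. Fit mode computes means and
population SDs from the given table (zero-variance features map to zero);
transform mode applies supplied statistics unchanged — held-out data is
always transformed with training-fold statistics.

**Fusion** concatenates the selected features of per-modality tables
aligned on `sample_id`, prefixing each name with its modality
(`FLAIR.glcm_Contrast`) so provenance survives; labels come from the first
table. Because z-scoring is columnwise, normalization commutes with fusion
on disjoint namespaces.

## Synthetic data generator

The generator emulates the *structure* of a multimodal glioma radiomics
study, not the marginal distributions of real texture features (no GLCM
value ranges, no inter-feature correlation structure — a stated non-goal).
Passing tests therefore demonstrate correctness of the machinery and
learnability under controlled signal, not clinical performance.

- Informative feature j of a class-c sample is N(c·δ·σ, σ²) with effect
  size δ (default 1.5, a strong but not trivial radiomics separation;
  benchmark suites use δ = 3 where near-separability is the premise) and
  noise SD σ = 1. Class-ordered mean shifts make the 3-class survival
  signal monotone, so macro metrics are meaningful.
- Default class counts (76, 293) emulate a low-grade/high-grade glioma
  grading cohort; the survival generator's (75, 86, 74) cases with days
  drawn uniformly inside (0–250, 251–500, 501–1800) emulate a 235-case
  survival cohort. Labels are assigned by binning the drawn days, so
  generator and binning logic cannot disagree.
- The age column is Normal(60, 12) years truncated to [18, 90] — a
  realistic glioma cohort profile; the generator does not model an
  age–survival association.
- Augmentation appends k jittered copies per row (Gaussian feature jitter,
  default SD = 0.1 × per-feature SD), preserving label and `group_id`.
  Feature-space jitter stands in for image-space flips/rotations/noise:
  downstream, only the row counts and the leakage structure matter. The
  multiplicities are parameters, not constants; k = 3 on 76 minority cases
  gives 304, and k = 2 on 235 survival cases gives 705 with class totals
  225/258/222 — the emulated study conditions.
- Every table is bit-reproducible from its seed; per-modality streams are
  derived from (seed, CRC32(modality)) so multi-modality studies share
  labels but not noise.

## Wrapper feature selection

**Fitness.** For a candidate mask the fitness is 1 − (stratified k-fold CV
accuracy of a linear SVM on the masked features), computed entirely on the
table the selector is given — callers pass training folds only. An empty
mask returns exactly 1.0. The linear SVM (scikit-learn `LinearSVC`, C = 1,
fixed random state) suits high-dimensional small-sample radiomics data and
makes the fitness deterministic, which permits memoizing evaluations on
the mask bit-pattern — the dominant cost saving, since a wrapper fitness
retrains a classifier per evaluation.

**Binarization.** Positions evolve continuously in [0,1]^d; a candidate is
evaluated through a logistic transfer function centred at 0.5 with a
strict threshold: mask_j = 1 iff sigmoid(gain·(x_j − 0.5)) > 0.5, so a
coordinate exactly at 0.5 is *not* selected. This is the standard
transfer-function recipe for binary metaheuristics.

**Initialization.** Populations start sparse: each coordinate lands above
the threshold with probability `init_density` (default 0.15). This is a
deliberate design choice: on easily separable data, dense random masks
already sit at zero CV error, so the search receives no gradient and the
elitist best freezes at whatever random mask was evaluated first. Starting
from small subsets means features enter a mask only when they measurably
reduce error, which biases the search toward parsimonious, signal-carrying
subsets — the behaviour a wrapper selector exists to produce.

**The three optimizers** implement the canonical update rules of their
source algorithms, each documented per phase in the code:

- *HHO*: prey escape energy E = 2·E0·(1 − t/T) drives the phase switch;
  |E| ≥ 1 explores (perch on a random hawk or relative to the population
  mean), |E| < 1 exploits via soft/hard besiege, with Lévy-flight rapid
  dives (Mantegna's algorithm, β = 1.5) accepted greedily.
- *mGTO*: exploration by migration to unknown places (probability 0.03),
  movement toward other gorillas, or migration to known places;
  exploitation by following the silverback or competing for adult females.
  The "modified" refinement adopted here is a nonlinear (cosine) decay of
  the exploration-control parameter C, sharpening the handover from
  exploration to exploitation relative to the original linear schedule.
- *ZOA*: foraging toward the pioneer zebra (best member), then defense —
  flee-in-place against a lion (step shrinking with time, rate 0.01) or
  convergence on an attacked herd-mate; all moves accepted greedily.

All three clamp positions to [0,1] after every update and share elitism:
the best (mask, fitness) ever evaluated is retained, making per-iteration
best-fitness traces monotone nonincreasing by construction. Defaults
follow standard practice for ~100-feature tables: population 20, 50
iterations, 10 independent seeded runs with mean ± SD of (1 − best
fitness) reported.

**Ensemble vote and Shapley refinement.** The three best masks are
combined by majority vote (feature kept iff selected by ≥ 2); vote counts
are recorded on the result. If the vote is empty (total disagreement —
only seen on degenerate inputs) the union is used and flagged in the
mask's provenance. A linear SVM is then fitted on the ensemble subset and
features are ranked by exact linear Shapley importance: for a linear model
the Shapley value of feature j on sample i, with the data mean as
background, is φᵢⱼ = wⱼ(xᵢⱼ − x̄ⱼ), so importanceⱼ = meanᵢ|φᵢⱼ| in closed
form — deterministic, which the tests exploit. A model-agnostic
permutation sampler is provided behind the same interface for nonlinear
models and converges to the closed form in the linear case. The refinement
keeps top-ranked features until their cumulative share of total importance
first reaches θ (default 0.9), *including* the crossing feature; ties
break by original feature order; θ = 1 keeps all nonzero-importance
features; an all-zero importance vector is an error. The refined mask is a
subset of the ensemble mask by construction.

Per-fold selection (selection fitted inside each training fold) is the
leakage-safe primary mode; running once on a whole training split is a
convenience for global feature-count summaries.

## Reinforcement-learning formulation

The environment presents one sample per step: the state is the feature
vector, the action space is {0,1} for grading or {0,1,2} for survival, the
reward is +1 iff the action equals the label, and an episode ends after a
full traversal (episode length = n). The transition is action-independent
— the cursor advances regardless — so episode accuracy is exactly
(Σr + n)/2n. Traversal order is reshuffled each episode from a seeded
stream (decorrelates replay without changing semantics; the paper-style
fixed order is available by disabling shuffling). The terminal "next
state" is a zero vector whose value is never used, because TD targets
reduce to the reward at terminals. Discounting with γ = 0.99 couples
consecutive, clinically unrelated samples; this is a property of the
episodic formulation itself and is implemented as specified rather than
reinterpreted.

**Networks.** A shared trunk of two 64-unit ReLU layers (He
initialization) feeds variant-dependent heads; the width is adequate for
≤ 120-dimensional radiomics vectors and fast on CPU. Variants:

| variant | architecture | targets |
|---|---|---|
| `dqn` | plain Q head | max |
| `double` | plain Q head | double |
| `dueling` | V + centred A (Q = V + A − mean A) | max |
| `dueling_double` | V + centred A | double |
| `dueling_double_attn` | elementwise sigmoid gate on the trunk output, then V + centred A | double |
| `context_attn` | scalar sigmoid w(s); Q = w·V + (1−w)·(A − mean A) | double |

Two identities follow from centring and are asserted numerically in the
tests: mean_a Q(s,a) = V(s) for plain dueling, and mean_a Q(s,a) =
w(s)·V(s) for the convex fusion. Note the convex fusion at w = ½ is *not*
the plain dueling form (it halves the scale); no compensation is applied —
the two variants are distinct members of the ablation family. The
attention gate of `dueling_double_attn` is the same trunk-level mechanism
without the convex fusion. Forward and backward passes are written
directly in numpy with analytic gradients (verified against central finite
differences in the tests) and a standard Adam optimizer.

**Training loop.** Per step: ε-greedy action (ties → lowest index),
environment step, transition stored in a FIFO replay buffer (capacity
10,000), and — once the buffer holds a batch — one MSE gradient step on
the taken-action Q-values against TD targets from the target network
(batch 16, sampled uniformly without replacement, learning rate 0.001).
Double variants evaluate the online network's argmax action under the
target network. The target network hard-syncs every 100 environment steps
(configurable; "periodically" is the only constraint inherited from the
formulation). ε decays multiplicatively (×0.995, floor 0.01) once per
environment step by default: with 50 episodes a per-episode decay would
never approach the 0.01 floor, rendering that parameter vacuous; per-step
decay honours all three exploration parameters. Per-episode decay remains
selectable. All randomness — initialization, traversal order, ε draws,
batch sampling — flows from one seeded generator hierarchy, so runs are
reproducible to floating-point associativity.

Policies serialize to a single JSON checkpoint (parameters, config, and a
SHA-256 hash of the feature namespace); prediction refuses namespace
mismatches.

## Evaluation

Binary metrics score the high-grade class (label 1) as positive;
multiclass metrics are macro-averaged. Cross-validated reports aggregate
per-fold values as mean ± SD with a normal-approximation 95% CI
(half-width 1.96·sd/√k), matching the usual presentation of fold
statistics. The `crossval_report` contract takes a `fit_predict(train,
validation)` callable that must fit everything — selection included — on
the training fold; fold isolation is asserted in the tests. McNemar's
paired test uses the continuity-corrected statistic (|b−c|−1)²/(b+c) with
an exact two-sided binomial p-value when b + c < 25 and the χ²(1) tail
otherwise. Q-values map to class probabilities via a temperature-1 softmax
— a convention for the Brier/ROC utilities, not a claim that Q-values are
calibrated probabilities. Brier scores use the classical binary form for
1-D inputs and the one-hot multiclass form otherwise; ROC/PR areas are
trapezoidal.

## Benchmark problem sizes

The test suite and the acceptance script keep simulations at desk scale,
chosen so each check exercises the regime it is about:

- Brute-force optimizer checks enumerate all 2^d masks at d ∈ {6, 10}.
- Planted-feature recovery uses 150 + 150 samples, 5 informative of 40
  features at effect size 3, population 20, 30 iterations, 5-fold wrapper
  CV. The cohort size matters: recovery of a redundant signal set by any
  wrapper method requires the CV error to retain a gradient up to the full
  informative set, which at effect size 3 holds around n ≈ 300 but not at
  n ≈ 60 (where two informative features already separate the folds
  perfectly). The acceptance script averages the recovery rate over three
  replicate cohorts for a stable estimate.
- Agent benchmarks use 60 + 60 samples, 20 features, 30 episodes.

## Known limitations

- The synthetic generator plants independent, identically shifted
  informative features; correlated or interacting signals, non-Gaussian
  radiomics marginals, scanner batch effects and censored survival are out
  of scope.
- Wrapper recovery is inherently stochastic: on strongly separable data
  the CV-error plateau means no wrapper can distinguish masks beyond the
  plateau, and reported recovery rates fluctuate run to run.
- The metaheuristic implementations follow the canonical published update
  rules; where the literature offers several "modified" GTO variants, the
  nonlinear exploration-decay refinement was adopted and is isolated in
  one documented code path.
- Exact Shapley values are available only for linear models; the
  permutation sampler is a Monte-Carlo estimate whose error decays with
  the number of permutations.
- No prioritized replay, distributional RL, reward shaping or
  class-weighted rewards; no GPU path — the networks are small enough
  that CPU numpy is the simplest correct implementation.
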