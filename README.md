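# gliorl

Reward-driven glioma grading and survival classification from radiomics
feature tables.

Quantitative MRI (radiomics) pipelines for glioma reduce each tumour to a
vector of ~100 shape, intensity and texture features per modality (FLAIR,
T1, T2, T1CE). Two clinical questions follow: is the tumour low-grade or
high-grade (binary grading), and will the patient's overall survival fall
in the short (0–250 d), medium (251–500 d) or long (501–1800 d) band
(3-class survival prediction)? `gliorl` is a tested, reusable
implementation of a two-part approach for these tasks, aimed at
researchers working with tabular radiomics data:

1. **Ensemble metaheuristic feature selection with Shapley refinement.**
   Three binary swarm optimizers — Harris Hawks Optimization (HHO), a
   modified Gorilla Troops Optimization (mGTO) and the Zebra Optimization
   Algorithm (ZOA) — each search the mask space over the feature namespace,
   minimizing the wrapper fitness 1 − accuracy of a linear SVM under
   stratified cross-validation (an empty mask is penalized to 1.0).
   Features chosen by at least two of the three optimizers form the
   ensemble mask; a linear SVM is fitted on that subset and its exact
   linear Shapley importances φᵢⱼ = wⱼ(xᵢⱼ − x̄ⱼ) rank the features, keeping
   the top-ranked set whose cumulative share of total mean-|φ| importance
   first reaches θ = 0.9. Per-modality selections can then be fused into a
   multi-modality table (`<modality>.<feature>` namespace).

2. **A context-attention dueling deep Q-network.** Classification is cast
   as an episodic reinforcement-learning task: each state is one sample's
   feature vector, actions are class predictions, the reward is +1/−1 for
   correct/incorrect, and an episode is one full traversal of the dataset.
   The Q-network splits into a state-value stream V(s) and an advantage
   stream A(s,·); a learnable scalar attention weight w(s) ∈ (0,1) fuses
   them as

       Q(s,a) = w(s)·V(s) + (1 − w(s))·(A(s,a) − mean_a' A(s,a'))

   trained with experience replay, an ε-greedy policy (ε: 0.5 → 0.01,
   decay 0.995), a periodically synced target network, TD targets
   y = r + γ·max Q'(s',·) (γ = 0.99, y = r at terminals) and MSE loss under
   Adam. The full ablation family is available: `dqn`, `double`,
   `dueling`, `dueling_double`, `dueling_double_attn` (sigmoid gate on the
   trunk) and `context_attn` (the full model).

A synthetic-data module generates radiomics-like per-modality tables with
planted class-informative features, minority-class augmentation with
patient-grouped leakage control, and survival-day labels, so the whole
pipeline is testable without any imaging data.

## Worked example

The `pipeline` subcommand chains simulate → select → train → evaluate from
one YAML config:

```yaml
# pipe.yaml
class_counts: [76, 76]   # samples per class
n_features: 40           # total features, 5 informative
n_informative: 5
effect_size: 3.0         # standardized class separation per informative feature
population: 12           # optimizer agents
iterations: 15
cv_folds: 3
episodes: 30
seed: 7
```

```sh
$ gliorl pipeline pipe.yaml --outdir demo
selected 4 features; test accuracy 1.0000 (reports in demo)
```

`demo/metrics.json` then contains the held-out test metrics and training
curves:

```json
{
  "precision": 1.0, "recall": 1.0, "f1": 1.0, "accuracy": 1.0,
  "confusion": [[15, 0], [0, 15]]
}
```

Here the selector reduced 40 features to 4 (all carrying planted signal),
and the agent's episode accuracy climbed to ~1.0 within 30 episodes
(last five episodes: 0.984, 1.0, 1.0, 0.992, 1.0); the greedy policy then
classifies the 30 held-out samples perfectly — the expected outcome on
strongly separated synthetic data, and a quick end-to-end health check of
selection, training and evaluation together.

The same functionality is available as a library:

```python
from gliorl import (SynthSpec, generate_classification_table, zscore_normalize,
                    select_features, ClassificationEnv, AgentConfig, train)

table, informative = generate_classification_table(
    SynthSpec(class_counts=(150, 150), n_features=40, n_informative=5,
              effect_size=3.0, seed=0))
table, _ = zscore_normalize(table)
mask, report = select_features(table, seed=0)          # HHO + mGTO + ZOA -> vote -> SHAP
env = ClassificationEnv(table.select_features(mask.selected_names()), seed=0)
policy, log = train(env, AgentConfig(episodes=30, seed=0))
```

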