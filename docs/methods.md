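# Methods

This note documents the models, the simulator, and every numerical
convention in `perturbgraph`, including the choices made where the design
was genuinely open.

## Problem setting

A cell state is a vector x ∈ [0,1]^n of normalized expression values over
n genes. A perturbagen is abstracted as the set U of genes it targets
(singletons emulate knockouts, multi-gene sets chemical compounds).
Interventions follow do-operator semantics on a *proxy causal graph*
G: perturbing U deletes every arc into U (intervened genes stop listening
to their parents) while arcs out of U are kept so effects propagate.
Undirected input networks (PPI-like) are doubled into two arcs per edge
before any surgery, so mutilation is well defined for both directed and
undirected sources.

Two data kinds drive training: disease triplets (x_h, U, x_d) — healthy
state, disease genes, diseased state — and treatment triplets
(x_d, U′, x_t). The learning task is the inverse problem: given
(x_d, x_t), predict U′.

## Model

Both modules share one architecture, differing only in the second node
attribute and the output head.

**Node features.** Each gene i carries per-gene learnable tables
("different between nodes, shared across samples"):

- a bin embedding: the expression value is assigned to one of B quantile
  bins (default B = 5; thresholds at quantiles 1/B … (B−1)/B of the
  training expression, linear interpolation, *per gene* by default with a
  global-threshold flag). A value equal to a threshold falls in the lower
  bin; a constant gene maps everything to bin 0.
- a second-attribute embedding: for f_r a perturbation-flag table with
  two states; a flag f ∈ [0,1] selects the interpolation
  (1−f)·E[0] + f·E[1], which is what makes the cycle loss differentiable.
  For f_p the second attribute is the treated-state expression value,
  embedded through a second bin table with the same thresholds.
- a positional embedding, initialized N(0, 1/√d) and trainable.

Concatenation gives 3d features per node (default d = 16; the bundled
validation study uses d = 8, see "Problem sizes").

**Message passing.** The general GNN layer leaves message, aggregation
and update functions free; the implementation uses the simplest
instantiation: mean aggregation over in-neighbors and one learned linear
map on the concatenated [h_i ‖ mean_j h_j] with ReLU update
(`sum` aggregation available; a max aggregator is not implemented).
K layers are stacked (grid-searched over {1,2,3} by default); K = 0
degrades gracefully to a per-node head, useful as an ablation.

**Heads.** A two-layer feedforward head (hidden width 2d) maps each node
embedding to a scalar: f_r applies a logistic to stay in [0,1]; f_p emits
an unbounded score. Rankings sort scores non-increasingly with a
documented tie rule (ascending node index by default; seeded shuffle
optional).

**Graphs seen by each pass.** f_r's supervised (hard-flag) passes run on
the graph mutilated by the known intervention. f_p always sees the
unmutilated graph (U′ is unknown at inference). The soft (cycle) pass
through f_r also runs unmutilated: a soft flag cannot half-delete an arc,
and interpolation of flag embeddings is the minimal differentiable
relaxation.

## Training

- **L_fr** = continuous-target cross-entropy CE(x_out, f_r(x_in, U))
  summed over disease and treatment triplets (disease triplets optional,
  equal weight by default and configurable; the validation study trains
  on treatment data only).
- **L_fp** (mode `supercycle`) = CE(x_t, f_r(x_d, σ(f_p scores))) with
  f_r frozen + per-node binary CE against the indicator of U′. Unit
  weights between the two terms. The supervision term weights positive
  nodes by n/|U′| against the severe class imbalance. Modes `super` and
  `cycle` use one term each; `supercycle` is their exact sum at identical
  parameters (asserted to 1e-10 in tests).
- "Trained in parallel" is implemented as interleaved per-epoch updates
  (f_r step, then f_p step with f_r frozen); the contract is ordering,
  not concurrency. Freezing means f_p's optimizer owns only f_p's
  parameters and gradient accumulation into f_r is disabled — f_r's
  arrays are bit-identical across an f_p update.
- Early stopping per module: stop when the module's validation loss has
  not improved on its best by ≥ 1e-5 for 15 consecutive epochs; the
  reported model is the best-validation snapshot. Optimizer Adam
  (lr 1e-3 default), full-batch unless `batch_size` is set.
- Splits: seeded 5-fold cross-validation with near-equal folds and an
  8:2 train/validation split inside each fold's training portion;
  leave-cell-out trains/validates on one cellular context and tests on
  the union of all others.
- Layer grid: per fold, one fit per K; selection by validation nDCG of
  f_p (ties favor smaller K). The selection criterion is a package
  choice — the training procedure only asks for the best-performing
  hyperparameter setting on validation data.

Numerical notes: cross-entropies are computed from logits via
softplus(z) − t·z (stable for any z); predictions entering the public
`loss_response` are clipped to (1e-7, 1−1e-7); NaN losses abort training
with the epoch number.

## Simulator

Structural equations are logistic-linear with additive Gaussian
exogenous noise: in topological order of a random DAG,

    x_i = logistic( Σ_{j∈Pa(i)} w_ij x_j + b_i + ε_i ),  ε_i ~ N(0, σ)

with intervened genes clamped to exogenous values. The logistic keeps
every state in [0,1], matching normalized expression, and admits
closed-form checks (zero weights ⇒ x_i = logistic(b_i)). DAGs are
sampled by ordering nodes randomly and keeping forward arcs with a given
density; weights are uniform on ±[0.5, 2] (random sign), biases
uniform[−1,1]; default noise σ = 0.05, a mild measurement-scale noise
that leaves intervention effects clearly identifiable.

Clamp values for disease/treatment interventions default to draws from
Beta(0.5, 5) (knock-down, mass near 0) or Beta(5, 0.5) (activation, mass
near 1), with the direction fixed per gene per dataset and the value
redrawn per sample — strong but not degenerate 0/1 states. Paired states
share their exogenous draw by default (`shared_noise=False` available;
how real paired profiles share exogenous variation is not identifiable
from the data the method consumes, so both interpretations are exposed).
The treated state applies only the perturbagen's intervention; a
`keep_disease_intervention` flag keeps the disease clamps active too.
With zero noise, clamping the disease genes back to their healthy values
restores the healthy state to machine precision — the identifiability
floor used by the training tests.

**Latent confounders.** Genes are partitioned into 50 contiguous,
near-equal index blocks; each group g draws μ_g ~ U(−0.5, 0.5) and
σ_g ~ U(0.1, 0.5); a seeded random fraction of groups is selected, and
every expression value of every gene in a selected group is incremented
by a fresh N(μ_g, σ_g) draw, then clamped to [0,1]. The mean range is a
symmetric interval (a degenerate single-point range would make all
confounders identical, contradicting their purpose); group membership by
contiguous index blocks keeps the partition reproducible, with a seeded
assignment available.

**Corruptions of the graph.** Bridge removal deletes a seeded uniform
sample of ⌊fraction·#bridges⌋ bridge edges (bridges computed once on the
input graph); random removal samples from all undirected edges; both
delete the two arcs of a doubled edge. Confidence filtering removes arcs
strictly below the linear-interpolation quantile of the confidence
distribution. The random-removal schedule is configuration, not code
(default 0…0.5 in steps of 0.1).

What the simulator does **not** emulate: assay artifacts, dose/time
covariates, replicate structure beyond i.i.d. noise, feedback loops
(the simulation graph is acyclic), and the scale of real networks
(10⁴ genes). Passing tests therefore show that the method's machinery —
losses, training dynamics, ranking, statistics — behaves as designed
when the causal model is within the model class; they do not certify
performance on real perturbation compendia.

## Evaluation conventions

- **nDCG**: gain 1 − rank/n, discount 1/log2(rank+1) (the standard IR
  discount; stated prominently because it changes absolute values),
  normalized by the ideal ranking's DCG. In [0,1]; 1 iff all true
  targets occupy the top |truth| ranks.
- **Accurately predicted**: the top-N prefix (N = the sample's true
  target count) intersects the truth; the percentage averages over test
  samples.
- **R²**: sample-wise is the squared Pearson correlation of one
  predicted vs one observed profile (undefined for constant vectors,
  reported missing); perturbagen-wise correlates the per-gene means of
  the predicted and observed sample sets of one perturbagen.
- **Reconstruction R²** (used by the ablation): f_p's top-N genes are
  applied as hard flags on the graph mutilated by them, f_r predicts the
  response, and sample-wise R² against the observed treated state is
  averaged.
- **Proximity**: d(P,R) is the mean shortest-path distance over all
  (p,r) pairs on the undirected view (the per-pair-mean formula is the
  primary definition; a closest-node variant sits behind a flag).
  Disconnected pairs are excluded with a logged count. The comparison
  against a random reference uses a one-sided Mann–Whitney U test
  (alternative: method distances smaller), rank-biserial
  r = 2U/(n₁n₂) − 1 — negative when the method is closer — and a
  1,000-resample percentile bootstrap 95% CI.
- **Aggregation**: per method, metric values (percentages rescaled to
  [0,1]) are averaged over metrics and folds; the focal method is
  compared to each competitor with a paired t-test over folds
  (one-tailed for benchmarks, two-tailed for ablations, α = 0.05).
  Zero-variance paired differences make the t statistic undefined; the
  implementation reports the limiting convention (p = 1 for no
  direction-consistent advantage, p = 0 for a constant advantage in the
  tested direction).
- **Baselines**: `random` is a seeded permutation; `prior_list` places a
  given ordered gene list first and shuffles the rest (cancer genes,
  drug targets, and perturbed-genes baselines are instances). The
  indirect wrapper sorts drugs by descending response-R² (ties broken
  lexicographically by drug id), expands each drug to its targets in
  seeded random internal order keeping first occurrences, and appends
  all genes missing from every ranked drug in seeded shuffled order.

## Problem sizes of the bundled validation study

The self-validation harness (`perturbgraph.harness`, driven by
`scripts/acceptance.py` and the heavy tests) simulates 60 genes at arc
density 0.07, 3 disease genes, a 20-perturbagen library of 1–3-gene
sets, 40 paired samples per perturbagen (800 triplets), 5-fold CV with a
{1,2} layer grid, and three replicate seeds. Model width d = 8,
minibatch 128, Adam lr 2e-3, at most 80 epochs under the patience-15
early-stopping rule — a configuration at which the study completes on a
single CPU in well under an hour while the scientific effects of
interest (learned recovery far above chance, the ablation ordering,
confounder robustness) are large against seed-to-seed variability. The
random-baseline reference is a 200-draw Monte Carlo of fresh random
rankings over the same test samples.

## Implementation notes

The GNN modules and training loop run on a small reverse-mode autodiff
engine over numpy (`perturbgraph.autodiff`) written for exactly the
operations this architecture needs; gradients are verified against
central finite differences in the test suite, and graph aggregation runs
as grouped GEMMs (samples sharing an intervention set share a mutilated
adjacency). float32 training is available (`TrainConfig.dtype`), float64
is the default. Checkpoints serialize architecture config plus parameter
arrays and reproduce forward outputs bit-identically on the same
platform.

## Known limitations

- The cycle loss trains through a *soft*, unmutilated relaxation but is
  evaluated with hard top-N mutilated interventions; the gap is a
  modeling choice inherent to differentiating through a discrete output.
- Graph aggregation offers mean and sum but not max.
- The simulator's SCM and the GNN share the "effects flow along arcs"
  assumption; none of the experiments probe cyclic or time-resolved
  dynamics.
- Statistical conventions (quantile interpolation, tie rules, p-value
  conventions at zero variance) are documented rather than universal;
  absolute metric values should be compared only within these
  conventions.
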