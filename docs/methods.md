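# Methods

`pkmt` models two human pharmacokinetic endpoints jointly — clearance
(CL, mL/min/kg) and steady-state volume of distribution (VDss, L/kg) —
from multi-modal molecular inputs, with a gradient boosting machine whose
trees share their structure across the two tasks. This note records the
model, the choices that were genuinely open, and what the synthetic study
does and does not demonstrate.

## The multi-task boosting model

Both targets are modeled on the log1p scale after standardization. Each
boosting round fits **one** regression tree on the pooled second-order
statistics of both tasks and stores a two-component value in every leaf:

* gradients/Hessians per task: `g_t = pred_t − y_t`, `h_t = 1` (squared
  error), zeroed for rows missing that task's target;
* split gain: the sum over tasks of the usual second-order gain
  `G_L²/(H_L+λ₂) + G_R²/(H_R+λ₂) − G²/(H+λ₂)`;
* leaf values per task: `w_t = −sign(G_t)·max(|G_t|−λ₁, 0)/(H_t+λ₂)`
  (soft-thresholded Newton step); a leaf containing no unmasked rows for a
  task emits 0 for it.

Growth is best-first (leaf-wise) to a leaf cap with a depth limit, the
split scan is exact over midpoints of sorted unique feature values (no
histogram binning — datasets here are a few hundred to a few thousand
rows, and exactness lets small instances be checked against a brute-force
reference), and ties prefer the lowest feature index, then the lowest
threshold. Early stopping monitors the validation MSE summed over tasks
with equal weights. Setting `n_tasks=1` yields the single-task baseline
from the identical engine, which makes the multi-task comparison a clean
ablation: the only difference is whether the second task's gradients are
on the table.

How multiple tasks should be combined in the split gain is an open design
point in shared-tree boosting; we use the unweighted sum, which is
deterministic, makes the duplicated-task case exactly reducible to the
single-task fit, and is easy to test. A per-task weight hook exists in the
gain computation path if unequal weighting is ever needed.

Default hyperparameters for the multi-task model are the estimated values
used throughout: learning rate 0.014, 44 leaves, depth 13, L1/L2 =
0.71/2.89, up to 15,000 rounds with 100–150 rounds patience. Single-task
baselines are tuned by seeded random search over learning rate 0.005–0.05
(log scale), 8–64 leaves, depth 6–15, `min_child_samples` 10–50 and L1/L2
on a log scale, minimizing validation GMFE computed on the original scale
after inverse transformation.

## Supervised embeddings

Two small regression networks produce 2-d embeddings per endpoint:

* **CNN**: strided 3×3 convolution blocks over RDKit depictions (RGB,
  white background), global average pooling, then a 2-unit **linear**
  bottleneck, dropout, and a scalar output. The full-scale profile renders
  224×224 images and widens the stack to 512 features; the default test
  profile uses 32×32 images and three blocks (8/16/32 channels) so CPU
  training takes seconds. Weights are randomly initialized (no pretrained
  backbone is assumed anywhere).
* **MLP**: a 561-length descriptor vector — molecular weight, Crippen
  logP, H-bond donors/acceptors, TPSA; a 256-bit Morgan fingerprint
  (radius 2); and a 300-d dense block of feature-hashed radius-0/1
  circular-substructure counts (a deterministic, download-free stand-in
  for pretrained substructure embeddings, keeping length and determinism)
  — through 1–3 ReLU hidden layers into the same linear-bottleneck head.

Training is a three-step protocol per (network, endpoint): (1) seeded
random hyperparameter search (learning rate, dropout 0–0.5, batch size
{8,16,32,64}, and for the MLP 1–3 layers of 32–256 units), each candidate
early-stopped on the validation partition; (2) refit on train+validation
with the selected configuration — early stopping again monitors the
validation partition, the least-leaky monitor available once train and
validation are pooled; (3) extraction of bottleneck activations in
inference mode for all rows. Test rows are used only in step 3, and the
run log proves no fitting stage ever read a test target. The trainer
itself is a compact numpy implementation (Adam, inverted dropout, seeded
shuffling, best-weight restoration), so a fixed seed reproduces training
bit for bit. Maximum epochs act as a cap; early stopping decides the
effective length.

## Shadow-feature selection

Per endpoint, candidate features (transformed animal PK, fup, pKa, and
the eight embedding columns) pass through Boruta-style selection: each
iteration appends a freshly permuted shadow copy of every column, fits a
depth-5 LightGBM learner, and scores all columns by mean |Shapley value|
using the package's own attribution estimators (exact enumeration up to
10 columns, the kernel estimator above that). A feature scores a hit when
it beats the 80th percentile of that iteration's shadow scores; a
two-sided binomial test at α = 0.05 converts hit counts into
accepted/rejected/tentative. The multi-task model uses the union of the
two accepted lists (CL order first); tentative features are excluded.

One calibration detail matters on fixed finite samples: if the learner
sees the identical rows every iteration, a null feature's chance
correlation with the target is *frozen*, recurs every iteration, and can
consistently beat freshly permuted shadows — inflating acceptances. Each
iteration therefore fits the learner on a fresh 50% row subsample with
70% feature sampling per tree, which restores real-vs-shadow
exchangeability for null features. With this in place, a planted feature
explaining ~80% of variance is accepted and pure-noise features are
rejected across seeds at 200 iterations (the full-scale default is
5,000 iterations).

## Attribution

Shapley values use the interventional value function (absent features
replaced by background rows, model output averaged over a background set,
default 30 training rows). The kernel estimator solves the
Shapley-kernel-weighted least squares over an enumerated-plus-sampled
coalition design, constrained so attributions sum exactly to prediction
minus base (local accuracy is enforced, not approximate); with the budget
covering all nonempty proper coalitions it reproduces exact enumeration.
No tree-specific fast path is implemented — both the multi-task model and
the baselines are explained by the same model-agnostic estimator, so
modality-share comparisons are on one convention. Modality shares are
computed over the top-10 features by mean |Shapley|: each modality's
share is its fraction of the summed top-10 importance.

## Preprocessing and splits

* Physiological filter: drop compounds with CL ≥ 20 mL/min/kg or VDss ≥ 5
  L/kg (inclusive bounds); such values are treated as implausible.
* Winsorization at the 1st/99th percentiles applies to numeric *feature*
  columns (animal PK, fup, pKa) on the pooled pre-split table. Targets
  are not winsorized: clipping evaluation targets would couple partitions
  and distort original-scale metrics.
* Transforms: targets and animal PK get log1p then standardization;
  physicochemical covariates standardization only; columns prefixed
  `Caco_2` or `water_solubility` are excluded from transformation. Means
  and SDs are fitted on the training partition only and stored for exact
  inverse transformation (round-trip error ≤ 1e-10).
* Splits are 60/20/20. The optimized mode draws many random partitions
  (10,000 at full scale) and keeps the one minimizing the mean pairwise
  two-sample Kolmogorov–Smirnov statistic of the log1p targets across the
  three partitions — the concrete choice made here for "distribution
  similarity", pluggable via the criterion function. The repeated-split
  protocol uses plain seeded random partitions, which read no data values
  at all. Note the optimized criterion inspects target marginals of all
  three candidate partitions before any model exists; the leakage
  invariance checks therefore run in random-split mode.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular compound collection. Task latents share a common
standard-normal factor with weight √ρ (default ρ = 0.6; the shared-latent
correlation is a free parameter with no anchoring measurement) plus a
molecular-size signal (weight 0.3) carried by fragment-assembled SMILES,
so the structure-derived embeddings have something real to learn. Human
log10 CL is N(0.5, 0.45²) and log10 VDss N(−0.15, 0.45²) — medians ≈ 3.2
mL/min/kg and 0.71 L/kg, chosen so under 10% of compounds trip the
physiological filter, keeping the filter exercised without gutting the
sample. Animal values are log-linear in the task latent with species
intercepts/slopes and noise SD 0.35; fup is a logistic transform of the
distribution latent (higher-VD compounds more protein-bound); pKa values
are truncated normals; 10% of CL and 15% of VD values are masked missing
(never both). Truth latents are kept in a side table that model-fitting
code never touches.

Not emulated: realistic medicinal-chemistry diversity, assay noise
structure, correlated missingness, inter-species nonlinearities. Passing
tests therefore demonstrate that the machinery recovers known structure
under its own assumptions — correlation recovery, multi-task benefit when
tasks genuinely share a latent, selection power/control — not predictive
accuracy on real compounds.

## Problem sizes and numerics

The test and acceptance profiles run the identical code paths at reduced
loop counts, a deliberate scaling of the study protocol: 300–700
compounds, 200 split candidates, 1–2 embedding search trials with tens of
epochs, 25–200 selection iterations, and up to a few hundred boosting
rounds; the full-scale profile (10,000 candidates, 100 trials, 5,000
iterations, 15,000 rounds) is configuration-selectable. Degenerate inputs
are handled explicitly: zero-variance columns scale with SD 1 (warned),
GMFE clips nonpositive predictions at 1e-6 (warned), zero-variance DM
loss differentials are flagged degenerate rather than producing infinite
statistics, empty VD strata report no GMFE, and single-run repeat
summaries report no SD. All randomness flows from one global seed through
`SeedSequence(seed, spawn_key=(stage, substream))`.

## Known limitations

* The shared-tree split criterion (summed gain) is one defensible choice
  among several; alternatives (weighted or randomized combinations) may
  behave differently when tasks conflict strongly.
* The kernel Shapley estimator at reduced budgets is noisy in high
  dimensions; selection consequently subsamples rows for scoring, trading
  variance for runtime.
* The multi-task benefit demonstrated on synthetic data at ρ = 0.8 is a
  directional property of the method under shared structure, not a
  guarantee for weakly correlated real endpoints; negative transfer is
  possible when tasks share little.
* Single-task baselines and the multi-task model differ in tuning effort
  (searched vs fixed configuration), mirroring the study protocol; this
  asymmetry can favor either side depending on budget.
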