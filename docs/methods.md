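# Methods

## The model

A compound is represented as an undirected heavy-atom graph; hydrogens are
implicit and enter only through the per-atom hydrogen-count feature.  The
initial encoding of an atom concatenates: one-hot element identity over
{C, N, O, S, F, P, Cl, Br, I, other}, one-hot topological degree 0–6, one-hot
attached-hydrogen count 0–4, an aromaticity flag, and one-hot formal charge
clipped to [−2, +2] — 28 features in total.  The source method describes its
atom features only as learned, so this initial encoding is the package's own
conventional choice (the standard neural-fingerprint recipe); everything
above it is learned.

Each hidden layer applies, in order:

1. **Degree-indexed graph convolution.**  For node *v* with clipped degree
   *d*, `h'(v) = ReLU(W_d · (h(v) + Σ_{u∈N(v)} h(u)) + b_d)`.  The same
   matrix `W_d` multiplies the self term and the neighbor sum, exactly as the
   update rule is printed; a configuration switch
   (`GCNConfig.tie_self_neighbor=False`) provides separate self/neighbor
   matrices for ablation.  Degrees above 6 share the `d = 6` parameters;
   parameters for degrees absent from a dataset exist but remain at their
   initialization, which keeps checkpoint shapes independent of the data.
2. **Node-level batch normalization** across all nodes of all molecules in
   the mini-batch (not per molecule), per feature channel, with ε = 1e-5 and
   running-statistic momentum 0.9.  A single-node batch is rejected in
   training mode.  Eval mode uses the running statistics.
3. **Neighborhood max-pooling** over the closed neighborhood {v} ∪ N(v).

After the stack, a **graph-gather** readout forms
`g = tanh(Σ_v Φ_{deg(v)} · h(v) + β)`.  The printed readout indexes its bias
by the degree of an unspecified single node inside a sum over all nodes,
which is ill-defined; the package implements β as one shared bias vector
added after the node sum.  The dense head applies a sigmoid per task, so one
multi-task network serves all 12 Meridians.

Multi-fragment SMILES (salts) stay one graph with several components; the
gather sum runs over all atoms regardless of connectivity.

## Training

The objective is the focal loss
`L(y=1) = −α(1−ŷ)^γ log ŷ`, `L(y=0) = −(1−α) ŷ^γ log(1−ŷ)`, averaged over
all (sample, task) cells — the mean (rather than sum) keeps the meaning of
the learning rate independent of batch size and task count.  Probabilities
are clamped to [1e-7, 1 − 1e-7] before the logarithm.  γ = 0 recovers
α-scaled cross entropy.

Optimization is mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).  Reference
defaults: 3 hidden layers × 1024 neurons, batch 64, 200 epochs, learning rate
5e-4, γ = 2, α = 0.5.  Weights use scaled-uniform (fan-in) initialization
with zero biases.  All randomness — initialization, epoch shuffling,
generator sampling — derives from one seed via spawned generator streams, so
a run is reproducible bit-exactly on one platform.

No autodiff framework is used.  The backward pass (focal-loss gradient,
sigmoid/tanh chains, gather scatter, max-pool argmax routing with
first-occurrence tie-break, train-mode batch-norm backward through the batch
statistics, degree-bucketed convolution gradients) is derived and coded by
hand in NumPy, and is checked against central finite differences at relative
tolerance 1e-4 in the test suite.  Arithmetic is float64 throughout.

**Model selection.**  After every epoch the validation macro ROC-AUC is
recorded.  By default `fit` returns the final-epoch parameters
(`FitConfig.model_selection="final"`); `"best_valid"` returns the
best-validation-epoch parameters instead.  Final is the default because on
heavily imbalanced tasks a 10% validation fold may contain only a handful of
positives — the validation AUC is then a coarse, high-variance statistic, and
selecting an epoch by it can return a barely trained model.  With
`"best_valid"`, ties resolve toward the later epoch for the same reason.

## Splitting

All strategies target 80/10/10 fractions; fold sizes use largest-remainder
apportionment, which keeps every fold within one sample of its nominal
fraction for any n.

* **index** — first 80% of rows in input order, then 10%, then 10%.
* **random** — seeded permutation followed by the index cut.
* **random stratified** — iterative multi-label stratification: tasks are
  processed from rarest to most common; each task's not-yet-assigned
  positives are spread 80/10/10 at random and then bumped so that every task
  with ≥ 3 positives keeps ≥ 1 positive per fold (capacity permitting); tasks
  with 1–2 positives go to the training fold with a warning; remaining
  samples fill the folds at random.  The source material uses single-label
  stratification vocabulary for a 12-task problem without elaboration, so
  this jointly-stratifying algorithm is the package's design choice.
* **scaffold** — molecules grouped by canonical Bemis–Murcko scaffold (RDKit),
  groups sorted by size descending (ties by scaffold string), assigned
  greedily: train until ≥ 80%, valid until ≥ 10%, remainder test.  Acyclic
  molecules share one pseudo-scaffold group by default (configurable).  Fold
  sizes here follow group boundaries, not the ±1 guarantee.

## Evaluation

ROC-AUC is the normalized Mann–Whitney U statistic with midrank tie handling
(ties count half).  A task whose evaluation slice contains a single class
reports an undefined AUC rather than an imputed value, and the macro average
skips undefined tasks — with tasks as rare as a few positives per dataset
this happens routinely and imputing 0 or 0.5 would bias the average.
Confusion matrices use threshold 0.5 (prediction positive iff ŷ ≥ 0.5).
Task–task cosine similarity is computed between binary label columns;
all-zero columns flag their pairs as undefined (NaN).

## Synthetic data

The generator emulates the structure of the real compound–Meridian problem —
multi-label supervision, substructure-determined activity, heavy per-task
imbalance — without attempting to mimic real TCM chemistry.  Base molecules
are assembled by seeded random single-bond attachment of 2–6 fragments from a
30-fragment valence-safe library (alkyl chains, carbocycles, benzene, ethers,
amines, carbonyls, amide, chloride, ...); every assembly is sanitized by
RDKit, so 100% of outputs are parseable.  Each task has a planted motif
(pyridine, thiophene, furan, CF₃, nitrile, carboxyl, sulfonamide, bromide,
iodide, nitroalkane, imidazole, cyclopropane by default); the required number
of positives per task receive that motif by additional attachment, and base
molecules are rejection-sampled to be motif-free, so at zero label noise the
label exactly equals the containment indicator and per-task positive counts
are exact.  Label noise flips each cell independently.  The default 12-task
positive fractions (0.528 … 0.0066) reproduce the per-Meridian herb
annotation counts (402 … 5 of 761).

What passing tests on this generator do **not** show: real compounds'
activity is not determined by a single clean substructure, real label noise
is not independent per cell, and the chemistry spans a far larger scaffold
and size distribution.  The synthetic results demonstrate that the
implementation can extract topological signal under controlled imbalance,
not that the reported real-data performance transfers.

A secondary raw-random-graph mode emits arbitrary symmetric graphs with dense
features, bypassing SMILES entirely, for unit-testing the network layers.

## Problem sizes and numerical choices

Desk-scale experiments (tests and `scripts/acceptance.py`) run a depth-2 ×
width-64 network instead of the reference 3 × 1024: on the synthetic tasks
this capacity saturates performance while keeping a full experiment in CPU
minutes.  The focal-vs-cross-entropy comparison trains for 400 epochs — both
arms reach their training-loss plateau, so the comparison measures the
converged classifiers rather than optimizer speed (focal gradients vanish
quadratically near confident predictions, making it the slower-converging
arm).  The learning-sanity check uses n = 500 molecules, 10% positives,
60 epochs; the imbalance comparison n = 1000, 2% positives, 5% label noise,
3 seeds.

Other numerical details: batch-norm ε 1e-5; probability clamp 1e-7; AUC tie
handling by midranks; max-pool gradient routed to the first member attaining
the maximum; degree clip at 6; checkpoint I/O round-trips tensors bit-exactly
(single .npz container with a format-version field).

## Known limitations

* CPU-only, dense per-degree batching: fine up to tens of thousands of
  molecules, not engineered for million-compound corpora.
* No edge (bond-type) features, no attention, no stereochemistry — the
  printed update rules only.
* The compound–Meridian labels inherit herb-level annotations wholesale
  (union over herbs), which ignores mixture effects; this mirrors the source
  construction and its caveats.
* Focal loss improves ranking robustness under imbalance but is known to
  yield under-confident probabilities; threshold-based metrics at 0.5 can
  lag cross entropy early in training even when ranking quality is equal.
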