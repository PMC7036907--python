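# meridiangcn

Cost-sensitive graph convolutional networks for multi-label classification of
chemical compounds, built for the Traditional Chinese Medicine (TCM) Meridian
prediction problem: given a compound's structure (SMILES), predict which of
the 12 Meridian categories (liver, stomach, lung, spleen, kidney, heart,
large/small intestine, bladder, gallbladder, cardiovascular, three end) the
herbs containing it are annotated with.  The tasks are heavily imbalanced —
positive rates in the herb data span ~53% (liver) down to ~0.7%
(cardiovascular, three end) — which is what the cost-sensitive loss addresses.

The package is aimed at cheminformatics practitioners who want a transparent,
CPU-only, NumPy implementation of this model family: every layer's forward
pass *and* analytic gradient is explicit, hand-derived code, verified against
finite differences in the test suite.

## Model

A molecule is an undirected heavy-atom graph *G = (V, E)*.  Each atom *v*
starts from a fixed-length encoding (element, degree, attached H count,
aromaticity, formal charge) and is updated by stacked hidden layers, each
consisting of:

* **degree-indexed graph convolution** —
  `h'(v) = ReLU( W_d · (h(v) + Σ_{u∈N(v)} h(u)) + b_d )`, where the weight
  matrix `W_d` is shared by all nodes of topological degree `d = deg(v)`
  (clipped to 0..6);
* **node-level batch normalization** over all nodes of the mini-batch;
* **neighborhood max-pooling** — element-wise maximum over the closed
  neighborhood `{v} ∪ N(v)`.

A **graph-gather** readout produces one embedding per molecule,
`g = tanh( Σ_v Φ_{deg(v)} · h(v) + β )`, followed by a dense multi-task head
with element-wise sigmoid: one probability per Meridian task.

Training minimizes the **focal loss**

```
L(y=1) = −α (1−ŷ)^γ log ŷ        L(y=0) = −(1−α) ŷ^γ log(1−ŷ)
```

with Adam (lr 5·10⁻⁴, batch 64, 200 epochs, γ=2, α=0.5 by default; γ=0
recovers α-scaled cross entropy).  Four splitting strategies are provided —
index, random, random-stratified (iterative multi-label stratification), and
Bemis–Murcko scaffold split — and evaluation reports per-task confusion
matrices and Mann–Whitney ROC-AUC with a macro average.

Because the original herb→compound annotation database is not redistributable,
the package ships a synthetic-data module that generates valid molecules by
fragment assembly and plants task-specific substructure motifs at configurable
positive fractions (defaults mirror the 12-task Meridian imbalance profile),
so the full pipeline is testable end to end.

## Worked example

```python
from meridiangcn import MeridianGCN, FitConfig
from meridiangcn.synthetic_data import SynthSpec, generate_dataset

spec = SynthSpec(n_molecules=500, task_names=("planted",),
                 positive_fractions=(0.1,), motifs=("c1ccncc1",), seed=0)
smiles, graphs, labels = generate_dataset(spec)

model = MeridianGCN(graphs, labels, smiles)
split = model.split("random_stratified", seed=0)
res = model.fit(split, FitConfig(depth=2, width=64, epochs=60, seed=0))
print(res.summary())
```

prints (abridged):

```
MeridianGCN fit results
================================================================
compounds: 500   tasks: 1   split: random_stratified (seed 0)
depth 2  width 64  batch 64  epochs 60  lr 0.0005  gamma 2.0  alpha 0.5
best epoch: 60 (valid macro-AUC 1.0000)

[test] macro ROC-AUC: 1.0000
   task  TP  FP  TN  FN    AUC  n
planted   4   0  45   1 1.0000 50
```

The test ROC-AUC of 1.0000 says every motif-carrying molecule in the
50-compound test fold is ranked above every non-carrier — the network has
recovered the planted pyridine signal from topology alone.  The confusion
row shows the threshold-0.5 decisions: 4 of the 5 test positives cross the
threshold, one sits below it (ranking perfect, calibration slightly
conservative — typical of focal-loss training), and there are no false
alarms.

The same pipeline is available from the shell:

```bash
meridian-gcn simulate --n-molecules 500 --seed 0 --out-dir run/
meridian-gcn split run/compounds.csv --strategy random_stratified --out-dir run/
meridian-gcn train run/compounds.csv --seed 0 --out-dir run/
meridian-gcn evaluate run/compounds.csv run/checkpoint.npz --out-dir run/
meridian-gcn sweep run/compounds.csv --preset layers --out-dir run/sweep/
```

`featurize` additionally exports the ECFP4 (radius-2, 1024-bit hashed
circular) fingerprint matrix for use with external baseline classifiers.

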