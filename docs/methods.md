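# Methods

## The problem

The octanol/buffer distribution coefficient at physiological pH, logD7.4,
summarizes a drug candidate's effective lipophilicity across all of its
ionization states. Unlike logP — which describes only the neutral species —
logD depends on how strongly and where a molecule ionizes at pH 7.4, and it
is the quantity most predictive of absorption, distribution and toxicity
risk. Experimental logD data are scarce (the shake-flask method is slow),
while two related data sources are abundant: logP measurements and liquid
chromatography retention times (RT), which correlate strongly with
lipophilicity. This package implements a modeling strategy that exploits
both: pretrain a graph neural network on RT, then fine-tune it as a
two-headed logD/logP multitask regressor, with per-atom microscopic-pKa
channels injecting ionization information directly into the atom features.

## Model

The backbone is an attention-gated message-passing network in the
Attentive FP family:

1. **Atom embedding.** Each atom's 76-dimensional feature vector (layout
   documented in `rtlogd.featurize`) is projected to the hidden width and
   passed through a leaky ReLU.
2. **Message passing** (default 3 layers). For every directed edge the
   network scores the (receiver, neighbor) pair, normalizes scores over
   each receiver's incoming edges with a softmax, and forms an
   attention-weighted context vector; node states are updated with a GRU
   cell. The first layer's neighbor messages are built from the neighbor
   state concatenated with the 12-dimensional bond features, so bond
   information enters once at the bottom.
3. **Attentive readout** (default 2 timesteps). A virtual super node,
   initialized as the sum of node states, repeatedly attends over all
   atoms of its molecule and updates through its own GRU. The final
   per-atom attention weights are the interpretability signal exposed by
   `Model.atom_attention` (min–max normalized per molecule; an all-equal
   distribution, including single-atom molecules, maps to 0.5).
4. **Output head.** Batch normalization, dropout (p = 0.2) on the pooled
   vector, then a two-layer MLP producing one output (RT pretraining) or
   two (logD, logP).

The network, including training, runs on a small reverse-mode autodiff
engine over NumPy arrays (`rtlogd._autodiff`). The engine implements only
the dozen operations the model needs (dense algebra, elementwise
nonlinearities, gather/segment-sum over ragged graphs, segment softmax)
and every operation is validated against central finite differences in the
test suite, as is the assembled model end to end. Node aggregation uses
unordered scatter-adds, so predictions are invariant to atom relabeling to
within float tolerance (checked at 1e-5).

### pKa atom channels

Columns 74–75 of the atom features carry the acidic and basic microscopic
pKa of the atom, affinely rescaled from [−10, 20] pKa units to [0, 1]
(bounds chosen to cover the micro-pKa range of drug-like ionizable groups;
configurable). Assignment rules: an acidic pKa only on non-carbon atoms
bearing at least one hydrogen; a basic pKa only on nitrogen atoms without
a positive formal charge. Atoms without an assigned site carry sentinels
at the non-ionizable end of each scale — 1.0 on the acidic channel (low
values mean stronger acids) and 0.0 on the basic channel (high values mean
stronger bases).

pKa values come from a pluggable provider. The shipped provider is a
rule-based surrogate: a SMARTS table of common ionizable groups
(carboxylic acid 4.2, phenol 10.0, aliphatic alcohol 15.5, thiol 10.5,
sulfonamide 10.1, amide N–H 17.0, pyrrole N–H 16.5; aliphatic amine 10.5,
aniline 4.6, pyridine 5.2, imine 6.0), with the strongest site winning
when rules overlap. A precomputed per-atom table
(`smiles,atom_index,kind,pka`) can be supplied instead; any callable
mapping an RDKit molecule to a `PkaAnnotation` works. Training a
machine-learned microscopic-pKa predictor is out of scope by design.

## Training schedule

* **Pretraining** (`pretrain_rt`): single-head model on RT with SmoothL1
  loss (β = 1 on internally z-scored targets), Adam with L2 weight decay,
  a seeded 9:1 random train/validation split, and early stopping on
  validation SmoothL1.
* **Fine-tuning** (`finetune_multitask`): the backbone transfers, the
  output heads are freshly initialized, and the learning rate drops by
  `finetune_lr_factor` (default 10) to preserve pretrained structure.
  Passing no checkpoint gives the from-scratch ablation at the full
  learning rate. Per molecule, SmoothL1 is computed for whichever of
  logD/logP is present; when both are present the two task losses are
  averaged; the batch loss is the mean over molecules. Masked slots are
  provably inert: the loss and its gradients are independent of the value
  stored in an absent label, and a batch with only logD labels leaves the
  logP head's weights untouched. Early stopping maximizes the averaged
  squared Pearson correlation over the validation molecules of each task
  (tasks with no labels at all are excluded from the average).
* Data enters fine-tuning through a Bemis–Murcko **scaffold split**
  (default 8:1:1): scaffold groups are assigned whole, largest group
  first, filling train, then validation, then test, so no framework leaks
  across partitions; acyclic molecules form one shared bucket. Partition
  sizes can therefore deviate from the exact ratio by up to one scaffold
  group. The split is deterministic given its seed, and fine-tuning
  refuses a split with scaffold leakage.

Default training parameters: lr 1e-3, weight decay 1e-5, batch 128,
patience 20, SmoothL1 β 1.0, Adam betas (0.9, 0.999). All randomness
(initialization, batch order, dropout, splits) flows from explicit seeds;
identical configuration and seed reproduce predictions byte-identically on
CPU.

## Metrics and the CALlogD baseline

`rtlogd.evalbase` implements MAE, RMSE, the coefficient of determination
R² = 1 − SS_res/SS_tot (against the mean of the measured vector — *not*
squared Pearson, which is used only for early stopping; the two are kept
distinct throughout), and Spearman's rank correlation with average ranks
for ties. All four are checked against independent reference
implementations to 1e-10.

The analytic baseline is the classic ionization-correction formula

    logD(pH) = logP − log10(1 + 10^((pH − pKa)·δ)),   δ = +1 acids, −1 bases,

which assumes only the neutral species partitions into octanol, so
logD ≤ logP always, with equality only for a vanishing ionized fraction.
The strict form is monoprotic; an explicitly labelled two-term extension
for amphoteric molecules (one acidic plus one basic site) is available and
is used by the synthetic-label generator, but the strict mode is the
default for baseline comparisons. Equivalence with an independent
Henderson–Hasselbalch species-fraction computation is verified to 1e-9
over 1,000 random (logP, pKa) tuples.

## Curation pipeline

`rtlogd.curation` reproduces a database-curation protocol for distribution
coefficients: pH window filter (inclusive 7.2–7.6 by default — records
"outside the range" are removed, so the boundary is kept), octanol-only
solvent filter (case-insensitive), flag-and-report screening against any
reference predictor (|deviation| > 3 log units by default; corrections
remain manual, preserving auditability), RDKit structure standardization
(largest organic fragment, canonical tautomer, charge neutralization where
a simple (de)protonation is valid — quaternary ammonium stays charged),
and replicate aggregation (arithmetic mean when the spread is ≤ 0.5 log
units, exclusion otherwise; the tolerance is configurable because
"significant variation" has no standard numeric definition). Every input
record ends up either in a surviving record's provenance or in the
rejection log with a reason, and the pipeline is insensitive to input
order.

## Synthetic data: what it does and does not show

`rtlogd.synthdata` generates valid, standardizable molecules by decorating
~30 ring-system templates (benzene, pyridine, piperidine, indole,
naphthalene, biphenyl, benzyl-piperidine, …) with ~28 substituents
(halogens, alkyl, carboxylic acid, amines, phenol, amide, sulfonamide, …),
about 6,400 unique structures in all. Ground truth is constructed, not
predicted: logP from a small additive atom/group contribution table; pKa
from the same functional-group rules the featurizer uses; logD7.4 from
logP and the strongest site(s) through the ionization correction above;
RT = 600 + 150·logD seconds, clipped to the typical chromatographic span
0.3–1471.7 s. Observed labels add independent Gaussian noise (defaults:
0.2 log units for logD/logP, 30 s for RT — roughly the reproducibility of
shake-flask and LC measurements) and 30% of molecules carry only one of
logD/logP, exercising the masked loss.

This generator makes every claim in the test suite checkable against a
known mechanism: the RT–logD link is affine by construction, logP and logD
are monotonically related except where ionization intervenes, and the
label function is exactly representable by a function of molecular
structure. Passing tests therefore demonstrate that the machinery —
curation bookkeeping, featurization, optimization, transfer — behaves
correctly, and that the network can recover a structured ground truth from
graphs. They do not demonstrate chemical accuracy on real measurements:
real logD data have heavier noise tails, far broader chemistry, and pKa
values that no lookup table captures.

## Measured properties (recomputed by tests and `scripts/acceptance.py`)

* **Parameter recovery:** a hidden-width-64 model trained on 800 synthetic
  molecules (noise sd 0.2, scaffold split) reaches held-out logD R² ≥ 0.7
  against the noise-free ground truth.
* **Transfer benefit:** with only 200 logD training molecules, the median
  external-set MAE over 5 training seeds is lower with RT pretraining (on
  2,000 RT molecules, trained to convergence) than without. The
  evaluation set is 300 generated molecules disjoint from the training
  library; an earlier protocol that scored the ~16-molecule scaffold-test
  partition and capped both arms at the same small epoch budget was too
  noisy to be meaningful and under-trained the pretrained arm, which
  learns at lr/10.
* Problem sizes throughout (800/2,000/200/300 molecules, hidden width 64)
  are the package's chosen desk-scale study conditions; they keep every
  experiment reproducible in minutes on one CPU while leaving the
  mechanisms under test fully exercised.

## Numerical choices and degenerate cases

* Segment softmax subtracts the per-segment maximum before
  exponentiation (standard stabilization).
* Batch normalization uses batch statistics in training and running
  statistics (momentum 0.1) at inference, so repeated inference is
  bit-identical; dropout is inference-disabled.
* Molecules with no bonds (single heavy atom) receive zero message
  context and are handled throughout; their attention weight is the
  degenerate 0.5.
* Tanimoto similarity of two empty fingerprints is defined as 0.
* Tie-breaks are deterministic everywhere: dissimilarity-prioritized
  sampling orders by (similarity, canonical SMILES); equal-sized scaffold
  groups are ordered by a seeded shuffle before the stable size sort.
* Unknown elements fall into the one-hot catch-all slot; hydrogens are
  implicit (heavy-atom graphs only).

## Known limitations

* The rule-based pKa surrogate ignores electronic effects of neighboring
  substituents; it is a provider for testing and desk-scale modeling, not
  a pKa predictor.
* The additive synthetic logP scheme has no conformational or proximity
  effects; real group contributions interact.
* The amphoteric logD extension treats the two sites as independent
  (no zwitterion partitioning term).
* Training is CPU-only and single-threaded by design; wall-clock scales
  linearly with dataset size and quadratically with hidden width, which
  is the main practical constraint on model capacity.
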