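# rtlogd

A toolkit for predicting **logD7.4** — the n-octanol/buffer distribution
coefficient at physiological pH — with a graph attention neural network
that transfers knowledge from chromatographic retention time (RT), learns
logD and logP jointly in a two-headed multitask setting, and injects
microscopic-pKa information directly into its atom features. It is aimed
at cheminformatics and ADMET modelers who need a lipophilicity model that
stays accurate in the data-scarce logD regime.

## What's inside

* **Curation** (`rtlogd.curation`) — turn raw endpoint tables into clean
  per-molecule datasets: pH window 7.2–7.6, octanol-only solvent filter,
  flag-and-report outlier screening, RDKit standardization (salt strip,
  tautomer, neutralization), replicate averaging with exclusion of
  discordant groups, full rejection-log bookkeeping.
* **Featurization** (`rtlogd.featurize`) — 76-dimensional atom features
  (74 canonical + acidic/basic microscopic-pKa channels normalized to
  [0, 1]), 12-dimensional bond features, a pluggable pKa provider with a
  rule-based surrogate, ECFP4/Tanimoto utilities, Bemis–Murcko scaffold
  splitting, and dissimilarity-prioritized sampling.
* **Model** (`rtlogd.net`) — an Attentive-FP-style network: attention-gated
  message passing with GRU node updates, attentive super-node readout,
  batch norm + dropout, two-layer MLP head(s); per-atom attention weights
  for interpretability. Runs on the package's own NumPy autodiff engine —
  no GPU or deep-learning framework required, fully deterministic under a
  seed.
* **Training** (`rtlogd.train`) — SmoothL1 pretraining on RT, multitask
  fine-tuning at a 10× reduced learning rate with masked per-molecule
  losses, early stopping on averaged squared Pearson correlation.
* **Evaluation** (`rtlogd.evalbase`) — MAE, RMSE, R², Spearman, and the
  closed-form **CALlogD** baseline
  `logD(pH) = logP − log10(1 + 10^((pH − pKa)·δ))` (δ = +1 acids, −1 bases).
* **Synthetic data** (`rtlogd.synthdata`) — a seeded generator of valid
  molecules with internally consistent ground-truth logP/logD/RT labels
  and per-atom pKa annotations, so the entire pipeline is testable offline.

## Worked example

Generate a synthetic benchmark, curate it, pretrain on RT, fine-tune the
two-headed logD/logP model, and predict:

```bash
rtlogd synth --n 600 --seed 0 --out synth.csv
rtlogd curate --in synth.csv --out curated.csv --log rejections.csv
# -> {"kept": 1639}
rtlogd pretrain --data synth.csv --seed 0 --hidden-dim 64 --max-epochs 40 --out rt.npz
# -> best epoch 39 val loss 0.0366
rtlogd finetune --data synth.csv --init rt.npz --seed 0 --hidden-dim 64 \
    --max-epochs 150 --out model.npz
# -> best epoch 108 val avg r^2 0.9823
rtlogd predict --model model.npz --in mols.csv --out preds.csv
```

`preds.csv` then contains one row per molecule with both heads:

```
smiles,logD_pred,logP_pred
OCc1ccc(CC2CCCCC2)cc1,4.064963,4.134968
CC(C)c1cc2ccccc2cc1C(C)(C)C,5.866692,6.197891
Clc1ccccc1,2.658931,2.556680
CC(=O)c1cccc(CO)n1,1.322764,1.113523
NCc1csc(-c2ccncc2)c1,-1.141476,1.628536
```

Note the last molecule: its aliphatic amine ionizes at pH 7.4, so the
predicted logD (−1.14) sits well below its predicted logP (1.63) — exactly
the ionization gap the pKa channels and multitask head are designed to
capture. `rtlogd evaluate --model model.npz --data synth.csv --out metrics.json`
reports per-task metrics on this set:

```json
{"logD": {"mae": 0.3080076737354704, "rmse": 0.4096366650548909,
          "r2": 0.9727726356864813, "spearman": 0.9895414693102554, "n": 519},
 "logP": {"mae": 0.26469959460370246, "rmse": 0.3436262772404291,
          "r2": 0.9547322678022858, "spearman": 0.9820494329320174, "n": 520}}
```

The analytic baseline and per-atom attention are one command each:

```bash
rtlogd callogd --logp 2.0 --pka 7.4 --type acid      # -> 1.69897 (half-ionized)
rtlogd explain --model model.npz --smiles "CC(=O)Oc1ccccc1C(=O)O"
```

The same functionality is available as a library — see
`rtlogd.train.pretrain_rt` / `finetune_multitask` and
`rtlogd.featurize.mol_to_graph` — and the modeling details are documented
in [docs/methods.md](docs/methods.md).

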