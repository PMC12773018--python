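# pepdev

Multi-property therapeutic-peptide prediction toolkit: dual-modality
(amino-acid / SMILES) data handling, similarity-aware leakage-proof
train/validation splitting, embedding-based predictor heads, a
cross-attention multitask binding-affinity model, and transfer-learned
half-life regression — all exercisable end to end on seeded synthetic
fixtures, with no downloads and no pretrained weights.

## What's inside

| module | role |
| --- | --- |
| `pepdev.core` | domain types: records, tasks, datasets, validation |
| `pepdev.io` | FASTA, CSV/TSV dataset tables, split manifests, checksummed model artifacts |
| `pepdev.chem` | sequence→SMILES assembly, Morgan fingerprints + Tanimoto, physicochemical profile (MW, pI, GRAVY, net charge at tunable pH), low-complexity flag |
| `pepdev.align` | global affine-gap alignment with documented scoring/tie rules |
| `pepdev.split` | greedy identity clustering (0.3 / 0.8 bidirectional coverage), Taylor–Butina clustering at Tanimoto 0.6, 80/20 cluster-level splits, split propagation across modalities, distribution-matched splits, leakage audits |
| `pepdev.embed` | deterministic baseline featurizers (pooled/unpooled), external-embedder adapter contract, embedding cache |
| `pepdev.nn` | small NumPy autodiff engine + layers (conv, multi-head attention) so positional heads need no DL framework |
| `pepdev.heads` | head families: elastic net, SVM/SVR, gradient-boosted trees, MLP (pooled) and CNN, transformer (unpooled, masked); Huber loss; warm-start fine-tuning |
| `pepdev.hpo` / `pepdev.metrics` | log-uniform random search with trial budgets (200/50/20); F1 / best-F1 / AUC / MCC / accuracy, Pearson / Spearman / R²; per-task best-model selection |
| `pepdev.affinity` | unified −log10-molar affinity scale with strong/medium/weak classes, cross-attention multitask affinity model, half-life unit normalization, stability-pretrain → half-life fine-tune under 5-fold CV |
| `pepdev.synth` | seeded generators for every task family (imbalanced binary corpora, bimodal log-permeability around −6.0, position-dependent peptide–protein affinity on the 4–12 scale, sparse log-normal half-life + large stability corpus) |
| `pepdev.cli` | `pepdev` command wiring synth → split → featurize → train → evaluate → predict |

## CLI quick start

```bash
# synthetic corpus with a planted charge signal
pepdev synth --task hemolysis --n 2000 --seed 1 --rule charge --out data.tsv

# leakage-proof identity-cluster split (whole clusters are atomic)
pepdev split --table data.tsv --method identity --seed 1 --out split.tsv

# train a gradient-boosted head on the train partition, report val metrics
pepdev train --table data.tsv --task hemolysis --manifest split.tsv \
             --family gbt --seed 1 --out model/

# predict new peptides (adds MW, pI, GRAVY, net charge columns)
pepdev predict --artifact model/ --fasta peptides.fa --out preds.tsv

# small hyperparameter search across families, pick the winner
pepdev benchmark --table data.tsv --task hemolysis --manifest split.tsv \
                 --families enet,gbt,mlp --trials 20 --seed 1

# cross-attention affinity model on the synthetic pair generator
pepdev train-affinity --n 1500 --seed 1 --epochs 12

# stability-pretrain then fine-tune half-life regression (5-fold CV)
pepdev train-halflife --n 150 --seed 1 --family transformer --target log1p
```

Every stochastic stage takes an explicit `--seed`; split manifests record
method, parameters and seed so any split can be reproduced and audited.

## Notes

* External pretrained embedders (protein / chemical language models) are
  integrated only through the adapter contract in `pepdev.embed`; this
  repository ships no weights, and all tests run on the deterministic
  baseline featurizers.
* The greedy identity clustering is a documented re-implementation of the
  usual identity/coverage clustering protocol (min identity 0.3, bidirectional
  coverage 0.8); memberships are not bit-identical to external tools.
* Real curated corpora (and therefore published benchmark numbers) are out
  of scope; the synthetic generators emulate their statistical structure
  so the pipeline's behavior is testable offline.
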