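# immunoloop

An active-learning screening pipeline for discovering small-molecule
modulators of innate-immune signaling, built around a virtuous cycle of
surrogate-model training and (simulated) high-throughput screening:

1. **Representation** — candidate molecules (SMILES, salts split and joined
   with a reserved `[LINK]` token) are tokenized to SELFIES, one-hot encoded,
   and embedded into a fixed low-dimensional latent space by a variational
   autoencoder (NumPy implementation: MLP encoder, Gaussian latent, 2-layer
   GRU decoder), or alternatively by 2048-bit ECFP4 fingerprints.
2. **Objectives** — plate readings are normalized by same-plate positive
   controls, replicates merged with propagated errors, a 70%-confluency
   viability filter applied, and 12 signed functional goals defined over
   8 agonist–pathway combinations (NF-κB × {LPS, MPLA, CpG, generalist}
   enhance/suppress, IRF × {LPS, MPLA, cGAMP, generalist} enhance).
3. **Surrogates** — 12 independent exact Gaussian-process regressors (RBF
   kernel, marginal-likelihood hyperparameter fitting) map latent
   coordinates to signed log2 fold-changes with predictive uncertainty.
4. **Selection** — Expected Improvement scoring combined with a
   multi-objective Kriging-believer loop assembles batches of at least *B*
   candidates per round; believed labels are rank-1 Cholesky updates that
   never survive into the next round's refit.
5. **Convergence** — stabilizing-predictions monitoring (mean Bhattacharyya
   distance between successive posteriors over a frozen stop set) and 5-fold
   cross-validated MAE trajectories.
6. **Interpretation** — 85 RDKit `fr_*` fragment counters, zero-variance and
   |ρ| > 0.95 correlation filtering, row normalization, and LASSO models per
   agonist–pathway combination with cross-validated penalty selection.
7. **Synthetic HTS** — a planted fragment-based structure–activity oracle
   generates libraries, plate readings (lognormal replicate noise,
   multiplicative plate effects, positive controls) and viability scores, so
   the whole pipeline is testable offline.

## Test

```bash
python -m pytest tests/            # full suite incl. acceptance properties
python -m pytest tests/ --ignore=tests/test_acceptance.py   # quick subset
```

The acceptance tests that recompute statistics from the published
screened-compound supplementary CSV skip automatically unless
`IMMUNOLOOP_SCREEN_CSV` points at a local copy.

## CLI

```bash
immunoloop simulate  --config sim.yaml --out simout/   # synthetic screen CSVs
immunoloop run-round --config run.yaml --round 1       # fit + select a batch
immunoloop converge  --config run.yaml --out conv.csv  # D_B trajectory
immunoloop report -r round1.csv -r round2.csv --library-size 139998
immunoloop glossary  --out fragment_glossary.csv       # 85 fragment codes
```

`run.yaml` example:

```yaml
library: simout/library.csv
embedding: {kind: fingerprint, n_bits: 64}
batch_size: 72
seed: 0
stop_set_size: 1000
profiles: [simout/round0.csv]
```

## Layout

```
src/immunoloop/
  chemlib.py          molecules, SELFIES, one-hot, fingerprints, Tanimoto
  hts_data.py         plate normalization, replicates, viability, 12 goals
  embedding.py        NumPy VAE + fingerprint embedding (LatentSpace)
  surrogate.py        exact GPs, CV-MAE, incremental candidate posteriors
  active_learning.py  EI, Kriging-believer batching, campaign orchestration
  design_rules.py     fragment features, filtering, LASSO rule models
  synthetic_hts.py    planted-SAR libraries, plate simulation, viability
  reporting.py        campaign summary statistics
  cli.py              click command group (`immunoloop`)
  _vendor/selfies/    vendored SELFIES tokenizer
```
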