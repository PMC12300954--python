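# wheatyield

Multi-source seasonal data fusion and winter-wheat yield prediction with
triple cross-attention.

The package models one region-year ("season record") from four sources —
monthly remote-sensing vegetation indices (NDVI/EVI), monthly climate
variables, monthly dynamic soil variables, and a static soil vector —
plus year / region / planting-area covariates, and predicts yield per
unit area (kg/hm²). The pipeline:

1. **`synthetic`** — seeded generator of season records with a known
   yield function (linear terms + a remote-sensing × climate interaction
   + region effects + year trend + noise), standing in for proprietary
   observational data so every stage is testable end to end.
2. **`dataset`** — monthly resampling, linear interpolation of missing
   time nodes, year-based test split with a seeded, region-stratified
   8:2 train/validation split, normalization (train statistics only;
   reversible per-sample series normalization available), covariate
   encoding (one-hot region, z-scored area, linear year), growth-stage
   and prefix time windows.
3. **`features`** — per-source extraction: sliding windows → stacked
   GRUs → convolutional residual block (CRB) for dynamic sources; a CRB
   over a lifted static-soil token; all sources emit a common model
   dimension.
4. **`fusion`** — six directed cross-attention interactions among the
   three source embeddings (efficient additive attention), channel
   concatenation, CRB, and a sigmoid/LayerNorm gate. Concat/add/avg/max
   baselines are drop-in alternatives.
5. **`model`** — covariate tokens + sinusoidal positions, a 2-layer
   dual-branch encoder (multi-head self-attention ∥ graph attention over
   a local token graph), and a 2-layer Fourier (cos‖sin‖MLP) decoder.
6. **`training`** — Adam, MAE loss, batch 8, lr 1e-3, early stop after
   20 stalled epochs, ×0.9 lr decay after 10; MAE/RMSE/MAPE/MSPE/R²;
   ablation grids and time-window studies.

Everything runs on a small in-repo numpy autograd engine (`autograd`,
`nn`) — no deep-learning framework required.

## CLI

```sh
# generate a dataset (CSV + generator-coefficient JSON)
wheatyield simulate --seed 7 --out data/

# train (config file optional; flags win over file values)
wheatyield train --data data/ --seed 0 --out runs/full/

# held-out test metrics for the 2021/2022 seasons
wheatyield evaluate --data data/ --model runs/full/ --out runs/full/eval/

# per-record predictions
wheatyield predict --data data/ --model runs/full/ --out runs/full/preds.csv

# ablations: tfe_gat (4 rows) or fusion (8 rows)
wheatyield ablate --data data/ --grid fusion --epochs 30 --out runs/abl/

# time-window studies: prefix (first 3..9 months) or stage (T1..T4)
wheatyield window-study --data data/ --study stage --out runs/win/
```

Every command writes a `resolved_config.json` snapshot next to its
outputs, and a single `--seed` drives all randomness (generation, split,
init, shuffling, dropout).

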