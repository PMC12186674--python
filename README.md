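# reactopt

Multiobjective Bayesian self-optimization of chemical reactions over mixed
continuous + descriptor-featurized discrete (solvent) design spaces.

The package closes the loop a self-optimizing flow platform needs, with no
hardware attached:

- **`reactopt.space`** — bounded continuous variables plus a solvent choice
  carrying five sigma-moment descriptors; per-solvent upper-bound overrides
  (solubility caps); stratified Latin hypercube sampling; numeric condition
  encoding (raw descriptors or PCA components).
- **`reactopt.solvents`** — library filtering (basic solvents out, insolubles
  out, solubility-capped equivalents attached), descriptor standardization +
  PCA, the analytic per-experiment cost objective, and Beer–Lambert
  transparency checks (`A = εcl`).
- **`reactopt.surrogates`** — a model zoo (Gaussian process, gradient-boosted
  tree ensemble, random forest, MLP ensemble) behind one
  `predict -> (mean, sd)` contract, with seeded k-fold cross-validation and
  best-family selection per objective.
- **`reactopt.moo`** — Pareto dominance, exact 2-D hypervolume,
  Monte-Carlo **joint batch EHVI** under common random numbers (yield sampled
  from the surrogate, cost analytic), batch selection (exhaustive on small
  pools; greedy + swap hill-climbing otherwise) and L-BFGS-B batch
  refinement within bounds.
- **`reactopt.campaign`** — the closed loop (initialize → propose → update →
  check_stopping) with a master seed fanning out to every RNG, plus the
  pool-based acquisition benchmark (one point per iteration, surrogate
  refit each step, hypervolume learning curves).
- **`reactopt.explain`** — permutation feature importance (RMSE units,
  optional block shuffling of the solvent descriptors) and partial
  dependence curves.
- **`reactopt.simulate`** — a synthetic yield surface driven by the
  catalyst×time photon dose, reagent equivalents and the solvent's sig3
  descriptor, with 1.8 % replicate noise; plus solvent-library and
  evaluated-pool generators, so every downstream module can be exercised
  offline.
- **`reactopt.io` / `reactopt.cli`** — campaign CSV / solvent library
  formats, JSON run configuration (schema-validated), state persistence and
  a packaged 16-row seed-campaign fixture.

## CLI

All commands read a JSON run configuration (see `reactopt.io.RunConfig` for
the schema; unknown keys are rejected) and are deterministic given
config + seed + inputs.

```sh
reactopt init      --config cfg.json --out design.csv          # LHS design
reactopt simulate  --config cfg.json --conditions design.csv --out campaign.csv
reactopt suggest   --config cfg.json --campaign campaign.csv --out proposals.csv
reactopt update    --campaign campaign.csv --results new.csv --out merged.csv
reactopt benchmark --config cfg.json --pool campaign.csv --out curves.csv
reactopt explain   --config cfg.json --campaign campaign.csv --out-prefix xai
reactopt solvents  --config cfg.json --out report.json
```

A minimal config is `{}` (all defaults; a synthetic solvent library is
generated from the master seed). Point `"solvent_library"` at a CSV/TSV with
columns `name, sig0, sig2, sig3, sig4, sig5, price_per_L, he_solubility_mM,
cat_solubility_mM, is_basic` to use your own.

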