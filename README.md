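# streamnets

A pipeline for analysing how oil-and-gas development relates to stream
benthic macroinvertebrate (BMI) communities, exercised end-to-end on a
synthetic data generator with known planted effects:

- **`streamnets.synth`** — synthetic BMI samples (200 ± 20 individuals,
  multinomially allocated from a log-linear abundance model), taxon traits
  (order, functional feeding group, pollution tolerance 0–10), and well
  records with catchment geometry. Stress effects (conventional /
  unconventional well density, developed land cover) and latent
  co-occurrence blocks are planted and recorded in latent-truth tables.
- **`streamnets.wells`** — point-in-polygon attribution of wells to
  catchments (boundary counts as inside) and COGD/UOGD density and presence
  computation; only active wells spudded strictly before the sample date
  count.
- **`streamnets.metrics`** — richness, Shannon diversity (natural log),
  sensitive-EPT richness (E/P/T orders with tolerance ≤ 4), functional
  feeding group proportions (unknown/piercer excluded), mean pollution
  tolerance, and a surrogate composite condition index on [0, 100] with a
  configurable calibration.
- **`streamnets.cooccur`** — co-occurrence networks from 10-sample
  observation matrices: Pearson on ln(x+1) pair statistic, 100
  richness-preserving null communities (taxa drawn ∝ regional frequency,
  abundances resampled from regional pools), standardized effect sizes,
  normal-approximation p-values, Benjamini–Hochberg retention at
  FDR < 10⁻⁴, and topology/composition metrics (size, connectance, Newman
  modularity, mean |SES|). GraphML export included.
- **`streamnets.ensemble`** — eligibility filter (spring, wadeable, no AMD,
  DLC ≤ 20%), joint 4-way OGD classification, (HUC8 × class) strata with a
  ≥ 15-sample minimum, and the replicated ensemble (100 reps × 10-sample
  subsets per stratum) with keyed RNG substreams so results are independent
  of processing order.
- **`streamnets.models`** — REML random-intercept linear mixed models
  (crossed intercepts for ecoregion and AMD at sample level, HUC8 at network
  level), Wald 95% CIs and p-values with significance stars, and the OLS of
  the network condition index on topology metrics.
- **`streamnets.cli` / `streamnets.io`** — CSV I/O with schema validation
  and the command-line orchestration.

## CLI

Stages are individually re-runnable from intermediate CSVs; `all` runs
everything and is byte-reproducible for a fixed config and seed:

```sh
streamnets simulate --config config.yaml --out-dir out
streamnets wells    --config config.yaml --out-dir out
streamnets metrics  --config config.yaml --out-dir out
streamnets networks --config config.yaml --out-dir out --reps 100
streamnets models   --config config.yaml --out-dir out
streamnets all      --config config.yaml --seed 7 --out-dir out
```

Example `config.yaml`:

```yaml
seed: 7
reps: 100          # networks per stratum
k: 10              # samples per network
min_n: 15          # stratum eligibility minimum
dlc_filter_max: 0.20
q_threshold: 1.0e-4
n_perm: 100
simulation:
  n_taxa: 50
  n_huc8: 3
  default_stratum_size: 20
  block_strength: 1.0
  effect_sizes: {cogd: -0.5, uogd: 0.0, dlc: -0.3}
```

Outputs land in `--out-dir`: `samples.csv`, `taxa.csv`, `counts.csv`
(long format), `wells.csv`, `catchments.csv` (WKT polygons),
`attribution.csv`, `metrics.csv`, `ensemble.csv`,
`model_results_{samples,networks}.csv`, `ols_ibi_topology.json`, and the
latent-truth tables `truth_samples.csv` / `truth_taxa.csv`.

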