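# alanphen

Process-based autumn-phenology modelling with a nighttime-light forcing
term. The package implements four date-of-foliar-senescence (DFS) models —
cooling degree days (CDD), the Delpierre model (DM), its spring-influenced
(SIAM) and spring–summer-temperature (DMT) variants — plus ALAN-enhanced
versions in which an annual coefficient
`ALANin_i = exp(k·(ALAN_i − ALAN_max)/ALAN_max)` multiplies the daily
forcing rate. Around the models it provides:

- **`alanphen.synthetic`** — seeded synthetic site datasets (seasonal AR(1)
  temperature with a warming trend, growing noisy radiance, monthly climate,
  leaf-unfolding dates, GDP) with observed DFS generated by a known model,
  so every stage is testable with ground truth;
- **`alanphen.alan`** — night-length astronomy, monthly disaggregation of
  annual radiance by night hours, the MAD outlier filter, water/light-use
  efficiency ratios, and the ALAN–GDP regression used to project radiance;
- **`alanphen.calibration`** — particle-swarm calibration (RMSE objective
  with a missing-year penalty), Pearson-R/RMSE/AIC scoring, base-vs-ALAN
  model comparison, and century-scale projection;
- **`alanphen.stats`** — detrended standardized anomalies, Theil–Sen +
  Mann–Kendall trends, partial correlations, preseason-window optimization,
  ridge-regression driver sensitivities, moving-window modulation of climate
  sensitivity by ALAN, and a Gaussian sensitivity-vs-intensity fit;
- **`alanphen.pipeline`** — a YAML-driven end-to-end workflow
  (simulate → filter → fit → evaluate → sensitivity → project) whose stages
  communicate only through CSV tables (see `docs/data_dictionary.md`).

Conventions: fixed 365-day years (Feb 29 dropped), 1-based day-of-year,
accumulation starting no earlier than the northern summer solstice (DOY 172).

## CLI

```sh
alanphen run-all --config experiment.yaml   # full pipeline
alanphen simulate -c experiment.yaml        # just the synthetic bundle
alanphen evaluate -c experiment.yaml        # through model comparison
```

A minimal config (all keys optional; defaults in `alanphen.pipeline`):

```yaml
synthetic: {n_sites: 5, year_start: 2001, year_end: 2022, seed: 1}
truth:
  family: CDD
  alan_enabled: true
  params: {t_th: 22.0, cdd_th: 120.0, k: -3.0}
models:
  - {family: CDD, alan_enabled: false}
  - {family: CDD, alan_enabled: true}
pso: {particles: 40, iterations: 200}
projection: {end_year: 2100, gdp_growth: 0.05}
output_dir: experiment_out
master_seed: 17
```

Outputs land under `output_dir/` as plain CSV plus a `manifest.json`
carrying the config hash; reruns with the same config are bit-identical.

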