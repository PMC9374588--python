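# beemon

Biodiversity-dynamics analysis for multi-year, season-long bee monitoring
data: diversity and evenness summaries, individual-based rarefaction and
species accumulation, Bray–Curtis / NMDS / perMANOVA composition analysis,
community phylogenetic structure (SES-MPD with random species grafting
below genus tips), phenology (seasonality and breadth with subsampling
correction), per-species standardized abundance trends, and trait → trend
models (PGLS under Brownian motion, plus OLS). A synthetic monitoring-data
simulator with ground truth stands in for field collections and powers the
parameter-recovery test suite.

## Layout

| Module | Role |
| --- | --- |
| `beemon.core_io` | Specimen/trait/tree ingest and validation; month- and year-scheme community matrices with explicit zero units |
| `beemon.synthetic_data` | Simulator: lognormal rank abundance, Gaussian activity windows, per-species year trends, sites × traps × weekly design, pure-birth genus tree, traits, ground truth |
| `beemon.community_metrics` | Abundance, richness, inverse Simpson, evenness, analytic rarefaction, accumulation curves, replicate summaries, percent-change effect sizes, yearly CV |
| `beemon.phylo_structure` | Ultrametric forcing, random species grafting, cophenetic distances, MPD, SES-MPD against richness-matched nulls |
| `beemon.composition` | Bray–Curtis, nonmetric MDS (Kruskal stress-1), one-factor perMANOVA |
| `beemon.trends` | 5-knot regression-spline period fits; standardized per-species slopes ×5 with significance classes; abundance–change diagnostics |
| `beemon.phenology` | Median capture day, 10th–90th percentile breadth, 30 × 500 subsampling correction |
| `beemon.trait_models` | Brownian covariance, PGLS and OLS single-trait models |
| `beemon.pipeline_cli` | `beemon` CLI and the end-to-end `run_all` orchestration with seeded substreams and a manifest |

## CLI

```bash
# synthetic dataset (specimens CSV, genus tree Newick, traits, ground truth)
beemon simulate --seed 7 --out sim/

# full pipeline on a simulation; deterministic given the seed
beemon run --simulate --seed 7 --out run/

# single stages
beemon summarize --simulate --out metrics/
beemon run --simulate --only compose --only trends --out subset/

# real data
beemon run --config config.yaml --out run/
```

A YAML config supplies input paths, the site → site-group map, season
months, seeds, and replicate counts:

```yaml
simulate: false
specimens_path: specimens.csv
tree_path: genus_tree.nwk
traits_path: traits.csv
grouping: {S1: G1, S2: G1, S3: G2, S4: G2}
season_months: [4, 10]
seed: 1
n_null: 999
n_perm: 999
```

Each run writes tidy CSV tables (summaries, SES, ordination coordinates,
perMANOVA, species trends, phenology, trait models) plus `manifest.json`
recording seeds, config, and per-stage status. All randomness flows from
the master seed through named substreams, so re-running with the same seed
reproduces every table byte-for-byte.

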