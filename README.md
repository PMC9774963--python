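# beaktraj

Life-history reconstruction from stable-isotope trajectories along
cephalopod beak subsections.

Cephalopod beaks grow continuously: the rostrum tip holds the oldest
material and the posterior crest edge the newest, so δ13C/δ15N measured on
sequential crest subsections form an ontogenetic archive. `beaktraj`
implements the full analysis pipeline around that idea:

- **`data_model_io`** — domain types (measurements, subsections,
  trajectories, populations), tidy long-CSV readers/writers with explicit
  per-isotope missingness, the fine/coarse subsection cutting grid,
  advisory QC (C:N band, replicate precision), and YAML/JSON run configs.
- **`size_reconstruction`** — power-law allometry (beak length → mantle
  length → body mass) with additive mean-residual bias corrections; the two
  published regional crest-length models ship as presets. The default
  length–mass model is a two-anchor calibration (a ≈ 1.87e-4 g, b ≈ 2.60)
  because the source equation's coefficients are not published — treat it
  as approximate and override in config when better coefficients exist.
- **`isotope_metrics`** — δ notation, additive trophic-level estimation
  (beak +4.8‰ correction, Arctic 3.8‰ enrichment per level, baseline
  TL = 2), per-trajectory summaries (extremes, min→max and newest→oldest
  ranges, mean ± SE), the individual specialization index
  s = V_within / (V_among + V_within), and Spearman correlation with
  pairwise deletion.
- **`nonparametric_tests`** — Mann–Whitney U (midranks, tie-corrected
  variance, continuity-corrected normal p, exact enumeration for small n),
  Kruskal–Wallis + Dunn, Skillings–Mack for incomplete blocks (reduces
  exactly to Friedman on complete data) with a Nemenyi-style post hoc, and
  Pearson χ² / Fisher's exact by hypergeometric enumeration.
- **`niche_metrics`** — standard ellipse areas (SEA, SEAc, Bayesian SEAb
  under a vague normal–inverse-Wishart posterior), convex-hull area (TA),
  directional SEAc-ellipse overlap (720-vertex polygonal approximation),
  and probabilistic niche-region overlap matrices.
- **`mixing_model`** — two-isotope Bayesian diet mixing with TEF
  uncertainty, Dirichlet prior, adaptive random-walk Metropolis on
  log-ratio coordinates (no external PPL), mixing-polygon feasibility
  screening, draw-wise source aggregation, and posterior-profile
  comparison via count tests.
- **`stage_classifier`** — the four-stage size-based ecological
  periodization (<20 mm, 20–50 mm, >50 mm, gelatinous ≥200 mm), stage
  durations under linear growth, and biomass partitioning.
- **`synthetic_data`** — seeded trajectory/population simulators, consumer
  generators with known diet truth, and the packaged per-individual
  summary-table fixture used by the acceptance suite.

## CLI

```bash
beaktraj simulate --out pop.csv --n 14 --seed 42
beaktraj read --in pop.csv --validate
beaktraj summarize --in pop.csv --baseline 8.8 --tef 3.8
beaktraj fit-allometry --in pairs.csv --predictor UCL --out model.json
beaktraj size --in pop.csv --model model.json --crest-length 40
beaktraj test --method skillings-mack --in matrix.csv
beaktraj niche --in individuals.csv --baseline 8.8 --draws 2000
beaktraj mix --consumers cons.csv --sources sources.csv --iters 20000 --seed 7
beaktraj classify --in sizes.csv
beaktraj biomass --components nordic.json
```

Global flags: `--config cfg.yaml`, `--seed N`, `--log-level LEVEL`.

## Notes and caveats

- The canonical input is a tidy long CSV (one row per
  individual × subsection); blank isotope cells are kept as missing, never
  dropped.
- The packaged summary fixture transcribes printed table values verbatim,
  including one known internal inconsistency (individual F1's δ15N min/max
  vs. its printed range); consumers should prefer the range columns.
- The bundled prey-source library is synthetic and clearly labelled
  non-authoritative; supply real source values for actual diet inference.
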