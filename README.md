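# spatialtme

Single-cell spatial proteomics analysis of the tumor microenvironment
(TME), built for two-cohort multiplex immunohistochemistry (mIHC) studies
of tissue resections — e.g. treatment-naive vs immunotherapy-treated
pancreatic cancer. The package turns per-cell marker positivity with
preserved spatial coordinates into interpretable, patient-level machine
learning: which cell states, T cell functional phenotypes and spatial
arrangements distinguish treated tissue, and which associate with long
disease-free survival.

## What it computes

Given a cell table (centroids + binary marker positivity), region
metadata (patient, cohort, histopathologic site, tissue area) and a
patient table (disease-free survival for the treated cohort):

1. **Hierarchical phenotyping** — every cell is assigned exactly one of
   23 cell states by an exclusive marker-gating hierarchy (first matching
   sibling wins); 18 states are T cell states. The hierarchy is a YAML
   config, so the immunological definitions are data, not code.
2. **Functionality barcodes** — each T cell's binary expression over the
   fixed marker order (TOX1, TIM3, TCF-1, CD38, PD-1, EOMES, CD39, CD44,
   LAG-3, T-BET) is a 10-bit barcode (≤ 1024 possible) summarizing its
   differentiation/exhaustion phenotype.
3. **TME features per region** — state densities (cells/mm²), barcode
   densities, and cell–cell spatial interactions (centroid distance
   ≤ 20 μm, counts normalized by the summed densities of the states
   involved), assembled into one region × feature matrix.
4. **Leave-one-patient-out elastic net** — per-site logistic models with
   mixed L1/L2 penalty (l1_ratio 0.5) predict treatment status or DFS
   group (median split). Each fold holds out all regions of one patient;
   preprocessing (log10+1, train-fit min-max with test clipping) and
   SMOTE balancing happen inside the fold. Held-out predictions pool into
   one confusion matrix: accuracy, F1, AUC.
5. **Exact linear SHAP** — per-feature attributions with the closed form
   w·(x − μ); mean |SHAP| ranks features, the feature-vs-SHAP correlation
   sign gives the direction each feature pushes predictions.
6. **Interpretation** — Mann–Whitney U + Benjamini–Hochberg tests on top
   features; clustering of top barcodes by the T states expressing them;
   recurrent cellular neighborhoods (60 μm compositions, K-means with
   elbow-selected K), barcode residency over neighborhoods, and per-RCN
   Ki-67/GrzB functional fractions.

A synthetic-data generator ships as first-class, tested code: it emulates
the full data structure (clustered immune aggregates, gating-consistent
marker positivity, planted cohort and survival effects) so the entire
pipeline runs and validates without any real data.

## Worked example

```python
from spatialtme import AnalysisConfig, GeneratorConfig, generate_cohort, run_full

cells, regions, patients, _ = generate_cohort(
    GeneratorConfig(
        seed=5,
        n_patients_per_cohort={"naive": 6, "aCD40": 10},
        regions_per_patient={"T": 1, "IA": 2, "TAS": 1},
        cells_per_region=200,
    )
)
bundle = run_full(cells, regions, patients, AnalysisConfig(seed=5))
```

This generates 12,800 cells across 64 regions from 16 synthetic patients,
computes 807 TME features and prints (via `examples/06_full_pipeline.py`):

```
treatment-status models (pooled held-out metrics per site):
  T    acc=0.69 f1=0.76 auc=0.75  significant top features: 2/15
  IA   acc=0.91 f1=0.93 auc=0.98  significant top features: 15/15
  TAS  acc=0.75 f1=0.83 auc=0.63  significant top features: 0/15

survival models (treated cohort; normal pancreas excluded):
  T    acc=0.70 f1=0.73 auc=0.68
  IA   acc=0.85 f1=0.84 auc=0.97
  TAS  acc=0.40 f1=0.40 auc=0.24

RCN stage: K = 4 neighborhoods in treated immune aggregates
```

Reading: the immune-aggregate (IA) models recover the planted treatment
and survival effects best (AUC 0.98 and 0.97) because the generator
plants its T-cell effects where T cells live — in immune aggregates —
while sites with little planted signal sit near chance. All 15 top IA
features differ significantly between cohorts after multiple-testing
correction. The RCN stage then groups the neighborhoods of those regions
into 4 recurring composition motifs and reports where the survival
model's top barcoded T cells reside.

The `examples/` directory holds one short script per capability
(generation, phenotyping, features, modelling, neighborhoods, full
pipeline); each prints the numbers it computes and what they mean. A thin
CLI (`tme synth|features|model|run`) wraps the same library calls for
shell use.

## Layout

```
src/spatialtme/
  constants.py   canonical tokens (cohorts, sites, marker orders)
  io.py          CSV readers/writers + cross-table validation
  gating.py      gating hierarchy, state assignment, barcodes
  synth.py       synthetic cohort generator with planted effects
  features.py    densities, interactions, feature matrix
  models.py      LOPO elastic net, SMOTE, scoring, linear SHAP
  barcodes.py    expressing-state profiles + barcode clustering
  rcn.py         neighborhoods, K-means/elbow, residency, fractions
  stats.py       Mann–Whitney + Benjamini–Hochberg
  pipeline.py    end-to-end orchestration and report bundles
  cli.py         thin click CLI (`tme`)
  data/gating_default.yaml   the shipped 23-state hierarchy
```

See `docs/methods.md` for the full model description, parameter defaults
and numerical choices.
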