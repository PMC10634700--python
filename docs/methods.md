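# Methods

`spatialtme` implements a region-level analysis of multiplex
immunohistochemistry (mIHC) single-cell data from two-cohort tissue
studies: hierarchical cell phenotyping, T cell functionality barcoding,
spatial feature quantification, patient-level cross-validated elastic-net
classification with exact linear SHAP attribution, and recurrent cellular
neighborhood (RCN) clustering. This note records the model, its
assumptions, the tunable parameters, and the numerical choices made where
the design was genuinely open.

## Data model and assumptions

A dataset is three CSV tables. The *cell table* holds one row per
segmented cell with centroid coordinates in microns and binary positivity
for each antibody in the panel; thresholding of stain intensities into
positivity calls happens upstream in imaging software and is out of scope
here. Coordinates live in a per-region frame: every spatial operator acts
within one region, and regions are treated as independent tissue frames
(no global slide geometry is assumed). The *region table* maps each region
to a patient, a treatment cohort (`naive` vs `aCD40`), a histopathologic
site (tumor `T`, immune aggregate `IA`, tumor-adjacent stroma `TAS`,
normal-adjacent pancreas `NAP`) and a tissue area in mm². The *patient
table* carries disease-free survival (DFS) in months for treated patients.

## Phenotyping

Cell states are assigned by a declarative exclusive gating hierarchy
(`gating_default.yaml`). Each gate is a conjunction of required-positive
and required-negative markers, optionally with *any-of* groups (at least
one of a marker set positive) — the any-of extension is needed to express
exhaustion gates such as "PD-1⁺ with at least one of TIM3/LAG-3".
Siblings are evaluated in document order and the first match wins, which
makes the assignment a partition regardless of overlapping predicates.
Cells matching no terminal gate fall into a residual `Other` leaf, which
also reconciles the taxonomy count: 18 explicitly gated T states plus 4
named non-T lineages plus the residual = 23 leaves. Exact marker
predicates for the CD8 states (T_NAIVE, T_EFF, T_EM, T_EMRA, T_EX, T_TEX)
are configuration, not code: the analysis machinery is agnostic to the
immunological definitions, and correctness is defined against the config.

Every T-state cell receives a **functionality barcode**: its positivity
pattern over the fixed 10-marker order TOX1, TIM3, TCF-1, CD38, PD-1,
EOMES, CD39, CD44, LAG-3, T-BET (at most 2¹⁰ = 1024 distinct barcodes).
Ki-67 (proliferation) and granzyme B (cytotoxicity) are separate
functional flags, never barcode bits.

## TME features

Three families per region, assembled into one region × feature matrix
with a deterministic column order (densities by taxonomy order, then
barcodes, then interaction pairs, each lexicographic):

* **state density** — cells of each leaf per mm²;
* **barcode density** — T cells per barcode per mm²;
* **spatial interactions** — unordered cell pairs with centroid distance
  ≤ 20 μm (inclusive; compared on squared distances so the boundary never
  suffers square-root rounding), binned by unordered state pair and
  normalized by the summed densities of the *distinct* states involved:
  count{A,B}/(d_A + d_B), and count{A,A}/d_A for same-state pairs (the
  "states involved" are read as the distinct-state set; covered by a
  regression test). Pair counting is unordered: each cell pair counts
  once, a cell never pairs with itself.

The accelerated neighbor search (k-d tree) is required by test to agree
exactly with an O(n²) scan. Barcodes or pairs unobserved in a region are
zeros, not missing; the column-count identity |leaves| + |observed
barcodes| + |observed pairs| is asserted on every assembly.

## Classification

One elastic-net logistic model per histopathologic site, for two tasks:
treatment status (all regions) and DFS group (treated regions only; NAP is
excluded from the DFS task, which mirrors its scarcity in this study
design). DFS labels come from a median split over treated patients;
values strictly above the median are `long`, ties go to `short` (a
configurable choice — "long" should strictly exceed the median).

Cross-validation is leave-one-patient-out: each fold's test set is all
regions of one patient, so patient-specific signal cannot leak. Inside a
fold, in order: log10(x+1) transform; per-column min-max scaling fit on
the training rows only, applied to both, with test values clipped to
[0, 1] and training-constant columns mapped to 0 (information-free, and
avoids dividing by zero); SMOTE balancing of the training classes
(synthetic minority samples are convex combinations x_i + u(x_nn − x_i)
of a minority point and one of its k = min(5, minority−1) minority
neighbors; a single-point minority is left unbalanced with a warning);
then the penalized fit.

The fit minimizes (1/n)Σ log-loss + α(½(1−λ)‖w‖² + λ‖w‖₁) with mixing
λ = 0.5 (equal lasso/ridge weight) and a fixed per-sample strength
α = 0.05 shared across folds — on a typical fold of this data the
per-sample normalization makes this comparable to the common default of
an unnormalized C = 1 fit, and the normalization makes the optimum
invariant to duplicating training rows. The solver is SAGA at tolerance
1e-6 with a bounded iteration budget; non-convergence raises an error
with diagnostics rather than returning a half-converged model. A fully
degenerate design (every training row identical) is fit analytically as
the intercept-only model. Held-out predictions are pooled over all folds
into a single confusion matrix; accuracy and F1 (positive class: `aCD40`,
resp. `long`) come from that matrix, and AUC is the midrank statistic on
the pooled positive-class probabilities. Pooled leave-one-patient-out AUC
is mildly pessimistic under the null (each fold's training set
under-represents the held-out class), which the chance-level test
accounts for by using a cohort large enough to keep the bias small.

**Attribution** uses the exact closed form for linear models:
shap_i(x) = w_i (x_i − μ_i), with the background μ the fold-train feature
mean (computed before SMOTE, on real rows). Per row, Σ shap + (w·μ + b)
equals the model margin to machine precision. Feature importance is the
mean |SHAP| over all pooled held-out rows; a feature's direction is the
sign of the Pearson correlation between its value and its SHAP value over
those rows (for a linear model, the coefficient's sign toward the
positive class). The top-k importance share is Σ top-k / Σ all.

## Barcode interpretation

For each top barcode feature, only T cells carrying the barcode inside
regions of the model's site *and* of the group the barcode was predictive
of (by its SHAP direction) are counted; their distribution over the 18
T states is the barcode's expressing-state profile. Profiles are compared
by Pearson correlation and grouped by agglomerative clustering with
average linkage on the 1 − r distance. Correlation type and linkage are
configurable; the cluster count is a parameter (not auto-selected), since
on real data it is chosen by inspecting the heatmap. A zero-variance
profile has no defined correlation and is assigned 0 with a warning.

## Recurrent cellular neighborhoods

Every cell in the treated immune-aggregate regions seeds a neighborhood:
all cells with centroid distance ≤ 60 μm, seed included (distance 0 ≤ 60;
a configurable flag can exclude the seed), summarized as the taxonomy
proportion vector. Neighborhoods pooled across regions are clustered by
K-means for K = 2…12 with 10 restarts at a fixed seed; the best-restart
inertia curve is anchored at the trivial K = 1 inertia (the total sum of
squares, which needs no clustering run) and K is chosen at the point of
maximum perpendicular distance from the chord joining the curve's
endpoints, both axes normalized to [0, 1]. The anchor matters: without
it the chord construction could never select K = 2, since endpoints have
zero chord distance. Ties, including a perfectly linear decay, break
toward the smallest K. RCN indices are relabelled by descending member
count so RCN1 is always the largest; all-identical compositions fall back
to a single cluster with a warning.

Residency of the survival model's top barcodes is the per-(barcode, DFS
group) distribution over RCNs (rows sum to 1), log10(x+1)-transformed and
Ward-clustered (Euclidean) into two groups; per-cluster mean RCN-fraction
profiles are reported. Per-RCN functional fractions (share of Ki-67⁺ or
GrzB⁺ T cells among the RCN's T cells) are reported with raw counts
alongside — low-count RCNs are flagged by their counts, and an RCN with
no in-scope T cells reports a missing fraction. Regulatory T states are
excluded from the GrzB analysis (numerator and denominator).

## Statistics

Top features are compared between groups with two-sided Mann–Whitney U
tests on the *raw* feature values: both the log10+1 and min-max
transforms are strictly monotone, and a rank test is invariant under
monotone maps, so the scale choice is provably immaterial. The exact null
is used for combined n ≤ 20 without ties, otherwise the normal
approximation with tie correction. Benjamini–Hochberg step-up correction
is applied per analysis family (one model's top-feature set); adjusted
p < 0.05 is flagged.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any real
cohort's absolute numbers. Defaults mirror the study shape: 18 untreated
and 11 treated patients; 3 regions each of T/IA/TAS and 2 of NAP per
patient (319 regions); 0.5 mm² square regions; 250 cells per region (the
real data run to thousands of cells per region — the default is scaled so
a full run completes in about a minute, and all statistical contracts are
size-stable). Site-specific state frequencies make tumor regions
epithelial-dominant, immune aggregates T/B-cell-rich, stroma mixed and
normal pancreas myeloid-dominant, with CD4 helper lineages roughly
two-fold the CD8 compartment. Immune-aggregate regions use a clustered
spatial model (3 Gaussian aggregates, σ = 40 μm, holding 85 % of immune
cells); other sites are uniform.

Planted effects are multiplicative: the treated cohort gains
antigen-experienced Th1/CD8 density (e.g. CD44⁺ Th1 ×1.9) and
CD44/T-BET/TCF-1/TIM3/CD39 marker positivity (×1.4–1.6), the untreated
cohort gains TOX1/EOMES (×1.6–1.9) and naive populations; within the
treated cohort, long survivors gain CD44/CD38/CD39/TIM3/LAG-3 and short
survivors TOX1/PD-1. Probabilities that leave [0, 1] after shifting are
clamped with a logged warning. DFS months for treated patients are drawn
from two well-separated log-normals (medians ≈ 20 vs ≈ 5 months,
σ = 0.25 on the log scale) with n_long = n//2 planted long survivors, so
the median split provably recovers the planted grouping.

Two generator contracts make downstream stages exactly testable. First,
marker positivity for a planted state is drawn from the *exact
conditional* Bernoulli distribution given that the full positivity vector
gates to that state: the free gating markers that can influence the
assignment (≤ 8 per leaf) are enumerated exhaustively, each consistent
combination is weighted by its Bernoulli product probability, and one is
drawn — so hierarchical phenotyping recovers every planted state with
zero error while marker marginals stay correct on the consistent support.
Second, every (patient, region) pair owns an RNG stream derived from the
master seed by hashing the identifiers, so adding a region never perturbs
the cells of another.

What the generator does **not** emulate: segmentation artifacts, staining
batch effects, spatially varying cell density gradients, intensity-level
noise (positivity is generated directly), marker co-expression beyond
what the gating hierarchy induces, and realistic absolute densities.
Passing tests therefore demonstrate the correctness and statistical
behavior of the pipeline, not biological claims about real tissue.

## Problem sizes and determinism

The default test suite runs cohorts of 5–16 patients per cohort with
100–250 cells per region; the acceptance script runs the full study-scale
default (≈ 80,000 cells, 319 regions) in roughly a minute. Every source
of randomness (generator, SMOTE, solver, K-means) derives from explicit
seeds; the full pipeline is a pure function of (input tables, config,
seed) and is required by test to reproduce byte-identical report bundles.

## Known limitations

* Gating correctness is relative to the shipped config; alternative
  immunological definitions of the CD8/Th1 states require editing the
  YAML, not the code.
* The elastic-net regularization strength is a fixed constant, not tuned
  per fold; this trades a little accuracy for strict reproducibility and
  leakage safety.
* Pooled LOPO AUC carries a small pessimistic bias under the null in very
  small cohorts; permutation baselines should be run at adequate cohort
  sizes (see the chance-level test).
* Mann–Whitney p-values for n > 20 use the tie-corrected normal
  approximation; extremely small tail probabilities are approximate.
* The RCN stage clusters neighborhoods pooled across regions; it does not
  model between-region density differences beyond composition.
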