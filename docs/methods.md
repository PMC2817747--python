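# Methods

## Model and procedure

### Nested variance components

Healthy-tissue expression (median-centered log2) of gene *g* is modelled as

    y_wbs = μ + W_w + B_wb + ε_wbs,
    W ~ N(0, σ_w²),  B ~ N(0, σ_b²),  ε ~ N(0, σ_s²),

a two-fold nested random-effects model: women are sampled from a population,
breasts are nested in women, slices in breasts. The default estimator is
method-of-moments from the nested-ANOVA sums of squares. For unbalanced
designs (slice counts differ between breasts) the expected mean squares use
the standard design-derived coefficients

    E[MS_slice]  = σ_s²
    E[MS_breast] = σ_s² + k₁ σ_b²
    E[MS_women]  = σ_s² + k₂ σ_b² + k₃ σ_w²

with k₁–k₃ computed from the group sizes; solving top-down and truncating
negative estimates at zero gives the component estimates. On balanced designs
these reduce to the classical closed forms (verified against hand-computed
mean squares in the tests). An optional REML mode maximizes the restricted
likelihood of the marginal covariance `σ_w² Z_w Z_wᵀ + σ_b² Z_b Z_bᵀ + σ_s² I`
directly (Nelder–Mead over log-variances); it exists as a cross-check and
agrees with method-of-moments on simulated designs to within sampling noise.

Component **shares** divide SDs, not variances: `σ_c / (σ_w + σ_b + σ_s)`.
This is the convention under which the three reported shares sum to 100%,
matching the bundled reference panel, and is the package default
(`share_scale="sd"`; variance shares are available as an option). The label
mapping is: "within breast" = slice-level residual, "between breasts" =
breast-within-woman component. Degenerate genes (zero overall SD) are
returned flagged with NaN shares rather than propagating NaN silently.

### Threshold differential expression

The caller is deliberately non-parametric in the test-statistic sense: the
control (mammaplasty) distribution itself defines per-gene cutoffs —
mean + 3·SD (ddof = 1) for over-expression, the control minimum for
under-expression — and a gene is called when ≥20% of cancers and ≤5% of
controls lie strictly beyond the cutoff. Strict inequality means no control
can fall below the control minimum, so the control condition is automatic in
the under direction; with 28 controls the ≤5% condition in the over direction
admits at most one control (1/28 ≈ 3.6%). Fractions are compared as real
numbers, never rounded to counts. If both directions qualify, the direction
with the larger cancer fraction wins and ties go to over-expression.
Verdicts are invariant to per-gene affine transforms since cutoffs move with
the data, and the implementation is checked verdict-for-verdict against a
brute-force loop oracle on random matrices. No p-values or FDR are attached:
the rule is a prevalence criterion, not a test.

The ratio variant for single-replicate data counts a tumor as differential
beyond control-mean × 1.2 (or ÷ 1.2) and passes genes with >30% of tumors
differential in the majority direction, reporting the signed integer percent.

### Mining cascade

Database records carry subcellular localization labels, a housekeeping flag
and discretized expression levels (absent/low/medium/high; boundaries at 1×,
3× and 10× the median across tissues, closed on the left). Filters, in
cascade order: breast-cancer universe; localization (drop confirmed
nuclear/mitochondrial/ribosomal *unless* also secreted/membrane — a secreted
isoform can reach the blood); housekeeping; high (≥10× median) expression in
any of bone, brain, heart, kidney, lung, liver, skeletal muscle, pancreas
(high-cardiac-output organs that would raise the baseline blood level);
retention of genes at ≤ low in every normal-tissue dataset; then a
secreted/membrane priority partition (non-destructive) and a case-insensitive
union with a literature list. Every filter is a pointwise predicate, so
filters are idempotent and commute (property-tested); missing organ data
passes with a logged note, and an empty normal-tissue map passes with a
warning — the database is sparse by design and absence of data is not
treated as disqualifying. Values below 1× the median map to a configurable
level (`low` by default, `absent` optionally); exact zeros are always
`absent`.

### Clustering

Similarity is Spearman rank correlation (mid-ranks for ties,
pairwise-complete for missing data); linkage is **centroid**: the similarity
between two clusters is the correlation between their mean profiles on the
mean-normalized log2 scale, recomputed after every merge, with merged
centroids weighted by cluster size and NaN-aware. This is the convention of
the classic expression-clustering programs, *not* average pairwise
correlation. Centroid linkage admits inversions (a merge at higher
similarity than its predecessor); these are logged, not fatal. Ties are
broken by the smallest cluster-id pair, which makes output deterministic and
invariant to input permutation up to that rule. The two-cluster cut removes
the root merge; clusters are named by the majority of known cancer vs
mammaplasty members, and each normal category is then counted per cluster.
Items with zero variance have undefined rank correlations; they are flagged
and treated as similarity 0 inside the agglomeration.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions:

* **Nested design**: 10 women × 2 breasts × 3-or-4 slices (mean 3.5), all
  components Gaussian on log2. Default component SDs 0.64 / 0.06 / 0.30
  mirror the reference panel's mean SD shares (64/6/30).
* **Cohort**: 24 cancers, 38 ipsilateral, 3 contralateral, 28 mammaplasty;
  134 genes with 8 inconclusive (emitted all-missing, emulating repeated
  assay failure) and 67 of the 126 evaluable differentially expressed (34
  over / 33 under, 3 log2 units — a strong but realistic qPCR effect),
  measurement noise SD 1 log2 unit. 7/38 ipsilateral and 1/3 contralateral
  normals carry the full cancer profile (the contralateral one representing a
  tissue from a breast with malignancy). Cancers split into two subtypes
  (luminal/basal) whose marker genes (a split of the over-expressed set) are
  shifted ±2 log2 around the cancer effect; outcome events are drawn at 0.6
  probability in the basal group vs 0.05 in the luminal group.
* **Plates**: CT = C₀ − log(truth)/log(efficiency) + noise, with a duplicate
  5-point 1:3 dilution standard (1 … 1/81), three housekeeping genes at
  constant truth, and two replicates per well.
* **Toy gene database**: planted candidates satisfy every cascade filter;
  each non-candidate violates exactly one randomly chosen filter, so the
  cascade's survivor set equals the planted set by construction.

What the generators do **not** emulate: correlated biological structure
among the non-differential genes (normals are exchangeable noise around the
baseline), tumor cellularity gradients, plate-position or primer-efficiency
artifacts, and the long-tailed outlier behavior of real single-replicate
data. Consequently, passing tests demonstrate that the estimators and rules
recover the structure they are designed for; they do not demonstrate
robustness to the full messiness of clinical tissue data. In particular the
1.2-fold ratio rule is permissive at noise SD 1 log2 (noise alone exceeds
1.2-fold routinely), which the driver output makes visible.

## Numerical choices

* Standard curves regress CT on the natural log of dilution; efficiency is
  `exp(−1/slope)`, and linearization anchors the undiluted standard at 1.
  Non-monotone series warn but fit; <3 distinct dilutions or zero slope is an
  error.
* CVs use the n−1 denominator throughout; replicate discordance is flagged
  at CV > 50% (configurable) for re-run.
* Zeros are kept distinct from missing values in linear space; both become
  NaN in log space (with a warning for zeros), so "missing or zero" never
  silently turns into a number.
* Housekeeping normalization requires positive housekeeping values in every
  tissue and names the offending tissue otherwise; averaging precedes
  normalization by default (order configurable).
* Negative variance-component estimates truncate at zero *before* share
  computation.
* The variance-recovery check at 200 women averages estimates over 10
  generator replicates: a single 200-df variance estimate carries ≈10%
  relative sampling error by itself, so a single-replicate 10% check would
  mostly measure luck. Truth SDs (1.0, 0.6, 0.8) keep every component
  estimable at that precision.
* All generator randomness flows through `numpy.random.default_rng(seed)`
  with seeds mandatory in configs; no global state.

## Known limitations

* Centroid/Spearman linkage is implemented O(n³) with a cached similarity
  matrix; fine for hundreds of items, not for thousands.
* The REML mode builds dense n×n covariance matrices; it targets the small
  per-gene designs this analysis uses.
* The cascade treats annotation fields as given; it does not resolve gene
  symbols against nomenclature services, and the toy database is a synthetic
  stand-in, not a reconstruction of any real annotation resource.
* The two-cluster cut is always at the root; finer structure is available
  through the exported tree but no automatic cluster-number selection is
  provided.
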