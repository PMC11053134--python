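# Methods notes

## Model

The pipeline treats a standardized GWAS effect β = B/SE as the unit of
evidence linking a kidney-function lead variant to a secondary trait.
Arranged as a non-negative matrix X (trait-features × variants, |β|
values with each trait split into a "+" and a "−" direction row), the
working assumption is approximately additive, low-rank structure:
X ≈ W·H with W (traits × K) and H (K × variants) non-negative.  Columns
of W and rows of H are *soft* clusters — a variant may load on several
mechanisms — and H's rows double as polygenic-score weights, which is
what makes the factorization clinically actionable.

The directional trait split is a modelling choice: a non-negative
factorization cannot represent signed effects, and splitting each trait
into "increased"/"decreased" features lets opposite-direction clusters
(e.g. increased vs. reduced hematocrit) emerge as separate components
rather than cancel.

## Factorization

* **Updates.** Lee–Seung multiplicative updates for the Frobenius loss,
  denominators guarded by 1e−12.  The loss is non-increasing per
  iteration (asserted in tests on random matrices).
* **Stopping.** A restart stops at `max_iter` (default 10,000) or when
  the relative error improvement stays below `tol` (1e−6) for
  `conv_window` (80) consecutive iterations.  The window semantics
  mirror the convergence-stability setting of established NMF suites.
* **Restarts.** 30 random initializations by default; the restart with
  the lowest final error is reported, all restart errors are kept.
* **Rank selection.** For each K in the scanned range, variants are
  assigned to their argmax cluster on L2-normalized H columns; the mean
  silhouette width (Euclidean) summarizes separation.  A K whose
  solution leaves any cluster empty scores −1 and is effectively
  unselectable.  Selected K maximizes silhouette; ties break by lower
  Frobenius error, then smaller K.  Silhouette construction (argmax
  assignment, normalized columns) is our concrete choice; the metric
  itself is standard.
* **Gauge.** (W·D, D⁻¹·H) leaves W·H unchanged for positive diagonal D;
  we report H at raw multiplicative-update scale and record that choice
  in run metadata rather than imposing a normalization.

## Bayesian NMF with ARD

Half-normal priors on each component's column of W and row of H share a
relevance scale λ_k with an inverse-gamma(a, b) hyperprior; MAP
multiplicative updates with the exact λ update shrink superfluous
components toward zero, and the effective rank is the number of
components whose norm product exceeds 1e−8 of the largest.  Design
points that mattered in practice:

* **Fixed noise variance.** σ² is a parameter (default 1.0), not
  estimated: X entries are z-scores with unit sampling variance by
  construction, and estimating σ² from the residual lets a saturated
  fit disable the prior entirely (no pruning, observed empirically).
* **Scale normalization.** X is internally divided by its mean entry;
  at raw GWAS z-score scale the multiplicative shrinkage of a spurious
  component is O(1e−4) per iteration, which is why unnormalized runs
  need 1e5+ iterations to prune.  With normalization, planted ranks are
  recovered in under 1,000 iterations.
* **Burn-in.** 100 prior-free iterations precede the ARD updates; from
  a cold start the prior term dominates the denominators and collapses
  every component before the fit reaches the data manifold.
* **Hyperpriors.** a = 10, b = √(mean X)·(a−1)/K by default, exposed as
  configuration.  The consensus K over `n_runs` (default 1,000;
  reduced in tests) is the modal effective rank, ties toward smaller K.
* The negative log posterior is non-increasing across iterations
  (asserted in tests); each block update is an exact or majorization
  step for the joint objective.

## Synthetic data: what it emulates, and what it does not

`generate_truth` plants block-diagonal structure: every trait and
variant has one dominant cluster drawn U(1, 2) plus a uniform
cross-loading of 5% of the mean dominant weight, an optional exact-zero
sparsity mask (never a dominant entry), and a per-trait effect
direction.  Both factors are rescaled once so that the smallest entry
of the dense product is β = 6, i.e. every planted association is
genome-wide significant — mirroring the fact that association catalogs
contain only significant hits.  Consequences:

* `generate_association_records` emits a record per nonzero signal
  entry whose realized p = 2·Φ(−|β|) clears a configurable significance
  threshold (default 1e−6, matching the default filter); with the
  threshold at 1.0 every entry is emitted.  p-values are floored at
  1e−300 so extreme z-scores stay representable.  Decoy records each
  violate exactly one filter rule and carry the rule's label.
* With a sparsity mask, a few cross-block entries fall below the
  significance floor and are truncated from X; the noiseless matrix is
  then *approximately* rank K (relative Frobenius floor ≈ 4% in the
  default K = 4 instance).  Exact-recovery assertions therefore use
  sparsity 0.
* Genotypes are Hardy–Weinberg draws with group-specific allele
  frequencies — no linkage disequilibrium between variants, no
  admixture, no relatedness structure beyond what a test injects.
* Phenotypes are linear in the z-scored planted cluster scores with
  Gaussian noise scaled to a target h² (default 0.3; planted per-SD
  effect 0.3 on each cluster's matched quantitative and binary
  phenotype), binary phenotypes threshold the liability at a target
  prevalence (default 0.1), and ICD events obey the two-code Phecode
  rule with a 2% single-code exclusion stratum.  Real EHR phenotypes
  are, of course, not Gaussian-liability-with-known-h²; passing tests
  show the harness recovers what was planted, not that real CKD
  subtypes exist.

## Cohort preparation

* Kinship uses the KING-robust between-family estimator
  φ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i)+N_Aa(j)) restricted to variants
  observed in both individuals; pairs with φ > 0.0884 (the 2nd-degree
  bound 2^(−7/2)) are resolved greedily by repeatedly dropping the
  individual with most flagged partners (ties: lexicographically later
  id).  Greedy resolution is deterministic and O(n²); it does not
  maximize the retained set.  φ is noisy below ~1,000 variants.
* PCA coordinates are the top left singular vectors (orthonormal;
  Gram = I), after MAF ≥ 0.05 filtering, mean imputation, and
  2p/√(2p(1−p)) normalization.  PC signs are fixed by making each PC's
  largest-magnitude variant loading positive.  Note orthonormal
  coordinates rescale by 1/√2 under cohort duplication; only directions
  are duplication-invariant.
* Group assignment is a pluggable `predict_proba` classifier (default:
  random forest, 200 trees).  Tree-vote fractions are not perfectly
  calibrated far from the training clusters; where calibration at the
  decision boundary matters, plug in a calibrated classifier.  The
  optional within-group probability-quantile trimming is off by
  default because its intended target is underdetermined; it is
  exposed as `trim_quantiles`.

## Scores and tests

* cPGS is a weighted dosage *sum* (not a per-variant average): the
  z-scoring step makes the scale irrelevant and the sum keeps exact
  linearity and additivity over variant partitions.  Missing dosages
  are mean-imputed per variant; weighted variants absent from the panel
  are dropped and counted.
* Standardization uses the pooled cohort and sample SD (ddof = 1), so
  sub-cohort comparisons share one z axis.
* Anderson–Darling uses the composite-normality statistic with the
  (1 + 0.75/n + 2.25/n²) small-sample adjustment and Stephens'
  piecewise p approximation (n ≥ 8 required; no installed library
  exposes the p-value, only the statistic).
* Mann–Whitney delegates to the exact enumeration for n_a·n_b ≤ 400
  without ties, else the tie- and continuity-corrected normal
  approximation.
* Top-decile thresholds use the 90th percentile with linear
  interpolation; ties at the threshold are all included.

## PheWAS

Standardization follows refit semantics: variables are z-scored and the
model refitted (outcome and score for linear models; score only for
logistic), so estimates are per 1 SD of cPGS.  Wald-style intervals
come from the fitted information matrix (t-based for OLS).  Binary
traits require ≥ 100 observations *and* ≥ 20 cases — logistic fits with
a handful of cases are meaningless, and the observation-count rule
alone does not prevent them.  Non-converged or separated logistic fits
are flagged, not fatal.  The Bonferroni α = family α / (K·(n_quant +
n_binary)) is recomputed from the actually analyzable trait counts
unless given explicitly.

## Enrichment

The gene universe is the set of mapped genes (closest-gene assignment
is an input file; distance rules and tie-breaks are upstream
knowledge).  GSEA uses the weighted KS statistic with exponent 1, a
gene-label permutation null, NES = ES / mean |null ES| of the same
sign, and a two-sided empirical p with the +1 correction; ORA uses the
hypergeometric upper tail with fold enrichment (k/n)/(K/N).  Both lists
get Benjamini–Hochberg q-values.

## Problem sizes in tests and the acceptance script

Simulations run at 60 trait-features × 120 variants (K = 4), cohorts of
2,000–5,000 individuals, rank scans over K = 2..8 with 4 restarts and
500-iteration caps, and 50 ARD runs at 20,000 iterations — sizes at
which every planted structure is comfortably recoverable and the whole
suite runs in well under a minute of compute per component.  Defaults
in the library itself remain at the full analysis settings (30
restarts, 10,000 iterations, K = 2..20, 1,000 ARD runs).

## Known limitations

* No LD between variants anywhere in the simulator, so LD-aware score
  methods (clumping, shrinkage) are out of scope and untested.
* The silhouette-based rank rule assumes argmax assignment is
  meaningful; heavily overlapping planted structure (cross-loadings
  approaching the dominant scale) would degrade both the rule and the
  Hungarian accuracy metric.
* The PheWAS harness fits one trait at a time; no mixed models, no
  relatedness correction beyond the kinship pre-filter, no
  time-to-event outcomes.
* Curated composite phenotypes are consumed as externally supplied
  binary columns; no curation logic is implemented.
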