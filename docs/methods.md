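# Methods

`omistrat` implements a complete stratification pipeline for a small
longitudinal multi-omics cohort: severe septic-shock patients sampled at day
1 (D1) and day 7 (D7) after shock diagnosis, labeled survivor (S) or
non-survivor (NS) by 28-day mortality. The modeling substrate is the
per-patient **D7/D1 ratio** of every feature — metabolite concentration,
protein abundance, clinical variable — so that each feature expresses a
week of evolution rather than a snapshot. The pipeline is descriptive, not
prognostic: with 17 patients the goal is to identify which features'
temporal variation separates the groups, not to predict mortality in new
patients.

## Synthetic cohorts

No public data accompany this problem, so the package ships a first-class
generator whose defaults *are* the study conditions:

* **Shape.** 9 S + 8 NS patients; 137 metabolites, 132 proteins, 17
  continuous clinical variables; 6 proteomics batches (round-robin patient
  assignment). The metabolite namespace is a realistic 186-analyte targeted
  panel (40 amino acids/biogenic amines, 40 acylcarnitines, 90
  glycerophospholipids, 15 sphingomyelins, 1 hexose), of which a fixed
  137-analyte subset plays the role of the QC-retained panel.
* **Marginals.** Metabolite D1 concentrations are lognormal with
  per-feature log-means uniform on [log 0.05, log 200] µM and log-SD 0.6
  (concentrations are strictly positive, spanning decades). Protein D1
  log2 intensities are Gaussian, base uniform on [12, 18] with SD 0.5,
  matching the scale of typical normalized iTRAQ reporter intensities.
  Clinical variables use their natural scales (e.g. MAP ~ 78 mmHg, lactate
  ~ 3.2 mmol/L) with lognormal coefficients of variation between 0.5 %
  (pH) and 50 % (urine output, platelets).
* **Temporal structure.** D7 = D1 · 2^(δ_f + ε), where δ_f ~ N(0, 0.15) is
  a per-feature drift common to both groups (so within-group D1→D7 trends
  exist for the paired screen to find) and ε is log2-ratio noise with
  SD 0.25.
* **Planted effects.** A planted feature adds a constant shift to the NS
  group's log2 ratio, so E[log2(D7/D1)] differs between groups by exactly
  the stated shift. The reference preset plants ten effects — six
  metabolites (five phosphatidylcholine/sphingomyelin species falling in
  NS, tyrosine rising), three proteins, one clinical variable (MAP falling
  in NS) — each of magnitude 0.75 = 3 × the ratio-noise SD ("3σ").
* **Correlation.** Features share a latent Gaussian factor within
  consecutive blocks of 5, at correlation ρ = 0.5, both at D1 and in the
  ratio noise. This reproduces the strong within-panel correlation of
  lipid species that motivates elastic net over lasso and the redundancy
  term of mRMR. Planted features sit in distinct blocks.
* **Censoring and missingness.** Per-feature LOD is the 5 % quantile of
  the pooled D1/D7 values; values below it are flagged censored (not
  deleted). Missing cells ("non-detectable peaks") are drawn completely at
  random per group. The reference preset sets the missing rate to 0: it
  emulates the *post-QC modeling table*, in which every retained
  metabolite was modeled for all patients, with non-detection represented
  by LOD censoring. The `qc_challenge_cohort` preset instead generates the
  full 186-analyte panel with 49 analytes constructed to fail the filters
  (25 by missingness, 24 by censoring) so the 186→137 funnel is exercised
  with known ground truth.

What the generator does **not** emulate: real inter-metabolite biochemistry
(correlations are block-structured, not pathway-structured), abundance-
dependent non-detection, batch effects on the D7/D1 ratio (batch offsets
are per-patient and cancel in the ratio), or heavy-tailed clinical
outliers. Passing tests therefore demonstrate that the pipeline recovers
the signal structure it assumes — not that it would perform identically on
real plasma data.

## Quality filters

* Metabolites are retained iff (1) the fraction of missing values is
  < 20 % within **every** outcome group, pooling both time points (the
  pooling choice is configurable; the rule is stated per group without
  reference to time points), and (2) ≥ 50 % of all measured concentrations
  lie above the LOD.
* Proteins are retained iff detected in all iTRAQ runs, not a contaminant,
  and quantified with ≥ 2 unique peptides. Raw intensities are
  log2-transformed, and per sample a degree-1 LOESS curve (span 0.75 — no
  span is standard; 0.75 is the classical default) of the sample's
  deviation from the reference is fitted against the reference and
  subtracted. The reference is the per-protein mean log2 intensity across
  all samples of all runs; a single grand-mean scalar is available as an
  alternative (`reference="global_scalar"`).

## Ratios

ratio = D7/D1 per patient per feature. Below-LOD metabolite cells are
imputed at LOD/2 first (a standard targeted-metabolomics convention; the
alternative `drop` leaves them untouched). Features with a missing or zero
denominator are dropped (`zero_denominator`), as are features with missing
numerators (`missingness_rule`) — an outright missing cell, unlike a
censored one, carries no usable value for a ratio. Protein log2
intensities are linearized (2^x) before division so protein ratios are
abundance ratios, commensurate with the other layers.

## Univariate screen

Wilcoxon rank-sum (S vs NS at D1, at D7, and on the ratio) and Wilcoxon
signed-rank (D1 vs D7 within each group; zero differences dropped — the
classical convention, stated because n is tiny). Exact p-values by
enumeration for ≤ 25 untied observations, tie-corrected normal
approximation otherwise. The source texts name the paired test
inconsistently ("Mann-Whitney t-test" vs "sign-rank"); the signed-rank
test is primary because the data are paired. FDR control is
Benjamini–Hochberg (no procedure is named upstream; BH is the default
choice), applied per comparison family per layer (scope configurable), and
significance requires jointly p < 0.05 and q < 0.15.

## mRMR ranking and the integration cascade

Features are discretized to three levels at mean ± 0.5 SD (the
discretization of the original mRMR microarray work). At 17 samples the
alternative ± 1 SD band codes nearly every observation 0 and the class
signal disappears into plug-in MI estimation noise — measured directly:
with ± 1 SD, 3σ planted features score ~0.2 bits against a chance-maximum
of ~0.45 bits over 130 null features. Mutual information is the plug-in
estimate in bits. Greedy mRMR: step 1 maximizes relevance I(f; class);
step t maximizes relevance − mean MI with the selected set (MID, default)
or the quotient form (MIQ). Ties break toward higher relevance, then input
column order, so runs are exactly reproducible. Ranking operates on raw
ratios: the ternary code is location-scale equivariant, so Z-scoring first
would change nothing.

The cascade: tier 1 ranks the metabolite ratios; an independent mRMR run
ranks the proteins; tier 2 re-ranks the pooled top-50 + top-50; tier 3
re-ranks tier 2's top-20 together with all 17 clinical variables.
Shortlists larger than the available features fall back to all features
with a warning.

## Models

All models run on Z-scored ratios (mean/SD fitted on the training rows
only — the leakage-free choice; a `zscore_scope="all"` flag reproduces
normalize-first-then-split), with the cohort split 2/3–1/3 stratified by
outcome (round-half-up per class: 9 S + 8 NS → 6 + 5 train, 3 + 3 test)
and S = 0, NS = 1.

**Elastic net.** Penalized logistic regression, mixing weight α = 0.5,
objective (1/n)·logloss + λ(α‖w‖₁ + (1−α)/2·‖w‖₂²), intercept unpenalized.
The λ grid is 100 geometric values from λ_max (smallest λ zeroing all
slopes, computed from the KKT condition) down by 10⁻⁴. What varies across
the 50 repetitions is the random stratified assignment of CV folds
(default 5, capped at the training class sizes) on the fixed training set;
each repetition accumulates held-out binomial deviance along the path.
Strategy A takes the full-training-path coefficients at the (repetition,
λ) pair of minimal CV deviance; strategy B takes that λ and refits once,
cold-start, on the training set. The two agree up to solver tolerance by
construction; both are reported side by side because the upstream
description distinguishes them. Solver: FISTA proximal gradient with warm
starts along the path; all 250 fold-subproblems are solved as one batched
path over the shared design matrix (row-weight masks), and a subproblem's
path is frozen once it explains 99 % of its null deviance — beyond that
point (near-perfect separation) smaller λ only inflates coefficients
without changing fitted classes. Tolerances: 10⁻⁶ relative coefficient
change inside CV, 10⁻⁸ for the single refits; the solver matches
scikit-learn's saga at fixed λ to ~10⁻⁴.

**LDA.** Pooled within-class covariance with Ledoit–Wolf shrinkage toward
scaled identity by default: with 10 features estimated from 9 within-class
degrees of freedom, the raw (or barely-ridged) covariance produces a
boundary dominated by estimation noise — measured: a 10⁻³ ridge gave
perfect test classification in only 4/20 synthetic cohorts, Ledoit–Wolf in
20/20. Equal priors by default (the midpoint boundary; appropriate for the
unbalanced groups), empirical priors optional. A singular covariance with
shrinkage disabled raises an error suggesting shrinkage.

**PLS-DA.** Class coded −1/+1; each feature centered at the unweighted
average of the two class means ("weighted centering") so the majority
class does not drag the boundary — for balanced classes this is ordinary
centering. Components by NIPALS PLS1 with y-deflation, 3 components
(bounded by min(n_train − 1, k)); prediction by the sign of the regression
score, whose fitted class-mean midpoint is exactly 0 under weighted
centering. VIP_j = √(p · Σ_a w_ja² SSY_a / Σ_a SSY_a) with SSY_a the
response variance captured by component a and ‖w_a‖ = 1, which makes
mean(VIP²) = 1 an exact identity, verified numerically in the tests.

**Consensus.** A feature counts as selected by a model if its coefficient
is nonzero (elastic net, LDA) or its VIP exceeds 1 (PLS-DA). The
comparison table marks membership per model (not-applicable where a
feature never entered the model's tier), rank positions, and sign
consistency across the coefficient-bearing models.

## Problem sizes and verification scale

The test suite and the acceptance script run the full experiment at the
reference shape (17 patients; 137/132/17 features; 50 elastic-net
repetitions; 100-λ paths). The stochastic recovery check uses 20 generator
seeds (0–19); exact-test oracles enumerate all group sizes ≤ 7; the mRMR
oracle check uses 200 random instances with ≤ 8 features; null
calibration uses 1 000 features at the 17-patient shape and 10 000
generator-null rank-sum tests at 80 + 80 patients (large enough that the
discreteness of the rank-sum statistic is below the resolution of a
10 000-sample KS uniformity check; at small n exact p-values are stepwise
super-uniform and no continuous-uniformity test can pass).

Measured behaviour at these conditions (all numbers recomputed by the test
suite): planted features fill on average 54 % / 72 % / 75 % of the tier
1/2/3 top-10 rankings; every model family classifies the 6 held-out
patients perfectly in most seeds (elastic net 18/20, LDA 20/20, PLS-DA
17/20). The PLS-DA count deserves a note: each of its three failing seeds
is a single test patient with a near-zero decision score, the same
patients that sit at probability ≈ 0.5 for the elastic net. Because
features are Z-scored, per-patient separability depends only on the ratio
shift/noise-SD (fixed at 3 by the study conditions), so roughly 10–15 % of
6-patient test sets contain one ambiguous patient regardless of how the
noise scale is chosen; a perfect-classification run on a single test set,
as reported upstream, is entirely consistent with this regime.

## Known limitations

* The proteomics funnel starts at the 132 selected proteins (plus
  evidence-failing extras in tests); the upstream ~3000-protein
  identification stage is out of scope.
* MI estimation at n = 17 is noisy for any discretization; rankings
  beyond the top handful of features are not stable across seeds, which
  is a property of the method at this sample size, not of the
  implementation.
* The elastic-net path freezes after 99 % deviance explained; coefficients
  reported at λ values beyond that point are the frozen ones (the CV
  minimum never falls there).
* `run_pipeline` exercises LOESS normalization on the synthetic protein
  tables by linearizing them first; since generated batch offsets are
  intensity-independent, the LOESS correction is near-constant per sample
  there. The curvature-removal behaviour is exercised directly in the
  tests with injected smooth biases.
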