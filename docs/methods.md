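# Methods

This note records the statistical procedures implemented in `dnamesig`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Data model

A cohort pairs a probe-by-sample matrix of beta values (methylation
fractions in [0, 1], missing allowed) with per-sample clinical annotation:
binary marker status (the phenotype the signature surrogates), treatment
arm (carboplatin / cisplatin / none), survival time in years, a death
indicator, and optional covariates (age, stage, grade, residual disease).
Beta values are validated against [0, 1] (tolerance 1e-9 for round-off),
never clipped — an out-of-range value indicates an upstream processing
error and should fail loudly. Files are TSV, UTF-8, `NA`/empty for
missing, probes as rows by default. Missing beta values are preserved by
I/O and handled by each consumer (per-probe available-case testing in
discovery; per-sample coverage floor in scoring); no imputation anywhere.

## Probe ranking and FDR

Association of each probe with the marker uses Welch's two-sample *t* on
beta values — a robust default for two-group array methylation, tolerant
of unequal group variances; a Wilcoxon rank-sum alternative sits behind a
flag for heavy-tailed probes. Probes with missing values are tested on the
available values when each group retains at least two, otherwise skipped
and logged. Degenerate probes (both group variances zero) get statistic 0
and p = 1 when means agree. FDR is Benjamini–Hochberg step-up over the
tested probes. The ranking sorts by p ascending, breaking ties by |Δ|
descending then probe id lexicographically, so it is fully reproducible.
Betas are tested on their own scale rather than M-values; with planted
mean differences and validated [0, 1] values the variance stabilisation
M-values buy does not change the ranking materially, and raw betas keep
the delta template interpretable as a methylation difference.

## Signature size by cross-validation

Candidate sizes are compared by stratified k-fold cross-validation
(default 10 folds, reduced with a warning if a marker group is smaller):
within each training fold probes are re-ranked from scratch (avoiding
selection bias), the top-k training deltas form the template, held-out
samples are scored by the correlation score, and the per-size criterion is
mean held-out AUC for the marker label — the signature's stated purpose is
to surrogate the marker, so the marker is the natural CV target. The best
size wins; exact ties go to the smallest (cheapest) candidate. The final
signature is refit on the full cohort at the selected size and carries
`fdr_at_size`, the q-value of its last ranked probe. Folds derive from a
single user seed via scikit-learn's stratified splitter.

A consequence of the tie rule worth knowing: when the planted (or real)
signal is strong enough that every candidate size reaches held-out AUC
1.0, the smallest candidate is selected. Recovery of planted truth is
therefore assessed as precision — the fraction of selected probes that are
truly informative — not recall over all planted probes.

## Correlation score and frozen cutoff

The score of sample y is the Pearson correlation between the signature's
delta template Δ and y over the intersection of signature probes with the
sample's non-missing values. Pearson on raw betas keeps the score's sign
interpretable (positive = resembles the marker-positive centroid);
Spearman is available behind a flag. No centring or standardisation of the
profile is needed — correlation is invariant to affine rescaling of either
vector, which is also what makes the score portable across platforms and
batches. Samples covering fewer than `min_coverage` (default 0.8) of the
signature's probes, or fewer than 3, are left unscored; a cohort whose
median coverage falls below the floor raises a platform-mismatch error
rather than silently scoring on a sliver of probes. Cross-platform
transfer (27k-derived signature on 450k data) is by probe-id intersection.

The cutoff is chosen on the discovery cohort from candidate thresholds at
midpoints between consecutive distinct scores plus ±∞ (a sample is called
high when score ≥ threshold), maximising min(sensitivity, specificity) —
the operating point that balances the two targets (defaults 0.8/0.8) —
with ties broken by larger sensitivity + specificity, then by the lower
threshold. The rule is deliberately exhaustive and deterministic; tests
verify it against a brute-force search. The achieved operating point is
stored with the threshold and a warning is logged if it misses the
targets.

## Survival models

Kaplan–Meier estimation, the two-group log-rank test, and Cox
proportional-hazards fits are provided by lifelines behind the module
surface; Cox fits use Efron tie handling (the common default; tests cover
the tie-free case against a direct partial-likelihood maximisation).
Censoring at an event time follows the standard convention (censored
subjects remain at risk for same-time deaths). Constant covariates,
rank-deficient design matrices, and monotone-likelihood non-convergence
raise informative errors rather than returning unstable estimates.
Covariate selection for multivariate models keeps candidates significant
in univariate Cox analysis at alpha = 0.05, dropping candidates observed
in fewer than 80% of samples; each model is complete-case with dropped
rows logged.

The treatment-interaction test compares nested Cox models — marker +
treatment dummies (+ covariates) versus the same plus marker × treatment
products, one per non-reference arm — by likelihood ratio, referred to
chi-square with df = the number of added terms. A marker × treatment cell
with no events makes the interaction inestimable and is reported as an
error naming the cell.

## Meta-analysis and enrichment

Fisher's combined probability test uses −2 Σ ln p_i ~ χ²(2k); a single
p-value round-trips exactly. Contingency tables use Pearson chi-square
without continuity correction with df = (r−1)(c−1); expected counts below
5 warn but do not fail. Category levels labelled "Unknown" are excluded
before testing by default (retainable by passing the full table) — note
that for graded variables the choice matters: a published grade table
reproduces its printed p-value only when the Unknown row is retained
(df = 2), while the binary tables reproduce exactly without it.
Gene-set enrichment is the hypergeometric upper tail on de-duplicated gene
symbols, with the gene set intersected with the declared background first;
multi-gene probes contribute each symbol once.

## Synthetic cohorts

The generator produces the structure the analysis assumes, no more:

- **Betas.** Probe j has baseline mean m_j ~ U(0.2, 0.8) (bounds chosen to
  keep planted shifts away from the [0, 1] boundary); each value is drawn
  from a Beta distribution with that mean and concentration `precision`
  (default 50, giving per-probe noise SD ≈ 0.06 at mid-range — typical of
  good-quality array replicates). A planted subset (default 50 of 2,000
  probes; 2,000 is a desk-scale stand-in for a 27k array) shifts the
  marker-positive group mean by ±delta (default 0.2, half hyper- half
  hypomethylated), reflecting the comparatively large group differences a
  real signature of this kind shows.
- **Survival.** Death times are exponential with hazard
  `baseline_hazard` × HR^(marker), where the HR is arm-specific
  (`hr_marker_by_treatment`, default 3.5 under carboplatin, 1.0
  elsewhere); censoring is independent exponential. Defaults
  (baseline_hazard 0.15/yr, censor_rate 0.08/yr) give median survival
  near 4 years and event fractions around 60–75% at trial-like follow-up,
  in line with advanced ovarian-cancer cohorts. The exponential family
  was chosen for closed-form sanity checks, not as a claim about real
  hazard shapes.
- **Cohort sizes.** Discovery defaults to 35 marker-positive + 28
  marker-negative samples (a realistic single-centre discovery arm);
  treatment allocation defaults to roughly half carboplatin, 40%
  cisplatin, the rest untreated.
- **Shared population.** `population_seed` controls the probe-level
  structure (baselines, planted identities and directions) separately
  from the per-cohort seed: discovery and validation cohorts generated
  with the same `population_seed` share the same underlying biology, as
  two cohorts sampled from one disease population would. Without this, a
  signature discovered in one simulated cohort would carry no signal into
  another — unlike reality.

Not emulated: probe–probe correlation, batch and platform effects, tumour
purity and cell-type composition, copy-number confounding, and
non-proportional hazards. Passing tests therefore demonstrate that the
procedures are correct and well-calibrated under the assumed generative
structure; they do not certify performance on real arrays, where the
unmodelled factors above dominate the error budget.

## Random-signature null

Each draw samples `size` probes uniformly without replacement from the
probes shared by the discovery and evaluation cohorts, rebuilds a
delta-weight signature from the discovery group means, scores the
evaluation cohort, and records |z| of the score coefficient in a
univariate Cox fit. The empirical p is (1 + #{draws ≥ observed}) /
(n_draws + 1), never exactly zero. Draws are size-matched but not
variance-matched. Note the null is conservative in the package's own
simulations: a random draw occasionally includes truly informative
probes, whose large deltas then dominate its template, so null draws are
not pure noise — the observed signature must beat partially informative
competitors.

## Pipeline and reproducibility

The pipeline fans one global seed out to per-stage seeds by hashing
`seed:stage_name` (SHA-256, reduced below 2^31), so adding a stage never
perturbs another stage's stream. All artifacts are plain TSV/JSON written
with sorted keys; the manifest records a SHA-256 per artifact, and
identical configs reproduce identical checksums byte for byte. Default
problem sizes (2,000 probes, discovery ≈ 70 samples, validation ≈ 200,
100 null draws) keep a full run under half a minute on one CPU while
leaving every statistical check well-powered; all sizes are config fields.

## Known limitations

- The Welch-on-betas ranking and Pearson-on-betas score are defaults, not
  the only defensible choices; both have documented alternatives behind
  flags, and the CV machinery would support comparing them.
- Stage/grade/residual disease are consumed as user-encoded categories;
  the package does not impose an encoding.
- Relapse-free survival reuses the same code path with different columns;
  no competing-risks handling.
- The interaction test assumes proportional hazards within each
  marker × arm cell; no diagnostics are provided.
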