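# Methods

This note records the statistical models, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Data model and harmonization

A cohort is a protein × subject abundance matrix (`CohortMatrix`) tagged
with its platform (`mass_spec`, `aptamer`, `pea`) and the scale its values
are on (`raw`, `log2`, `zscore`). Every transformation appends to a
provenance log so the scale flag can be audited. Gene symbol is the
cross-study key; on aptamer platforms, multiple analytes mapping to one
symbol are collapsed by keeping the highest-variance analyte
(deterministic, information-preserving; ties break on analyte id).

The preprocessing pipeline order is fixed:

1. **Missingness filter** — drop proteins missing in strictly more than
   80 % of subjects. The boundary is kept: "more than 80 %" is read as a
   strict inequality, so a protein missing in exactly 8 of 10 subjects
   survives.
2. **Quantile normalization** — every subject column is mapped onto the
   across-column mean of order statistics. Missing entries stay missing
   and are excluded from the reference; columns with fewer observed
   values than the reference grid are matched by quantile interpolation,
   and ties within a column receive the mean of the reference values
   their ranks span. Hand-written because no installed library offers
   column-wise quantile normalization with this missing-data rule.
3. **log2 transform** — requires strictly positive values (after the
   optional pseudocount, default 0); a non-positive cell is an error that
   names the protein and subject rather than silently propagating NaNs.
4. **Optional per-batch median centering** — a deliberately simple batch
   adjustment (subtract each protein's batch median). The original
   per-cohort batch corrections were performed in an external web
   workflow whose algorithm is not recoverable; median centering is the
   documented stand-in and is off by default.
5. **z-scoring** — per protein, within the cohort, using the n−1
   standard deviation. Within-cohort (not pooled) scope was chosen
   because harmonization is defined across cohort matrices: after this
   step every platform's location and gain are gone, which is exactly
   the invariance external validation relies on. The stage is idempotent
   to 1e-9; zero-variance proteins are an error (or dropped explicitly
   with `on_error="drop"`).

A/T biological labels come from threshold rules on CSF biomarker ratios
(`ATRule`): the comparison is strict in the stated direction, so a ratio
exactly at the threshold is negative — boundary handling is not specified
by the classification conventions the rules transcribe, and a strict rule
is the conservative reading. Subjects lacking an input biomarker stay
`unknown`; the classifier is total on complete subjects.

The packaged cohort registry transcribes the demographic table of the
source compilation (per-study n, A/T strata, sex counts, platform);
`summarize_registry` reproduces each printed roll-up (e.g. 759 discovery
subjects, 1,198 validation subjects, 414 discovery A⁺T⁺, 1,227 females
across discovery/validation/differential roles) by summation, with NA
strata contributing zero, which is how the printed totals treat studies
that did not report a stratum.

## Discovery funnel

Per study, differential abundance is mean(case) − mean(control) on log2
data with a two-sided Welch t-test on observed values (pairwise deletion
of missing entries). Welch was chosen over the pooled-variance test
because the source studies never state an equal-variance assumption and
Welch is the safer default; the two differ negligibly at the group sizes
involved. Proteins with fewer than three observed values in a group are
skipped with a warning, mirroring the three-subjects-per-group inclusion
criterion.

The DAP filter keeps |log2 FC| ≥ 0.6 (inclusive — "±0.6" is read as the
boundary of the kept region) and p < 0.05 (strict). Both conventions are
one config flag apart (`lfc_strict`). No per-study multiple-testing
correction is applied: reproducibility across independent studies is the
error control.

Vote counting tallies genes present in the filtered lists of at least
`min_studies` (default 2) studies; each study contributes one sign
(sign of the largest-|FC| analyte if it measured the gene more than
once). The concordance filter keeps tallies whose signs all agree. The
coverage filter keeps candidates measured — post-missingness-filter — in
*every* validation matrix; "measured at all" rather than "measured above
a completeness threshold" is the assumed reading.

Down-selection is not specified by the source workflow beyond "based on
model performance", so a deterministic greedy forward search is used:
candidates are ranked by univariate cross-validated AUC (ties break
alphabetically), added in rank order, and the smallest prefix whose mean
CV AUC is within ε = 0.002 of the best prefix is kept. The full ranking
and prefix trace are stored in the returned signature's notes. A
constant (zero-information) candidate can never change the selection,
because it cannot move any prefix AUC.

## Diagnostic evaluation

Panel scores are linear predictors of an L2-penalized logistic
regression fit on z-scored, cohort-concatenated training data. The ridge
strength is 1e-3 on standardized inputs — small enough to leave
coefficients essentially unpenalized at the sample sizes involved, large
enough to keep the optimum finite and unique under perfect separation,
which makes every fit deterministic. Panel proteins a cohort does not
measure contribute 0 to the score (the mean on the z scale), and the
coverage fraction is recorded on every result, mirroring per-cohort
coverage bookkeeping in signature benchmarking.

AUC is computed by the Mann–Whitney identity (rank form), so it is
exactly the probability a random case outscores a random control with
ties counted one half, and is invariant under monotone transforms of the
score. Confidence intervals default to DeLong's structural-components
variance (implemented from the midrank algorithm; no installed package
provides it), with a seeded percentile bootstrap (2,000 replicates)
available by flag. The operating point maximizes Youden's
J = sensitivity + specificity − 1 over the rule "positive if
score ≥ t" at all observed thresholds; ties break toward higher
specificity.

Two regimes:

- **Repeated CV** (aptamer-platform cohorts): stratified 5-fold, 10
  repeats, folds re-randomized each repeat from a counter-based seed
  scheme (`seed·1000003 + repeat·7919 + 1 mod 2³¹−1`) so runs reproduce
  across platforms. Out-of-fold scores are pooled within each repeat; the
  reported AUC is the mean of per-repeat pooled AUCs (the aggregation
  rule is not stated by the source workflow; the mean is the
  lowest-variance choice, and both the across-repeat normal CI and the
  DeLong CI on pooled scores are emitted).
- **External validation** (mass-spectrometry cohorts): the model is
  fitted on designated training cohorts and frozen; test labels enter
  only at the metric stage, so test-set refitting is impossible by
  construction.

The exploratory separation check runs PCA on subject-wise z-score
vectors and a one-way MANOVA (Pillai's trace with the standard F
approximation) on the top components. With a single component MANOVA
degenerates to one-way ANOVA, where Pillai's trace equals the
between/total sum-of-squares ratio; that reduction is implemented
directly (the general-purpose MANOVA routine requires ≥ 2 responses).

## Prognostic evaluation

Subjects are stratified at the mid-rank sample median of their panel
score: strictly above → high, at or below → low (ties at the median go
low, keeping "high" strictly above the median). When a fitted panel
model exists its linear predictor is the score; otherwise the default is
the mean of member-protein z-scores, direction-aligned by each protein's
discovery sign — the phrase "median protein level values" is ambiguous,
so both modes exist and the mode is flagged in output.

The Cox model is fitted by partial likelihood with Breslow tie handling
(Efron by flag); HR = exp(coefficient), 95 % CI = exp(coef ± 1.96·SE),
two-sided Wald p. Age (centered, years) and sex (female indicator) are
included whenever present and non-constant. When all events fall in one
group the partial likelihood is monotone; the fit falls back to a light
ridge penalty (α = 0.01) with an observed-information Wald SE and a
warning, rather than failing or returning an infinite HR.

Transition datasets are assembled from visit histories: eligible
subjects start at the origin state (CU, or A⁺T⁺ MCI), have ≥ 2 visits
and follow-up within 0.5–12.5 years; the event is the first visit at the
destination state, otherwise censoring at the last visit (censoring at
study end is not assumed because per-subject study-end dates are not in
the data model). Non-monotone state sequences are included with the
first qualifying event, with a warning.

## Clinical association

Per protein × variable: OLS of log2 abundance on the variable plus age
and sex, complete cases only, classical t inference on the variable
term. Benjamini–Hochberg adjustment (step-up, via the standard
multiple-testing routine) is applied per clinical variable across
proteins — matching per-column significance marking in heatmap-style
reporting; the family definition is not stated by the source workflow
and is the package's choice. Collinear designs (e.g. a constant
variable) are flagged and excluded from the BH family rather than
contributing meaningless p-values.

Optional empirical-Bayes variance moderation pools residual variances
across proteins through a scaled inverse-chi-square prior whose
degrees of freedom are moments-matched on the log variances (Newton
inversion of the trigamma function); it adjusts SEs and p-values only,
never betas. It is off by default because the exact moderation settings
of the original workflow are unspecified.

Standardized effects are β·sd(variable)/sd(protein), which reduces to
the Pearson correlation in the bivariate-Gaussian no-covariate case;
standardization is idempotent.

## Benchmarking harness

Signatures are unweighted gene lists; published panels are refit per
cohort regime rather than importing original coefficients, so every cell
of the benchmark table used identical preprocessing, folds, ridge and
seeds. Coverage (count + missing symbols in signature order) is attached
per cell; zero-coverage cells are explicit not-evaluable entries. The
packaged registry holds the discovered 11-protein panel
(CHI3L1, CYCS, DDAH1, GDA, LRRC4B, NPTX2, PKM, SMOC1, SPON1, YWHAG,
YWHAZ) and thirteen published comparators, transcribed with their
original symbols (one registry cell's "DDHA1" is recorded as a typo for
DDAH1; "AT1B1" is kept as printed with a note).

## Synthetic generator

`simulate_cohort` draws log2 abundances Normal(baseline + group·effect,
noise_sd) — baseline per protein ~ N(8, 1) log2 units, the typical
dynamic range of log-intensity data — then applies a platform gain and
offset and masks entries completely at random with per-protein rates ~
Beta(1, 19) (mean 5 % missingness). Cases are labelled A⁺T⁺ and
clinically impaired, controls A⁻T⁻ CU. Planted effects must clear the
0.6 log2-unit detectability floor of the DAP filter, and each group must
have ≥ 3 subjects, mirroring the inclusion criteria. `simulate_multi_study`
plants a shared marker set in every study, flips the sign of a
(1 − concordance) fraction in exactly one randomly chosen study to
exercise the concordance filter, and gives each study private hits that
are disjoint across studies by construction.

`simulate_progression_cohort` draws exponential event times with hazard
λ₀·HR^group·exp(covariate effects) (λ₀ = 0.1 events/year) and uniform
administrative censoring on 0.5–12.5 years, so the true hazard ratio is
controlled in closed form. All generators are pure functions of
(config, seed).

What the generator does **not** emulate: protein–protein correlation,
heavy-tailed or intensity-dependent noise, informative missingness,
batch structure within a cohort, label noise in the A/T assignment, and
time-varying hazards. Passing tests therefore demonstrate that the
pipeline recovers truth under its own assumptions (Gaussian log2 signal,
MCAR missingness, proportional hazards), not that it is robust to every
pathology of real cohort data.

## Problem sizes and tolerances

The test and acceptance workloads use deliberately small problems chosen
to give the statistics enough power while staying quick on one CPU:
discovery recovery uses 8 studies × 300 proteins × 30/arm over 20 seeds
(planted effects ±0.8, noise 0.4 — a ~7.7-sigma per-study t, so recovery
failures indicate bugs, not sampling bad luck); hazard-CI calibration
uses 500 replicates at n = 300; null calibrations use 200 subjects
(CV AUC), 200 seeds (MANOVA uniformity) and 2,000 families (BH).
Numerical tolerances: z-score idempotence and round-trip I/O at 1e-9;
Cox coefficient vs the brute-force partial-likelihood grid at 1e-4 (the
grid's own resolution); oracle identities (AUC, BH, Youden) at 1e-12.

## Known limitations

- The funnel's exact published counts (1,067 → 68 → 41 → 13) require the
  compiled per-study differential tables, which are controlled
  supplementary data; the corresponding check runs only when the user
  supplies them under `data/external/`.
- Real cohort AUCs/HRs require controlled-access cohort data (ADNI,
  PPMI, Synapse) and are out of scope; the package validates behaviour
  on synthetic cohorts with known truth instead.
- Batch correction is a simple median centering, not the original web
  workflow's algorithm.
- No imputation beyond explicit drop; no time-varying covariates,
  competing risks or proportional-hazards diagnostics.
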