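# Methods

This note documents the models implemented in `bccstrat`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Synthetic cohort model

BCC columns are drawn from a block-structured multivariate normal via a
factor construction

    x_v = sqrt(rho_b) * g + sqrt(rho_w - rho_b) * b_{c(v)} + sqrt(1 - rho_w) * e_v

with a global factor g, one factor b_c per cluster and idiosyncratic noise,
giving unit marginal variance, within-block correlation `rho_within`
(default 0.9) and between-block correlation `rho_between` (default 0.1).
The 71 default variables are distributed over 58 blocks as 45 singletons
plus 13 pairs, matching a mostly fine-grained clustering of hematology
panels (e.g. hemoglobin/hematocrit or impedance/optical platelet counts
forming pairs). A log-normal marginal option (`marginal: lognormal`)
exponentiates the Gaussian draws for skewed-marginal studies; defaults stay
Gaussian because the real per-analyte distributions are not published.

Sex shifts: 21 of the 71 variables get a ±0.8 SD mean shift in women
(alternating sign — some analytes run higher in women, e.g. platelet count,
some lower, e.g. hemoglobin). These sizes mirror the scale of sex
differences reported for routine hematology panels.

Outcomes. Recanalization is Bernoulli with

    logit P(success) = alpha + sum_c beta_c(sex) * r_c

where r_c is the standardized cluster mean (theoretical SD used, so the
planted coefficients are per SD) and beta_c(sex) combines a shared term and
a female-only or male-only term. The default pattern plants 13 shared, 12
female-specific and 20 male-specific informative clusters (|beta| 0.3-0.35,
alternating sign), echoing the shared/sex-specific stable-set structure the
pipeline is designed to detect; alpha = 0 puts success near 50%, the rate
typical for TICI 3. Etiology (CE / LAA / UND) is multinomial-logit with
intercepts matching marginals (0.39, 0.34, 0.27) recomputed from the
baseline table, and per-cluster (CE, LAA) coefficients on a dual-signal
subset (3 shared + 12 female-only + 11 male-only clusters at |0.5|).
Covariates are independent Bernoulli draws at baseline-table prevalences
(e.g. hypertension 0.57, IVT 0.34); no joint covariate structure is
claimed. Missingness is MCAR at a configurable rate (default 0), so
complete-case stages stay unbiased in tests.

Report texts embed a TICI mention consistent with the planted label with
probability 1 − `label_noise`; configured fractions carry no mention or two
conflicting grades to exercise the manual-label triage.

What the generator does **not** emulate: realistic reference intervals and
units per analyte, skewed/heavy-tailed marginals by default, instrument
drift, informative missingness, correlated comorbidities, or the referral
patterns behind the real eligibility filter. Passing recovery tests
therefore show that the pipeline's machinery is correct and well calibrated
under its own assumptions — not that the clinical findings of any
particular cohort are reproduced.

## TICI extraction

Grades are matched case-insensitively as `TICI`/`eTICI`/`mTICI` followed by
optional whitespace/hyphen/colon and a grade in {0, 1, 2a, 2b, 2c, 3};
a bare "2" is not in the study's grade set and is ignored. Success is
grade 3 only; 2c counts as failure, following the study's dichotomy rather
than the common 2b+ convention. Repeated identical mentions count as one
grade ("more than one" is read as more than one *distinct* grade); the
alternative reading is flagged in debug logs. Reports with zero or multiple
distinct grades are routed to manual labeling.

## Univariate screen

The between-sex test is Mann–Whitney U (two-sided): laboratory values are
typically skewed and the screen reports medians/IQRs, so a rank test is the
natural default; a Welch t-test sits behind `test="ttest"`. A column that
is constant across all patients gets p = 1 by convention. FDR control is
Benjamini–Hochberg step-up across the screened variables (the field default
for "FDR-corrected"), with significance at q < 0.05. The 2×2 χ² is the
closed form N(ad − bc)² / (r₁r₂c₁c₂) without continuity correction, which
reproduces the published success-by-sex statistic (0.73, p 0.39) exactly.

## Clustering

Distance is 1 − |Spearman ρ| (pairwise-complete), making the partition
invariant to monotone transforms and to the sign of an analyte's scale;
linkage is average, robust for the small tight blocks expected here. The
published account reports an optimal k with a Rand index "similar for men
and women", read here as sex-concordance model selection: for each k in the
grid, women-only and men-only matrices are clustered separately and k
maximizes the adjusted Rand index between the two partitions (ties to the
smallest k); plain Rand and ARI at the chosen k are stored as the
concordance. A bootstrap-stability criterion is available
(`criterion="bootstrap"`) for the alternative reading. Representatives are
means of z-scored members rather than PC1: deterministic sign, exact for
singletons, and near-optimal for blocks of two. Inside cross-validation the
z-scoring constants come from the training fold only.

## Sparse PLS-DA

The in-repo core is the soft-thresholded NIPALS formulation: the weight
update is soft-thresholded to exactly keepX[h] nonzeros (threshold at the
(keep+1)-th largest magnitude, renormalized; exact boundary ties break to
the first index via hard thresholding so the support size stays exact),
iterated to tol 1e-9 (max 500 iterations, warning + best iterate on
non-convergence), followed by regression deflation of X and Y. With keepX
equal to all variables the first weight vector equals the dominant singular
direction of the centered X′Y — the dense-oracle equivalence the tests
assert at 1e-6. Signs are fixed so each weight vector's largest-magnitude
entry is positive, making loading plots reproducible. Prediction defaults
to `max_dist` (argmax of predicted dummy values, the stable two-class
default); centroid and Mahalanobis rules are provided. Ties break to the
first class label (classes ordered by first appearance in the training
labels).

## Repeated CV and stability selection

Stratified K-fold (default 5) repeated R times (default 100); the
per-repeat error is total misclassified over n. keepX is tuned *inside*
each training fold — sequentially per component over the grid
{5, 10, 15, 20, 25, 30} (clamped to the number of variables) by 3-fold
inner CV, ties to the sparsest — so no test-fold information reaches the
tuning or the standardization. Selection frequency of a cluster is the
fraction of all K·R fold-fits whose component-1 weight for that cluster is
nonzero (component 2 is reported but not thresholded); the stable set uses
a strict > 0.9 cutoff. Error distributions are compared with Welch's t and
Welch–Satterthwaite df.

Recovery experiments use scaled problem sizes chosen to exercise the
machinery at study-like dimensions while keeping runs short: five planted
informative clusters (log-odds 0.8 per SD) at n = 300 with R = 25 over 20
replicates for the stability experiments, and the same R = 25 for the
sex-stratification power experiment (female-only effects of 1.0 at the
default 143/190 cohort size).

**Known limitation — false stability under the null.** With zero planted
effects the mean CV error sits at the majority-class rate (0.50), but the
stable set is *not* reliably empty: a dataset's largest chance correlation
(|r| ≈ 0.15 among 58 clusters at n = 300) ranks inside keepX in nearly
every fold-fit, because CV folds of one dataset share 75–80% of their
samples. Empirically only ~25–30% of null datasets yield an empty stable
set at the 0.9 threshold. This matches theory: even ideal
half-sample stability selection bounds the expected number of falsely
stable variables at q²/((2θ−1)p) ≈ 0.5 per dataset for q ≈ 5 selected of
p = 58 at threshold θ = 0.9. Stability selection over resampled folds
controls *selection stability within a dataset*, not dataset-level type-I
error; stable sets should be read accordingly, and the acceptance suite
reports the null clean-fraction so the behavior is measured, not hidden.

## Dual-outcome consistency

The etiology rerun contrasts CE vs LAA only (UND excluded), matching the
two-class direction labels of the published figures; a three-class mode
exists behind `mode="three_class"`. Candidates are restricted per sex to
the recanalization-stable clusters ("previously related to recanalization
success"). Direction labels are the outcome class with the larger median of
the cluster representative; exact ties give "none" and are logged; labels
are invariant to monotone rescaling.

## Adjusted models

Logistic regression by Newton–Raphson/IRLS (deviance tolerance 1e-8, max 50
iterations), covariance from the inverse observed information, 95% Wald
intervals. Quasi-complete separation (|beta| > 15 or a singular information
matrix) raises a named error advising a penalized fit rather than returning
a divergent estimate. Analysis is complete-case — the registry context
makes any imputation model hard to justify, and MCAR test data keep
complete-case estimates unbiased. The cluster representative is
standardized so beta is per SD; negative beta means higher values associate
with unsuccessful recanalization. Covariates default to hypertension,
hyperlipidemia, atrial fibrillation, diabetes, smoking, prior stroke/TIA,
prior MI, antiplatelet use, DOAC use and IVT; age is not included by
default (the covariate list is configurable). Because a log-odds beta and
an odds-ratio CI are easily confused in published tables, effects are
reported on both scales explicitly.

## Pipeline conventions

Eligibility: EVT-not-performed rows are excluded first, then unparseable
timestamps, then panels drawn at/after EVT start, then panels outside the
arrival window — "within 60 min" is read inclusively (≤ 60 retained).
Exclusion tallies always sum to the input row count. All randomness flows
from one master seed through named substreams per stage, and the manifest
records config, seed, row counts and SHA-256 of every artifact, so a rerun
with the same config is byte-identical.
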