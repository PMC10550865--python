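# bccstrat

Sex-stratified analysis of peripheral **blood cell characteristics (BCCs)**
in relation to recanalization success of **endovascular thrombectomy (EVT)**
for acute ischemic stroke — rebuilt as a tested, reusable pipeline driven by
a synthetic cohort generator, so every stage can be validated against
planted ground truth without patient data.

## The problem and the method

EVT outcome is graded on the TICI scale (0, 1, 2a, 2b, 2c, 3); the study
outcome dichotomizes it as success (TICI 3) versus failure (everything
else), with grades text-mined from free-text radiology reports. Hematology
analyzers emit ~71 BCCs per patient (counts, percentages, morphology
indices of leukocytes, erythrocytes, reticulocytes, thrombocytes), many of
them highly collinear, and the question is which of them relate to EVT
success — and whether that differs between women and men.

The seven-step pipeline:

1. **Outcome labels** — rule-based extraction of TICI grades
   (`TICI`/`eTICI`/`mTICI`, any case, optional space/hyphen/colon); reports
   with no mention or more than one distinct grade go to manual labeling.
2. **Univariate sex screen** — Mann–Whitney comparison of each BCC between
   sexes with Benjamini–Hochberg FDR control (q < 0.05), plus Pearson χ²
   for the baseline contingency tables.
3. **Collinearity clustering** — average-linkage hierarchical clustering on
   d(i,j) = 1 − |ρ_Spearman(i,j)|; the number of clusters k maximizes the
   adjusted Rand index between women-only and men-only partitions; each
   cluster is summarized by the mean of its z-scored members.
4. **Sparse PLS-DA** — an in-repo soft-thresholded NIPALS implementation:
   per component h, iterate w ← X′u, soft-threshold to keepX[h] nonzeros,
   t ← Xw, u ← Yq until convergence, then deflate; classes are assigned by
   the maximal predicted dummy value (centroid and Mahalanobis rules
   available).
5. **Stability selection** — stratified 5-fold CV repeated R times (default
   100) with per-fold keepX tuning; a cluster is *stable* when its
   component-1 selection frequency across all K·R fold-fits exceeds 0.9.
   Pooled vs female-only vs male-only error distributions are compared with
   Welch two-sample t-tests.
6. **Dual-outcome consistency** — the stable clusters are re-analyzed with
   stroke etiology (cardioembolism vs large-artery atherosclerosis) as the
   outcome; clusters stable for both outcomes are mapped across sexes, with
   a direction label (the outcome class with the highest median).
7. **Adjusted models** — per-cluster logistic regression (in-house IRLS,
   Wald CIs) of success on the standardized cluster representative,
   adjusting for cardiovascular risk factors, antithrombotics and prior
   intravenous thrombolysis.

The synthetic generator plants all of this structure — block-correlated
BCCs (58 blocks over 71 variables), sex-shifted means, sex-specific
cluster→outcome coefficients, baseline covariate prevalences and report
texts — so recovery is checkable. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

```sh
python analysis/01_simulate.py          # default cohort, seed 17
python analysis/02_extract_tici.py
python analysis/03_screen.py
python analysis/04_cluster.py
python analysis/05_splsda_validation.py # 5-fold CV x 100 repeats
python analysis/06_etiology_consistency.py
python analysis/07_adjusted_models.py
```

Output of the run above (abridged):

```
cohort: 333 patients (143 women, 190 men), 71 BCCs in 58 planted clusters
333 reports: 302 with a unique grade, 14 without a mention, 17 with
conflicting grades -> 31 need manual labeling
agreement with planted labels on clean reports: 100.0% (302 reports)
21 of 71 BCCs sex-different at q < 0.05 (21 of the 21 planted shifts recovered)
optimal number of clusters: 58 (sex-concordance Rand index 1.00)
agreement with the planted partition: ARI = 1.000
pooled: error 0.38 (SD 0.02), 9 of 58 clusters stable (>0.9)
F     : error 0.46 (SD 0.04), 2 of 58 clusters stable (>0.9)
M     : error 0.34 (SD 0.03), 8 of 58 clusters stable (>0.9)
Welch F_vs_pooled: t(160.3) = 20.7, p = 4.4e-47
men: 8 recanalization-stable clusters, 4 also stable for etiology
  cluster_16: beta = 0.53 (95% CI 0.20 to 0.86, p = 0.002) -> higher values
  associate with successful recanalization
```

Reading this: the text miner labeled every clean report correctly and
triaged the rest; the screen found exactly the 21 planted sex shifts; the
clustering recovered the planted 58-block structure and chose k = 58; the
stratified models then diverge by sex because the generator's default
signal pattern is sex-specific, and the adjusted models report per-SD
log-odds for each stable cluster. (Which sex ends up with the lower error
depends on the planted coefficients and sample sizes; the generator's
defaults are not tuned to reproduce any particular dataset's values.)

The same steps run from a shell via the `bcc-strat` CLI
(`simulate`, `tici-extract`, `screen`, `cluster`, `validate`,
`consistency`, `adjust`, `run-all`).

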