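# Methods

This note documents the statistical procedures implemented in `irlncpair`,
their assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## The pair-indicator construction

For an ordered gene pair (A, B) and sample *s* the feature is
`S = 1{expr_A(s) > expr_B(s)}`, with ties scoring 0. Unordered pairs are
enumerated once in lexicographic canonical orientation; a fitted model's
own orientation is preserved separately, and evaluating a model pair on
new samples always recomputes the indicator from expression in the
model's orientation (a flipped stored pair comes back complemented at
non-tied samples). Because the indicator depends only on the within-sample
ordering, the whole downstream model is invariant to per-sample monotone
transforms of expression — the property that motivates pair signatures
for cross-platform use.

A pair is *valid* iff its indicator frequency `freq1` lies strictly in
(`freq_min`, 1 − `freq_min`), default (0.2, 0.8). A pair with `freq1`
near 0 or 1 is quasi-constant and carries no discriminative information;
the two-sided window is the established reading of the one-sided "more
than 20%" phrasing of this construction. `freq1` is computed over the
modeling cohort — tumor samples joined to clinical follow-up — since
those are the samples the signature is fitted on.

## Screening cascade

All screens operate on `log2(x + 1)` expression. The raw input scale
(FPKM/TPM/normalized counts) is deliberately unspecified; the log
transform stabilizes Pearson correlation and the linearity assumption of
Cox covariates, and the pair construction downstream is scale-free anyway.

* **Immune co-expression**: a lncRNA is immune-related iff Pearson r >
  `r_min` (0.5) and p < `corr_p` (0.001) against *at least one* immune
  gene; p from the t transform `t = r sqrt((n−2)/(1−r²))` with n − 2 df.
  The best-correlated partner is recorded.
* **Differential screen**: logFC = mean log2(x+1) in tumor − mean in
  normal; two-sided Wilcoxon rank-sum p; pass iff |logFC| > 2 and
  p < 0.05. The original analysis used moderated (limma) statistics; this
  implementation substitutes the plain fold change + rank-sum test, which
  preserves the screen's contract (thresholded effect size plus p) without
  empirical-Bayes internals. The threshold is applied two-sidedly because
  both under- and over-expressed lncRNAs are meaningful hits.
* **Univariate Cox**: one proportional-hazards fit per lncRNA
  (lifelines, Efron tie handling, Wald CI/p); pass iff p < 0.05.
  Non-converging features are flagged and excluded rather than fatal.
* **Core set**: intersection of the differential and survival screens.

No multiple-testing correction is applied in any screen — the thresholds
are raw p-values by design; the screens are filters, not inference.

## Signature selection

Valid pairs pass a univariate Cox screen on their binary indicator
(p < 0.05), then a repeated cross-validated lasso Cox:

* penalty grid: 100 log-spaced values auto-scaled from the data
  (glmnet-style path, `alpha_min_ratio` 0.01), binary indicators not
  standardized;
* each repeat draws a fresh k-fold split (default 10 folds), scores every
  penalty by mean held-out partial-likelihood deviance (−2 × Breslow
  partial log-likelihood of the test fold), picks the deviance-minimizing
  penalty (λ-min, not 1-SE), refits the full data there, and records the
  nonzero set;
* the final selection keeps features whose selection frequency across
  repeats exceeds `freq_threshold` (default 0.5). The repeat count is the
  procedure's only aggregation knob; the canonical setting is 1000
  repeats, and the tests/acceptance runs use 4–25 repeats, which already
  saturate selection frequencies at these problem sizes.

λ-min is deliberately liberal: on any fixed cohort realization a few
realized-noise features reduce CV deviance and are selected with high
frequency. Across fresh cohorts the *mean* noise-feature selection
frequency stays low (≈0.07–0.25 at n = 400 in our experiments) while
planted features sit at frequency ≈ 1; the frequency threshold plus the
final multivariate fit are the guards against the remaining optimism.

The selected pairs get one joint multivariate Cox fit (Efron ties);
perfectly collinear columns are dropped left-to-right with a warning.
`RiskScore = Σ βᵢ Sᵢ` with the multivariate coefficients. The pair-risk
cohort split uses the Youden-optimal cutoff (sens + spec − 1, ties toward
the smaller cutpoint) on the 5-year ROC; "best cutoff" is operationalized
this way because a ROC-based rule needs an explicit criterion, and Youden
is the standard one. The expression-risk model refits the signature
genes' log2(x+1) expression in a joint Cox model and splits at the median
score. The signature gene set is the exact union of genes appearing in
the selected pairs (for the shipped published tables this union has 17
genes while the published expression model lists an 11-gene subset; the
published reduction rule is unstated, so the package keeps the honest
union).

## Survival evaluation

* **Kaplan–Meier**: direct product-limit implementation
  (`Ŝ(t) = Π (1 − dᵢ/nᵢ)`), written in numpy because the time-dependent
  ROC evaluates thousands of small conditional KM curves; it is
  cross-checked against lifelines in the tests.
* **Log-rank**: lifelines two-group / multivariate tests.
* **Time-dependent ROC** at horizon t (KM-based cumulative-case
  estimator): for cutpoint c,
  `sens = (1 − Ŝ(t|X>c))·P̂(X>c) / (1 − Ŝ(t))` and
  `spec = Ŝ(t|X≤c)·P̂(X≤c) / Ŝ(t)`, clipped to [0,1]; AUC by trapezoid
  over (1−spec, sens) with (0,0)/(1,1) end anchors and FPR ties ordered
  by sensitivity. In the uncensored limit this reduces exactly to the
  empirical confusion-matrix ROC for the outcome {T ≤ t} (tested to
  1e-10). Unlike inverse-probability-of-censoring estimators, conditional
  KM within marker subsets can exceed [0,1] transiently, hence the clip.
* **Clinical association**: chi-square on trait × risk-group contingency
  (no continuity correction, matching the closed-form statistic), plus
  rank-sum (2 trait levels) or Kruskal–Wallis (>2) on the scores.
  Identical-score degenerate inputs return p = 1 by convention.
* **Group comparisons of external per-sample features** (immune
  infiltration fractions, checkpoint expression, IC50): two-sided
  Mann–Whitney rank-sum. The source analysis names the signed-rank test,
  which is undefined for unequal independent groups; the rank-sum test is
  the intended unpaired analogue. Stars at 0.05/0.01/0.001.
* **Independent prognostic analysis**: univariate Cox per covariate and
  one joint multivariate Cox over risk score + available clinical
  ordinals (complete cases; missing covariates are never imputed and are
  excluded pairwise).
* **Four-group analysis**: cross-classification by pair-risk ×
  expression-risk group; KM per subgroup, global and pairwise log-rank;
  empty subgroups are reported but excluded from testing.

Clinical ordinals (stage, T/N/M) are normalized to numeric codes
(I–IV → 1–4, T3 → 3, Tx/Nx/Mx → missing). Follow-up time is carried in a
declared unit (days or years, with a 365.25 d/yr conversion helper) so
the 1/5/10-year ROC horizons are unambiguous.

## Synthetic cohorts

The generator emulates the target study's shape: 473 tumor + 41 normal
samples and a 2,483-gene immune panel by default, with a desk-scale
transcript panel (300 lncRNAs, 3,000 mRNAs — panel sizes are the
package's own choice of a tractable, realistic screen substrate; tests
use smaller panels). Mechanisms:

* log-normal expression: per-gene log2 baseline ~ U(3, 8), unit-variance
  latent factor per mRNA; an immune-coupled lncRNA shares its partner's
  latent factor scaled by `latent_coupling` plus N(0, `noise_sd`²) noise,
  so the population log-scale Pearson r is
  `latent_coupling / sqrt(latent_coupling² + noise_sd²)` — directly
  steerable above or below the 0.5 screen threshold (defaults 0.9/0.5
  give r ≈ 0.87);
* differential lncRNAs add `de_log2fc` (default 3) to tumor samples;
* survival: `T ~ Exponential(rate = h₀·exp(Σ βₖSₖ))` where Sₖ are the
  planted pairs' 0/1 indicators computed exactly as the pair matrix
  defines them; censoring `C ~ U(0, censor_max)`; defaults h₀ = 0.08/yr,
  12-year uniform censoring, three planted pairs with β = (1, −1, 1).
  A Weibull baseline is available behind a switch; Cox estimation is
  baseline-agnostic, so the exponential default suffices for recovery
  tests. Planted-pair members share a log2 baseline so the pair's
  indicator frequency sits near 1/2 (a valid, informative pair);
* clinical covariates (age, stage, T/N/M) are independent noise, which is
  exactly what the risk-vs-covariate ROC comparison assumes.

Everything is driven by one integer seed through independent named
substreams; identical configs give bit-identical cohorts.

What the generator does **not** emulate: negative-binomial count noise,
library-size and batch effects, correlated clinical covariates,
non-proportional hazards, or informative censoring. Passing tests
therefore certify the pipeline's statistical machinery (calibration,
recovery, invariances) under its own assumptions, not performance on real
TCGA data; the published cohort-dependent counts (739 → 377 → 115 → 55 →
11) require the real cohort and are not reproduction targets.

## Numerical choices and degenerate inputs

* Cox fits: lifelines Newton–Raphson with Efron ties; non-convergence in
  *screens* flags the feature (NaN statistics, not passed) and continues;
  in the final multivariate fit it is an error.
* Partial-likelihood deviance for CV uses a Breslow log-likelihood with a
  max-shift guard against overflow (the shift cancels exactly).
* Ties in pair indicators score 0; ties in the Youden index resolve to
  the smaller cutpoint; equal risk scores at the cutoff go to "low"
  (group = high iff score strictly exceeds the cutoff).
* Expression values must be non-negative; duplicate gene/sample IDs,
  non-numeric cells, non-positive follow-up times and unknown event codes
  are rejected with the offending identifier.
* Seeds are combined as `SeedSequence([seed, stream])`; all derived seeds
  stay below 2³¹.

## Test and acceptance problem sizes

Statistical tests use the smallest sizes at which the checked property is
stable: calibration suites run 1000 null replicates (n = 150–300 per
replicate); lasso recovery runs 20 experiments at n = 600 with 25 CV
repeats; the hazard-fidelity check runs 100 replicates at n = 1000.
These sizes are the package's own balance of statistical resolution
against a desk-scale run; the full-size canonical settings (473-sample
cohorts, 1000 lasso repeats) remain the config defaults.

## Known limitations

* The differential screen is not a moderated-statistics replication;
  borderline DE calls can differ from limma on small cohorts.
* λ-min CV lasso over-selects on fixed realizations (see above); users
  wanting sparser signatures should raise `lasso_freq_threshold`.
* The time-dependent ROC estimator is the nearest-neighbour-free KM
  variant; it is consistent but can be noisy at horizons with few events,
  and errors out when no event precedes the horizon.
* Pairing is within-lncRNA only; lncRNA–mRNA pairs and weighted rank
  differences are out of scope.
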