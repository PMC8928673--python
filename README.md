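# irlncpair

Rank-based immune-related lncRNA **pair** signatures for survival
prognosis in bulk tumor cohorts (developed around colon adenocarcinoma),
implemented as a tested, reusable Python pipeline.

## The problem and the method

Expression-based prognostic signatures transfer poorly between platforms
and normalization schemes because they depend on absolute expression
values. A pair signature sidesteps this: for two lncRNAs A and B and a
patient *s*, define the indicator

```
S_{A|B}(s) = 1  if expr_A(s) > expr_B(s),  else 0
```

Only the *within-sample ordering* matters, so the feature matrix is
invariant to any per-sample monotone transform of expression (FPKM vs TPM,
log or not, rank normalization, ...).

The pipeline builds such a signature in five stages:

1. **Screen** — from a genes × samples matrix split into lncRNAs and
   protein-coding mRNAs by GTF biotype, keep lncRNAs that
   (i) co-express with at least one immune-panel gene (Pearson r > 0.5,
   p < 0.001 on log2(x+1) values), (ii) differ between tumor and normal
   samples (|log2FC| > 2, rank-sum p < 0.05), and (iii) pass a univariate
   Cox survival screen (p < 0.05). The core set is the intersection of
   (ii) and (iii).
2. **Pair** — enumerate all k(k−1)/2 unordered core-gene pairs and keep
   the informative ones: pairs whose indicator frequency lies strictly
   inside (0.2, 0.8) across the modeling cohort.
3. **Select** — univariate Cox on each valid pair's indicator, then a
   repeated k-fold cross-validated lasso Cox (`glmnet`-style penalty
   path, penalty chosen by minimum cross-validated partial-likelihood
   deviance, fresh fold split per repeat); features kept when their
   selection frequency across repeats exceeds 0.5.
4. **Fit** — one joint multivariate Cox fit yields the risk formula
   `RiskScore(s) = Σᵢ βᵢ·Sᵢ(s)`. Patients are split into high/low risk at
   the Youden-optimal cutoff of the 5-year time-dependent ROC. A companion
   *expression-risk* model refits the signature genes' log2(x+1)
   expression and splits at the median score.
5. **Evaluate** — Kaplan–Meier curves and log-rank tests, time-dependent
   ROC/AUC at 1/5/10 years (KM-based cumulative-case estimator),
   ROC comparison against clinical covariates, chi-square / rank-test
   clinical-trait association, univariate + multivariate independent
   prognostic Cox, and the four-group analysis crossing pair-risk with
   expression-risk groups.

A fully parameterized synthetic-cohort generator (tumor/normal classes,
immune co-expression structure, differential lncRNAs, survival driven by
planted pair indicators through a proportional-hazards model) makes every
stage testable without any external download.

## Worked example

```python
from irlncpair import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="demo_out", seed=17,
    simulate=dict(n_tumor=300, n_normal=40, n_lnc=60, n_mrna=200,
                  n_immune=100, n_irlnc_true=20, n_de_true=14, seed=17),
    lasso_repeats=5, lasso_folds=4,
)
manifest = run_pipeline(cfg)
```

The structured log mirrors the screening cascade:

```
immune co-expression screen: 20/60 lncRNAs passed (r > 0.5, p < 0.001)
differential screen: 14/20 passed (|logFC| > 2, p < 0.05; 14 up, 0 down)
univariate Cox screen: 6/20 passed (p < 0.05)
core set: 5 genes (DE 14 ∩ risk 6)
pair matrix: 10 candidate pairs from 5 genes; 4 valid (0.2 < freq1 < 0.8)
pair Cox screen: 3/4 pairs passed (p < 0.05)
lasso selection: 3/3 features kept (freq > 0.5 over 5 repeats)
```

and `demo_out/evaluation.json` then reports, for this seed,

```
"5.0": {"auc": 0.780, "optimal_cutoff": 0.311}
"km_logrank": {"chi2": 65.6, "p_value": 5.5e-16, "n_high": 151, "n_low": 149}
"multi_marker_auc": {"risk": 0.780, "age": 0.476, "stage": 0.548, ...}
```

i.e. the fitted pair signature discriminates 5-year survival with
AUC ≈ 0.78 on the simulated cohort, the high-risk group dies markedly
faster (log-rank p ≈ 10⁻¹⁶), and the risk score beats every noise
clinical covariate — exactly the qualitative behavior expected when the
planted pair effects drive the hazard. (Counts and AUCs vary with the
simulation seed; the run is bit-reproducible for a fixed seed.)

The same stages are available as a CLI:

```sh
irlncpair run-all --config cfg.yaml --seed 17 --outdir demo_out
irlncpair verify-tables            # internal consistency of the shipped
                                   # published signature tables
```

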