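# tallsurv

Survival subtyping of T-cell acute lymphoblastic leukemia (T-ALL)
transcriptomes with autoencoder latent features.

T-ALL is highly heterogeneous, and most molecular subtypes are defined
without reference to outcome — so they often fail to stratify survival. This
package implements the opposite strategy: let survival drive the subtyping.
Bulk RNA-seq FPKM profiles (genes × samples) are compressed by a five-layer
autoencoder, the bottleneck features are screened for association with
overall survival, the surviving features are clustered into subgroups, and a
gradient-boosted classifier turns the subgroups into a deployable risk
score. The intended users are computational biologists who have an
expression matrix and a clinical table and want a reproducible,
seed-deterministic subtyping pipeline with honest evaluation machinery.

## Method

Given expression matrix `X` (samples × genes, FPKM):

1. **Transform** — `log2(FPKM + 1)`, then per-gene min–max rescale to
   `[0, 1]`; parameters are frozen on the training cohort and reapplied to
   any external cohort.
2. **Autoencoder** — `d → 500 → 100 → 500 → d`, tanh hidden units, 50%
   dropout during training, 10 epochs of Adam minimising
   `‖X − g(f(X))‖²`; the bottleneck activations `h = f(X) ∈ ℝ¹⁰⁰` are the
   latent features.
3. **Cox screening** — for each latent feature, a univariate Cox
   proportional-hazards score test at `β = 0` (Efron tie handling); features
   with `p < 0.05` are kept. For a binary covariate without ties this score
   test *is* the log-rank test, an identity the test suite verifies to
   1e-6 relative error against an independent implementation.
4. **Clustering** — K-means (k-means++, 10 restarts) on the screened
   features; `K ∈ 2..10` selected by mean silhouette coefficient. Labels
   are oriented so **K1** is the poor-survival subgroup (smaller restricted
   mean survival time up to the latest common follow-up).
5. **Risk score** — features are standardized with training-set mean/SD,
   then an XGBoost classifier (grid-searched under stratified 5-fold CV) is
   fit to the K0/K1 labels; its predicted probability of K1 membership is
   the survival risk score.

Evaluation mirrors the original study design: the cohort is split into 5
near-equal folds, 3 train / 2 test (a 60/40 split), repeated 10 times;
each repetition reports the test-set log-rank p between predicted subgroups
and the time-dependent ROC AUC (IPCW, cumulative cases / dynamic controls)
of the risk score at 3- and 5-year horizons. Two dimension-reduction
baselines (PCA at ≥95% explained variance, and direct gene-level Cox
screening) feed the identical clustering stage for head-to-head comparison.

All survival statistics — Kaplan–Meier, log-rank, univariate Cox,
time-dependent AUC, exact 2×2 Fisher — are implemented in
`tallsurv.survival` and cross-checked in the tests against lifelines,
scikit-survival and scipy.

## Worked example

A synthetic cohort generator (`tallsurv.synthetic`) reproduces the
statistical structure the pipeline assumes — a latent two-subgroup signal in
a block of genes, Weibull survival with a subgroup hazard ratio, calibrated
right censoring, and subgroup-independent clinical covariates — so the whole
pipeline can be exercised without any data download:

```bash
tallsurv simulate --out demo/cohort --seed 7           # 200 samples × 2,000 genes
tallsurv subtype --expression demo/cohort/expression.tsv \
                 --clinical demo/cohort/clinical.tsv \
                 --out demo/run --seed 7
# K=2, 68 screened features -> demo/run
```

The run manifest (`demo/run/manifest.json`) records every stage:

```
n_screened_features = 68          # of 100 latent features, Cox p < 0.05
selected_k = 2                    # silhouette: 0.232 at K=2 vs 0.163 at K=3
subgroup_sizes = {'K0': 117, 'K1': 83}
classifier_best_params = {'max_depth': 2, 'learning_rate': 0.3, 'n_estimators': 50}
```

Of the 100 latent features, 68 carried survival signal; silhouette picked
two subgroups, and the oriented labels recover the planted subgroups with
adjusted Rand index 0.88. Re-applying the persisted bundle to a cohort
(here, the training cohort itself, via `tallsurv validate`) yields

```
{"logrank_p": 3.7e-15, "auc": {"365.25": 0.747, "1095.75": 0.788}}
```

i.e. the predicted K0/K1 split separates survival decisively, and the risk
score discriminates 1-year and 3-year mortality with AUC ≈ 0.75–0.79.
`tallsurv evaluate`, `tallsurv baselines` and `tallsurv clinical` run the
repeated 60/40 evaluation, the PCA / gene-level-Cox baselines, and the
Table-1-style covariate comparison (Fisher exact / rank-sum).

Real cohorts run through the same commands: expression as TSV/CSV
(genes-in-rows or samples-in-rows), clinical tables with `sample_id`,
`time_days`, `event` columns, and an optional two-column gene-ID → symbol
map for `tallsurv.io_preprocess.map_gene_ids`.

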