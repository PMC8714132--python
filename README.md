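# pairrisk

Prognostic risk modelling for bulk tumor transcriptomes from
**relative-ordering lncRNA pairs**, with a complete synthetic-cohort
generator so every stage is testable at desk scale.

## The problem

Gene-expression prognostic signatures built on absolute expression values
are fragile across platforms and batches. A *pair signature* sidesteps
this: for two genes A and B it records only whether A's expression exceeds
B's **within the same sample** (1 if so, else 0). Because the indicator
depends only on the within-sample ordering, it is invariant to any
per-sample monotone normalization — no batch correction is needed when the
model is applied to a new cohort.

`pairrisk` implements this design for autophagy-related long non-coding
RNAs (lncRNAs) in a tumor/normal cohort such as TCGA stomach
adenocarcinoma:

1. **Co-expression screen** — lncRNAs correlated with at least one
   autophagy mRNA (Pearson *r* > 0.6, *p* < 0.001).
2. **Differential expression** — Welch's *t* on log2 values,
   Benjamini–Hochberg FDR < 0.05 and |log2FC| > 2.
3. **Pair matrix** — all C(k,2) ordering indicators over the surviving
   lncRNAs; pairs whose indicator frequency lies outside the inclusive
   [20%, 80%] stability window are near-constant and dropped.
4. **Univariate Cox screen** — one proportional-hazards fit per pair
   indicator (Wald *p* < 0.01).
5. **LASSO-Cox** — L1-penalized partial likelihood by cyclic coordinate
   descent, penalty chosen by 10-fold cross-validated deviance.
6. **Risk model** — unpenalized multivariate Cox refit of the selected
   pairs; per-patient RiskScore

   &nbsp;&nbsp;&nbsp;&nbsp;RiskScore(s) = Σₖ βₖ · 1[exprₐₖ(s) > expr_bₖ(s)]

   with the training-median score as the low/high cutoff.
7. **Evaluation** — Kaplan–Meier curves, the log-rank test, IPCW
   time-dependent ROC/AUC at 1/2/3 years, multi-index ROC against clinical
   covariates, and a univariate/multivariate independence test.
8. **Downstream** — immune-infiltration scoring (mean-z signatures and
   NNLS deconvolution), immune-checkpoint marker comparisons, and ridge
   regression imputation of chemotherapy log-IC50 from cell-line training
   data, all compared between risk groups by the Mann–Whitney rank-sum
   test.

The Cox partial likelihood (Efron/Breslow ties), Newton–Raphson solver,
LASSO coordinate descent, Kaplan–Meier/log-rank machinery, IPCW
time-dependent ROC, BH adjustment, and the exact small-sample rank-sum
path are implemented from first principles in this package and
cross-checked in the tests against lifelines, scikit-survival and scipy.

## Worked example

Generate a synthetic cohort (375 tumors / 32 normals, planted
co-expression, differential expression and three pair hazards) and run the
full pipeline:

```sh
pairrisk simulate --seed 5 --out demo/cohort
pairrisk run --expr demo/cohort/expression.tsv \
             --groups demo/cohort/groups.tsv \
             --annot demo/cohort/annotation.tsv \
             --clinical demo/cohort/clinical.tsv \
             --seed 5 --out demo/results
```

which prints

```
wrote cohort (375 tumor / 32 normal) to demo/cohort
funnel: 90 genes -> 30 edges -> 30 autophagy lncRNAs -> 12 DE -> 66 pairs
        -> 25 stable -> 10 screened -> 6 in model
groups: 191 low / 184 high; log-rank p = 0
```

The funnel line is the stage-wise candidate count (every stage can only
shrink the set). `demo/results/manifest.json` records the run: the six
selected pairs include all three planted ones (`LNC0001|LNC0002`,
`LNC0003|LNC0004`, `LNC0005|LNC0006`), the median-RiskScore cutoff is
0.955, the low/high split is 191/184, the log-rank *p* between predicted
risk groups is below machine precision, and the time-dependent AUCs are
0.797 / 0.859 / 0.859 at 1 / 2 / 3 years — i.e. the model recovers the
planted hazard structure and discriminates survival well beyond chance.
`demo/results/` also contains the edge, DE, pair-frequency, LASSO-path,
model, score, KM and independence tables as TSV.

Each stage is also available separately (`pairrisk screen`, `pairs`,
`fit`, `evaluate`, `downstream`) and as plain library calls
(`pairrisk.run_pipeline`, `pairrisk.fit_cox`, `pairrisk.td_auc`, ...).

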