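# Methods

This note documents the statistical model behind `pairrisk`, the synthetic
cohort it is validated on, the numerical choices, and the limits of what
the tests demonstrate.

## The pair-signature model

Let X be a genes × samples matrix of log2 expression. For an ordered gene
pair (a, b) with a < b lexicographically, the indicator

    I_ab(s) = 1  if X[a, s] > X[b, s],  else 0   (ties score 0)

depends only on the within-sample ordering of the two genes, so it is
invariant under any strictly increasing per-sample transform — per-sample
additive batch offsets, library-size rescaling, rank normalization. This
is the property that lets a fitted pair model transfer across platforms
without batch adjustment, and it is asserted directly by property tests
(random per-sample monotone maps leave the pair matrix bit-identical).

Candidate lncRNAs pass two screens before pairing:

* **Co-expression** with at least one autophagy mRNA: Pearson r > 0.6 and
  two-sided p < 0.001, with p from t = r·√(n−2)/√(1−r²) on t(n−2). The
  screen is on signed r (positive co-expression) by default; |r| is a
  switch. Correlation uses all samples by default (tumor-only is a
  switch).
* **Differential expression** tumor vs normal: Welch's two-sample t on
  log2 values, BH step-up FDR < 0.05 and |log2FC| > 2, with log2FC =
  mean(tumor) − mean(normal) and BH applied across the tested subset only.
  Welch's t is used deliberately instead of a moderated (empirical-Bayes)
  statistic: it is self-contained, exact under the generator's Gaussian
  noise, and directly oracle-checkable; with cohort-scale group sizes the
  moderation would change little.

Pairs whose indicator frequency lies outside the inclusive [0.2, 0.8]
window are near-constant across patients and carry almost no contrast;
they are removed. The window is computed on the modelling cohort (tumor
samples with survival) by default, on all samples optionally. Both bounds
are inclusive — the weaker reading of a "20%–80%" rule, and the
reproducible one.

## Survival modelling

**Cox partial likelihood.** With Efron tie handling, an event time with d
tied deaths (tied set D, risk set R) contributes

    Σ_{i∈D} η_i − Σ_{l=0}^{d−1} log(S_R − (l/d)·S_D),
    S_R = Σ_{j∈R} e^{η_j},  S_D = Σ_{j∈D} e^{η_j},

and Breslow is the l/d → 0 special case. Efron is the default because
day-resolution follow-up data is heavily tied. All risk-set sums are
suffix cumulative sums over samples sorted by time, so each
gradient/Hessian evaluation is O(n) vectorized work. Maximization is
Newton–Raphson with step-halving; convergence at max |score| < 1e-9 or
relative log-likelihood change < 1e-12, at most 100 iterations. Standard
errors come from the inverse observed information. Constant covariates are
held at β = 0 with infinite SE (they carry no information); a singular
information matrix at β = 0 raises a collinearity error; |β| > 20 sets a
complete-separation flag and stops iterating.

**Univariate screen.** One single-covariate fit per stable pair; pairs
with Wald p < 0.01 survive. Pairs constant across the modelled samples are
skipped and reported.

**LASSO-Cox.** Cyclic coordinate descent on −(1/n)·loglik + λ‖β‖₁. Each
coordinate takes a one-dimensional Newton step followed by
soft-thresholding; an active-set strategy with a KKT sweep keeps the cost
near the support size. The grid is 100 log-spaced values from λ_max (the
largest |gradient| of the mean log partial likelihood at β = 0, the
smallest penalty with an all-zero solution) down to 0.01·λ_max, solved
with warm starts. Convergence per λ: max |Δβ| < 1e-7. Cross-validation
uses the Verweij–van Houwelingen partial-likelihood deviance
−2·[ll_all(β̂₋ₖ) − ll₋ₖ(β̂₋ₖ)] with fold assignment a pure function of
(seed, sample order); the selected λ minimizes mean CV deviance
("lambda.min"; a one-SE rule is available).

**Risk model.** The selected pairs are refit by unpenalized multivariate
Cox (optional AIC backward elimination, off by default — the refit is the
package's reading of the "stepwise" step). The RiskScore is the linear
predictor over pair indicators; the low/high cutoff is the **median of
training scores**, frozen and applied unchanged to new cohorts. Scores
exactly at the cutoff go to the low group. The score multiplies
coefficients by the 0/1 pair indicators — the model's actual covariates —
not by raw expression; an expression-weighted variant is out of scope.

**Evaluation.** Kaplan–Meier product-limit curves (censored subjects
remain at risk at their own tied time); the two-group log-rank test from
hypergeometric O/E/V sums; and time-dependent ROC in the
cumulative/dynamic sense: at horizon τ, cases have an observed event by τ,
controls are followed past τ, and subjects censored before τ are removed
with inverse-probability-of-censoring weights 1/G(T⁻) (cases) and 1/G(τ)
(controls), G being the Kaplan–Meier estimate of the censoring
distribution. With no censoring the weighted concordance equals the
Mann–Whitney AUC exactly (asserted to 1e-12). Horizons in years convert at
365.25 days/year. The independence test fits the score alone and the score
plus clinical covariates (listwise-complete); the model counts as an
independent predictor when the multivariate score p < 0.05. Sex is coded
0/1 and grade/stage as ordinal integers throughout.

## Downstream comparisons

Risk-group differences use the two-independent-sample Mann–Whitney
rank-sum test with midranks: exact enumeration of rank arrangements when
min(n₁, n₂) ≤ 8 (and the arrangement count is tractable), otherwise a
tie-corrected, continuity-corrected normal approximation. The exact
two-sided p is the probability of |U − n₁n₂/2| at least as extreme as
observed. A signed-rank test would require paired observations, which two
independent patient groups do not provide — hence rank-sum throughout.

Immune infiltration is summarized by two generic engines rather than the
seven named deconvolution algorithms: (i) mean of gene-wise z-scores over
a marker-gene set, and (ii) nonnegative least squares of each bulk profile
on a user-supplied reference matrix (optionally renormalized to sum to 1).
Published reference matrices are user inputs; tests ship only small
synthetic ones.

Drug response: ridge regression of cell-line log-IC50 on standardized
expression (variance filter, default threshold 0.2 on the normalized log2
scale; penalty by 10-fold CV over a log-spaced grid, minimizing squared
error). Patients are homogenized with the training cohort by gene-wise
quantile normalization whose target is the mean of sorted columns of the
combined matrix; standardization parameters are recomputed from the
homogenized training matrix, so a patient cohort identical to the training
cohort reproduces the fitted values exactly. When only a subset of
training genes is present (at least 50% required), the coefficient vector
is restricted to the shared genes.

## The synthetic cohort

The generator emulates the statistical structure the pipeline assumes:

* **Co-expression**: each linked lncRNA is ρ·z + √(1−ρ²)·ε times its noise
  SD, where z is its partner mRNA's standardized signal — population
  Pearson r exactly ρ (default 0.85).
* **Differential expression**: a subset of linked lncRNAs receives a
  tumor-mean shift of ±de_log2fc (default 3). The partner mRNA receives
  the same shift; otherwise the group-mean offset would attenuate the
  pooled-sample correlation below the screening threshold. Members of a
  planted survival pair always share an identical shift, since an unequal
  shift would drive the pair's ordering frequency toward 0 or 1 and
  silently remove it in the stability filter.
* **Survival**: tumor event times are exponential with hazard
  h₀·exp(Σ βₖ·Iₖ(s)), where Iₖ is the ordering indicator of planted pair k
  computed from the generated expression itself (guaranteeing internal
  consistency with the pairing module). Censoring is an independent
  exponential whose rate is solved by bisection so the expected censored
  fraction equals censor_rate (default 0.3). Exponential forms were chosen
  for their closed-form oracles.
* **Baselines**: lncRNA means are drawn from a narrow band (uniform on
  [4, 6] log2 units, SD = noise_sd = 0.5) so that a realistic fraction of
  pairs has an informative ordering frequency; mRNA means are uniform on
  [4, 9] with unit SD. Clinical covariates (age, sex, grade, stage) are
  generated independent of survival, which is what the independence and
  multi-index ROC calibration checks require.
* **Determinism**: one integer seed; all substreams derive from it via
  seed sequences, so identical specs give bit-identical cohorts.

Defaults (375 tumors / 32 normals, 20 autophagy mRNAs, 30 linked + 40
noise lncRNAs, 12 DE lncRNAs, three planted pairs with β = 1.2 / −1.0 /
1.0) mirror a TCGA-like stomach-cancer design with effect sizes well clear
of the screening thresholds. The parameter-recovery study design used in
the acceptance checks is slightly larger (400 tumors, 24 DE lncRNAs giving
roughly 90 stable candidate pairs) so the LASSO has a meaningful candidate
set; null-calibration replicates run at n = 150 per fit, a size at which
200 replicates complete quickly while the binomial tolerance on a 5% rate
remains informative.

**What passing does and does not show.** The generator plants Gaussian
log-expression, exponential hazards, proportional effects and independent
censoring. Real cohorts violate all four to some degree (heavy-tailed
expression, non-proportional hazards, informative censoring, correlated
clinical covariates), and the generator deliberately omits library-size
and batch structure beyond the additive shifts used in the invariance
tests. Recovery of planted parameters therefore validates the
implementation, not the biological claim; the published real-data numbers
(AUC, median cutoff, funnel counts) depend on a specific data snapshot and
annotation version and are not reproducible from synthetic data.

## Numerical and degenerate-input choices

* Expression ties in a pair score 0 (the literal "otherwise 0" rule) —
  deterministic, and measure-zero under the continuous generator.
* BH step-up maps q-values back to input order and clips at 1.
* r = ±1 yields p = 0 in the correlation test; constant vectors raise.
* The log-rank variance uses the hypergeometric form with the (n−d)/(n−1)
  finite-population factor; a zero total variance returns χ² = 0, p = 1.
* λ grid length 100, λ_min/λ_max = 0.01, coordinate-descent tolerance
  1e-7; the CV fold partition is `rng.permuted(arange(n) % k)`.
* Result tables are written with 12 significant digits; write→read is the
  identity at that precision.
* The run manifest contains only counts, identifiers and rounded
  statistics, serialized with sorted keys, so identical runs are
  byte-identical.

## Known limitations

* No elastic-net mixing, time-varying covariates, stratified Cox, or
  competing risks.
* The IPCW ROC assumes censoring independent of the score within the
  cohort; no covariate-adjusted censoring model.
* NNLS deconvolution and mean-z scores are generic stand-ins for
  published immune deconvolution algorithms; absolute fractions are only
  as good as the supplied reference.
* The drug model is release-agnostic: which cell-line panel and which
  reference matrices to use are the caller's choice.
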