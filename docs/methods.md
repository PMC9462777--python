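# Methods notes

## Model and pipeline

Each analyte (peptide or protein) row y_p of a log2 quantification table is
modelled as a one-way layout over K experimental conditions with cell-means
coding: E[y_pn] = β_pk for sample n in condition k, i.i.d. Gaussian noise.
The design matrix holds one indicator column per condition, so XᵀX =
diag(n_k) and the OLS coefficients are the condition means. This coding is
mandatory internally; arbitrary contrasts cᵀβ are applied at test time, so
XᵀX stays diagonal and the covariance projection below is well defined.

Missing cells are imputed D times with a stochastic engine; the D fits are
pooled with Rubin's rules,

    β̂_p = (1/D) Σ_d β̂_{p,d}
    Σ̂_p = (1/D) Σ_d W_d + (D+1)/(D(D−1)) Σ_d (β̂_{p,d}−β̂_p)ᵀ(β̂_{p,d}−β̂_p),

where W_d = σ̂²_{p,d}(XᵀX)⁻¹ is the within-imputation covariance. D follows
the rule-of-thumb "one draw per percent missing", floored at two
(`choose_num_draws`). A single-draw ensemble is allowed — with a warning
and a zero between-term — because the single-imputation baseline arm is
defined exactly that way.

Downstream testing needs a scalar variance, so the pooled K×K covariance
is projected as

    ŝ²_p = max_k Σ̂_{p,(k,k)} · (XᵀX)_{kk}.

The printed form of this projection is ambiguous about whether the k-th
diagonal covariance element is multiplied or divided by XᵀX. We multiply:
(i) the t-statistic later divides by (XᵀX)⁻¹_{jj}, which requires ŝ² on
residual-variance scale, and (ii) only this reading makes the complete-data
pipeline collapse exactly to the classical moderated t-test (Σ̂_{kk}·n_k =
σ̂²·(1/n_k)·n_k = σ̂²), which the suite asserts to machine precision. The
max over conditions deliberately penalises analytes whose imputed cells
concentrate in one condition.

The projected variances share strength across analytes through the
conjugate hierarchy ŝ²_p | σ²_p ~ σ²_p χ²_{d_p}/d_p, 1/σ²_p ~
χ²_{d₀}/(d₀ s₀²). Hyperparameters are estimated by moment matching on log
variances (trigamma inversion by Newton iteration, tolerance 1e-10): the
excess spread of log ŝ²_p over its chi-square sampling component
identifies d₀; s₀² follows from the digamma relation. Exact-zero variances
(constant rows) are excluded with a warning, since the hierarchy requires
positive scales. When the log variances show no excess spread the prior
degenerates to d₀ = ∞ with s₀² equal to the common scale — we return the
common value exactly rather than the finite-d_p digamma-corrected mean, so
the degenerate case is an exact fixed point. The moderated variance is the
posterior mean (d_p ŝ² + d₀ s₀²)/(d_p + d₀); d₀ adds to the Student
degrees of freedom as a real number (Gaussian tail when d₀ = ∞).
Benjamini–Hochberg step-up control is applied per contrast with π₀ = 1.
The significance threshold α defaults to 0.05 on adjusted p-values —
configurable, since no canonical value is attached to the benchmark
designs. One-vs-one comparisons reuse the variance estimated on the full
design (all conditions); analysing a condition pair in isolation is
possible by subsetting the table before the run.

## Imputation engines

* **mle** — rows are treated as i.i.d. draws of a Gaussian over the sample
  columns; (μ, Σ) fitted by EM (patterns grouped by missingness mask; stop
  when the relative observed-data log-likelihood change < 1e-6, cap 500
  iterations, error on non-convergence; singular blocks get a ridge of
  1e-6·trace/dim with a warning). Missing cells are *drawn* from the
  conditional predictive given the row's observed cells, so repeated draws
  differ. The EM fit is shared across the D draws of an ensemble — the
  data do not change between draws, only the conditional sampling does.
* **knn** — mean of the k (default 10) nearest donor rows under the
  nan-Euclidean metric (scikit-learn's `KNNImputer` does the donor
  search). Plain kNN is deterministic; between-draw variability comes from
  bootstrap-resampling the donor rows, an explicit substitute for the
  unstated stochastic element of repeated-kNN pipelines. Rows with more
  than 50% missing cells fall back to row-mean imputation (logged), the
  conventional guard in existing kNN imputers.
* **norm** — chained equations under the normal model: each incomplete
  column is regressed on all others, the noise variance is drawn from its
  scaled inverse-chi-square posterior and the coefficients from their
  conditional Gaussian (relative ridge 1e-5 on the cross-product diagonal
  stabilises collinearity), and missing entries come from the posterior
  predictive. Ten cycles, column order as in the input, *global* scope —
  this engine models samples across all conditions jointly, matching its
  usual implementation, while every other engine is applied
  condition-wise by default.
* **pca** — iterative low-rank SVD reconstruction (default rank 2) of the
  missing cells; iteration stops when the update is below 1e-5 of the
  imputed-cell norm, or when the per-cell movement falls below 0.1% of the
  current residual RMSE — near-degenerate component pairs otherwise drift
  through a sub-noise limit cycle for thousands of iterations. Gaussian
  noise with sd equal to the residual RMSE is then added to the imputed
  cells so draws differ.
* **rf** — missForest-style loop: each incomplete column is regressed on
  the others with a random forest (default 100 trees) and refilled with
  its predictions; sweeps stop when the normalised change between
  iterations stops decreasing, returning the previous completion. Draw
  stochasticity enters through the forests' seeds.

All engines preserve observed cells exactly and return the input unchanged
when it is complete. Ensembles are bit-reproducible given (method, seed,
D, scope); draw d of an ensemble uses a child RNG stream spawned from the
master seed.

## Peptide-to-protein aggregation

Shared peptides (mapping to more than one protein) are removed first;
aggregation then happens inside each imputed draw, on the raw intensity
scale: protein value = log2 Σ_peptides 2^(log2 intensity). Imputing before
aggregating keeps the protein matrices complete and lets the protein-level
Rubin pooling see the peptide-level imputation spread. All retained
peptides are summed (no top-N selection). For simulated protein-level
benchmarks a protein is truly differential iff its peptides were generated
differential — the generator assigns DE at protein level, so "any" and
"all" conventions coincide.

## Synthetic designs

The generators reproduce the benchmark conditions used throughout the
tests, with ground-truth labels and the complete pre-amputation matrix:

1. **mar1** — fixed-effect one-way ANOVA: 200 analytes × (5+5) samples,
   10 DE rows at condition means (100, 200), all others at 100, noise sd 1.
   The separation is enormous by construction; this design checks that
   sensitivity survives imputation, not that the test is hard.
2. **mar2** — hierarchical ANOVA: 1000 analytes × (10+10); per-row effect
   P_p ~ N(1.5, 0.5), group effect G_pk ~ N(1.5, 0.5) on 200 DE rows (0
   otherwise), noise sd 0.5. P_p is drawn once per row and replicated.
3. **mar3** — same distributions, but P_p and G_pk are redrawn
   independently per cell (random effects): the within-condition variance
   doubles and the linear model is deliberately misspecified.
4. **mnar1/mnar2** — Gaussian log2 intensities with DE means (12.5, 25)
   and sd 2 (1000 analytes/200 DE, or 10000/500); missingness is a mixed
   mechanism: a fraction `mnar_weight` (default 0.5) of the masked cells is
   sampled without replacement with logistic left-censoring weights
   centred at the 10th-percentile intensity (scale 1 log2 unit), the rest
   uniformly. The masked count is exact. The external generator this
   emulates does not publish its internals; the parameters here are
   explicit and exposed on the spec object.

Amputation of complete tables is uniform (exact cell count) by default; a
`covariate_mar` mechanism masks each cell with a logistic probability
driven by the mean of the *other* condition's values in the row (MAR in
the strict sense), with the intercept calibrated by bisection so the
expected proportion hits the target. An optional guard resamples (then
errors after 100 retries) if a row would lose an entire condition.

What the generators do *not* emulate: peptide-to-protein structure in the
analyte-level designs, batch effects, intensity-dependent variance,
correlated peptides within a protein, and the detailed replicate structure
of real LC-MS/MS designs. Passing benchmarks on these designs therefore
demonstrates correct propagation of imputation uncertainty under the
stated models, not performance on any particular real dataset.

## Benchmark harness

`run_benchmark` sweeps (method, proportion, dataset); dataset i uses seed
master+i for generation, amputation and both workflow arms, so the two
arms always see the same incomplete matrix. A dataset on which an arm
calls zero positives is *pathological*: it is flagged, excluded from that
arm's metric means (differences additionally require both arms healthy),
and always reported in the pathological-count table — the reference
results do not state how such datasets entered their summaries, so the
exclusion is our documented choice. Ratios with zero denominators
(e.g. precision with no positive calls) are NaN, never silently zero, and
drop out of summaries pairwise.

Observed outcomes under these conditions, recomputed by
`scripts/acceptance.py` and the acceptance tests rather than stated here:
the script reports design-1 sensitivity, design-2 specificity and the
MCAR+MNAR arm differences at 10–30 datasets per condition; these problem
sizes keep the full recomputation within a few minutes while leaving the
Monte-Carlo error well inside the tolerances the tests assert.

## Known limitations

* The MCAR+MNAR generator is a documented reimplementation of an
  unpublished parameterisation; arm-difference magnitudes on that design
  depend strongly on those internals (see the dispersion of published
  difference distributions) and should be read as properties of *this*
  generator.
* The chained-equations engine is stable under the benchmark conditions;
  it does not reproduce the extreme between-imputation variance (and the
  resulting mass of zero-positive datasets) reported for some global
  normal-model runs elsewhere.
* Multi-factor designs with interactions, robust/trend moderation
  variants, π₀ estimation before BH, and MNAR-devoted hybrid imputation
  are out of scope.
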