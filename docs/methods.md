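# Methods

This note records the modelling choices behind `mipm`: what each stage
assumes, which knobs matter, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## Signal-to-noise weighted voting

The per-gene statistic is `S_i = (μ_p − μ_m)/(σ_p + σ_m)` with class
means and **population** standard deviations (ddof = 0) of normalized
expression; the ddof convention is configurable in principle but fixed
here because the statistic is only used for ranking and voting, both of
which are insensitive to a common rescaling of the denominators. Genes
with `σ_p + σ_m = 0` carry no discriminative information and are assigned
`S_i = 0` and excluded from ranking, which also avoids division by zero.

Two boundary conventions are first-class:

* `boundary_mode="paper"`: `b_i = (μ_p − μ_m)/2`, the half-difference
  form, kept as the default for fidelity to the source description;
* `boundary_mode="midpoint"`: `b_i = (μ_p + μ_m)/2`, the classical
  weighted-voting boundary halfway between the class means.

The two differ materially on library-normalized data, where expression
values are non-negative and typically far from the half-difference of two
class means: with the "paper" boundary the vote sum is dominated by a
class-independent offset, so *accuracy* collapses toward one class while
the *AUC* of the vote sum (a rank statistic) is unaffected. Every
accuracy-bearing analysis in this package therefore states its mode, and
the pipeline runs in midpoint mode; the half-difference form remains
available and is exercised by the oracle-equivalence tests.

Ties in the vote sum (`Σ v_i = 0`) are broken deterministically to
"metastatic" and flagged; they have measure zero on continuous data.
Ranking is by `|S_i|` by default; a sign-balanced variant (half most
positive, half most negative, odd sizes favouring the positive side) is
provided for parity with the classical method.

**LOOCV fast path.** Leave-one-out refitting uses downdated class moments:
with per-class totals `Σx` and `Σx²` precomputed, removing one cell gives
the fold's mean and variance in O(genes) per fold. This is algebraically
identical to naive refitting; floating-point summation order differs, so
continuous vote sums agree to ~1e-12 rather than bitwise, while all
discrete outputs (per-fold calls, accuracies, chosen size) are identical —
the equivalence test asserts exactly that. The naive path is retained as
`fast=False` and serves as its own oracle.

Cross-validation AUC treats "primary" as the positive class and higher
vote sums as more primary-like. The chosen signature size maximizes LOOCV
accuracy, ties resolved to the smaller set. The default candidate grid is
geometric ({10, 25, 50, 100, 250, 500, 1000, 2000, 4000} ∩ available
genes, plus "all"); the grid is a free choice and is configurable.

## Single-cell QC and normalization

Cells are removed when they express fewer than 300 genes (nonzero counts)
**or** exceed 15% mitochondrial counts; both are strict removal
inequalities, so a cell at exactly 300 genes or exactly 15% is kept.
"Expressed" means a nonzero count, the field convention. The
mitochondrial fraction is computed on raw counts over all genes, before
any gene removal, since cell QC precedes gene QC. Gene QC removes
mitochondrial genes, ribosomal genes, genes expressed in fewer than 3
cells, and (when a protein-coding list is supplied) non-coding genes; the
rules commute. Gene categories come from GMT files so synthetic
namespaces work; an `MT-`/`RPL`/`RPS` prefix heuristic is provided as a
convenience.

Normalization is per-cell library-size scaling to 10,000 counts followed
by natural-log `log1p` — the documented default of the standard
single-cell toolchain — with an optional per-gene z-scaling flag.

## ssGSEA and HIRG selection

The single-sample enrichment score walks genes in decreasing expression
order (within-sample average ranks on ties): in-set genes step a
rank-weighted ECDF (weights `rank^α`, α = 0.25), out-of-set genes step an
unweighted ECDF, and the score is the sum of the differences. Scores are
raw running sums without cross-sample normalization: the only downstream
consumer is a within-cohort median split, which is invariant to any
monotone cross-sample transform. A set covering the whole matrix leaves
the out-of-set ECDF undefined; the score is defined as 0 for that
degenerate case. The implementation matches gseapy's `ssgsea`
(rank-normalized, weight 0.25) to numerical precision, which the test
suite checks as an independent cross-check.

The median split assigns "high" only to scores strictly above the median,
so ties go to "low" deterministically. HIRG selection trains a
500-tree random forest (√p features per split, fixed seed) on the
immune-gene submatrix against the high/low labels. Gini importances are
reported as average per-tree impurity decreases **rescaled by the sample
count**, which puts them on the scale of R's `randomForest`
MeanDecreaseGini — the scale on which the customary "> 1" threshold is
meaningful. Because absolute importances remain
implementation-dependent, a scale-free `top_k` selection mode is also
provided.

## Risk model

The Lasso family is the Cox partial likelihood: the outcome is survival
and the coefficients feed a linear hazard score. The penalty grid is 100
log-spaced values spanning four decades below the smallest
all-zero penalty (glmnet convention); folds (default 10) are stratified
by event status with a fixed seed; the chosen penalty minimizes the mean
out-of-fold partial-likelihood deviance (minimum-CV rule, not 1-SE).
Expression is standardized inside the solver and coefficients are
returned on the original log2 scale. All Cox fits use Efron tie handling
(ties are measure-zero in the simulations but the convention matters on
real data). The univariate screen keeps genes with Wald *p* strictly
below 0.05; score and likelihood-ratio tests were the alternatives, Wald
was chosen for its direct CI correspondence.

Risk scores are strictly linear in log2 expression with no intercept and
no re-normalization at scoring time. Missing model genes are an error by
default; an explicit imputation flag substitutes the per-sample mean
expression with a warning. The cutpoint search maximizes the absolute
standardized log-rank statistic over observed score values whose split
leaves at least 10% of the cohort on each side, ties to the lower
cutpoint; group assignment sends scores at or below the cutoff to "low".
Validation cohorts can either reuse a frozen training cutpoint or
re-derive one per cohort; both modes are supported and the pipeline
defaults to freezing.

## Survival evaluation

Times are months; the default horizons are 36 and 60. The horizon ROC
uses the cumulative/dynamic definition — cases have an event by the
horizon, controls have event-free follow-up to it, early-censored samples
are excluded — with Mann–Whitney AUC (ties ½). This estimator was chosen
over KM-weighted variants because it admits an exact brute-force oracle;
it mildly overweights complete follow-up under heavy censoring.
Calibration bins predictions by quantile and compares to within-bin KM at
the horizon (handles censoring; Greenwood 95% bands). Net benefit is
`TP/n − (FP/n)·pt/(1−pt)` with the same horizon case/control rule and n
the evaluable count; treat-all/treat-none references are included. Group
hazard ratios code the risk group as a binary covariate; stage is
dichotomized III/IV vs I/II by default (a 4-level coding is available),
sex is male vs female, age continuous.

The nomogram maps each Cox term's linear-predictor contribution to a
0–100 point scale (the widest-ranging term spans the full scale), rounds
to a configurable resolution (1 point), and maps total points to survival
through the model's Breslow baseline anchored at the covariate means.
Round-tripping against direct Cox prediction agrees to ≤ 0.02 absolute,
the discretization error of the points scale.

The two-group log-rank statistic, KM product-limit curve with Greenwood
variance, and Cox partial log-likelihood evaluator are implemented
in-package (`mipm.stats`) because the cutpoint search and the Lasso CV
need them standalone and vectorizable; each is cross-checked against
lifelines in the test suite.

## Synthetic data: what it emulates, and what it does not

**Single-cell.** Six patients with paired primary/metastatic samples, 100
cancer cells per patient per site, 2000 genes: gamma-Poisson (negative
binomial, dispersion 0.4) UMI counts with log-normal per-gene base means,
multiplicative per-patient effects (log-sd 0.2), and 200 planted site
markers at |log2FC| = 2, half up- and half down-regulated in metastasis
so both vote polarities are exercised. 5% of genes are tagged `MT-`; 5%
of cells are corrupted to violate exactly one QC rule (half to < 300
expressed genes, half to > 15% mitochondrial content). These sizes are a
deliberate desk-scale analogue of a six-patient paired-site study; the
generator does **not** model doublets, ambient RNA, batch chemistry or
copy-number structure, so passing tests certify the statistical machinery,
not robustness to those artifacts.

**Bulk.** Gaussian log2 expression (per-gene means ~N(8, 2), sds
~U(0.5, 1.5)), exponential event times with hazard
`0.01·exp(lp)` per month and independent exponential censoring (rate
0.008, ~45–55% events), where `lp` sums mean-centred planted gene effects,
optional clinical covariate effects, and optionally a latent "immune
activity" factor that loads heterogeneously on immune genes and can carry
its own hazard — the mechanism by which immune genes become genuinely
prognostic and transferable, as in real cohorts. Clinical covariates
follow plausible CRC demographics (age N(67, 10) truncated to [30, 90],
stage I–IV multinomial, sex/chemotherapy Bernoulli); their hazard effects
default to zero so gene-effect recovery tests are not attenuated by Cox
non-collapsibility, and are switched on explicitly where confounding or
nomogram behaviour is under test. A `gene_param_seed` lets independent
cohorts share per-gene baselines and marker identity — without it,
cross-cohort validation of a frozen score is meaningless, since each
cohort would draw unrelated gene-level biology. Proportional hazards hold
exactly by construction; violations are untested territory.

All generators draw from a single seeded RNG per dataset with
deterministically derived sub-streams per component, so identical configs
give byte-identical outputs.

## End-to-end pipeline defaults

The orchestrated study (`mipm.pipeline.run_pipeline`) uses a fixed
signature size of 200 (matching the number of planted markers rather than
the LOOCV-minimal size, so the signature is large enough to intersect the
immune set), embeds the signature genes among 500 bystanders in a
400-sample bulk cohort, defines a 200-gene immune set half-drawn from the
signature, loads the immune program at U(0.3, 1.0) per gene (1.5 on the
four planted prognostic genes, |β| = 0.6 each) with a program hazard of
0.5, and validates on an independent cohort sharing gene-level parameters.
These choices produce training/validation behaviour qualitatively matching
a real multi-cohort study — intersection sets of ~20 genes, validation
hazard ratios of 2–5 — at desk scale.

## Known limitations

* Gene identifiers must match across matrices; no cross-platform mapping.
* No competing risks, time-varying covariates, or elastic-net penalties.
* The absolute Gini-importance scale, and hence the "> 1" HIRG threshold,
  depends on cohort size; use `top_k` when comparing across cohorts.
* The "paper" boundary mode is faithful to its printed form but is not a
  calibrated classifier on non-centred data (see above); choose the mode
  consciously.
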