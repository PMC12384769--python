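# mipm — metastasis-based immune prognostic modelling for colorectal cancer

`mipm` builds and evaluates a **metastasis-based immune prognostic model
(MIPM)** for colorectal cancer: a linear risk score over the log2
expression of a small set of immune-related genes that separate primary
from metastatic cancer cells. It is aimed at computational oncologists who
want the full construction and evaluation chain — from single-cell
classifier to survival validation — as tested, reusable code, exercisable
end to end on bundled synthetic data with planted ground truth.

## The method

**1. Metastasis signature (single-cell arm).** For every gene *i*, a
signal-to-noise statistic separates primary (p) from metastatic (m)
cancer cells:

```
S_i = (μ_p − μ_m) / (σ_p + σ_m)
```

Top-ranked genes form a weighted-voting classifier: a cell *x* receives
per-gene votes `v_i = S_i (g_ix − b_i)` against decision boundaries `b_i`,
and the sign of `Σ v_i` calls the class. Gene-set size is tuned by
leave-one-out cross-validation (highest accuracy); leave-one-patient-out
cross-validation guards against patient-specific artifacts.

**2. Immune gene selection (bulk arm).** Bulk samples are scored against
an immune gene set by single-sample GSEA, split at the cohort median into
high/low immunity, and a random forest ranks immune genes by mean decrease
in Gini impurity; genes above threshold are the high-contribution
immune-related genes (HIRGs).

**3. Risk model.** Signature ∩ HIRGs → univariate Cox screen
(Wald *p* < 0.05) → Lasso-penalized Cox with ten-fold cross-validated
penalty. The resulting score is

```
risk = Σ_i r_i · Exp_i
```

and cohorts are split into high/low risk at a maximally selected log-rank
cutpoint. The published six-gene model ships frozen:

```
risk = 0.077·C5AR1 − 0.141·CCR7 − 0.359·ICOS − 0.191·IL2RB + 0.340·NRP1 + 0.191·VIM,   cutoff −0.17
```

**4. Evaluation.** Kaplan–Meier curves with the log-rank test, hazard
ratios with Wald CIs (uni-/multivariable Cox), 3-/5-year horizon ROC/AUC,
calibration against binned KM estimates, decision-curve net benefit, and a
points-based nomogram; endpoints OS or DFS, with chemotherapy subgroups.

## Worked example

```python
from mipm.pipeline import run_pipeline

res = run_pipeline(seed=1, boundary_mode="midpoint")
print("signature recall:", round(len(set(res.signature.genes) & res.sc_truth.de_gene_ids) / 200, 3))
print("LOOCV peak accuracy:", res.loocv.by_size["accuracy"].max())
print("patient-level AUC:", res.lopo.auc)
print("HIRGs:", int(res.hirgs["selected"].sum()), "| intersection:", len(res.intersection))
val = res.validation_report
print("validation HR:", round(val.hazard_ratio, 2), "log-rank p:", f"{val.logrank_p:.1e}")
print("3yr/5yr AUC:", round(val.auc_by_horizon[36.0], 3), round(val.auc_by_horizon[60.0], 3))
```

prints

```
signature recall: 0.995
LOOCV peak accuracy: 1.0
patient-level AUC: 1.0
HIRGs: 37 | intersection: 20
validation HR: 4.18 log-rank p: 3.0e-19
3yr/5yr AUC: 0.755 0.765
```

Reading: of the 200 planted metastasis markers, 199 are recovered by the
signal-to-noise ranking; the voting classifier separates primary from
metastatic cells perfectly in leave-one-out and leave-one-patient-out CV;
37 immune genes pass the Gini threshold, 20 intersect the signature; and
the Lasso-Cox model fitted on the training cohort stratifies an
*independent* validation cohort into risk groups with a hazard ratio of
4.2 (log-rank p ≈ 1e-19) and 3-/5-year AUCs around 0.76.

There is also a thin CLI mirroring the pipeline stages:

```bash
mipm simulate sc --seed 1 --out sc/
mipm preprocess --counts sc/ --out pre/
mipm signature cv --expr pre/normalized.tsv --annotation pre/annotation.tsv
mipm model score --published --expr expr.tsv --out scores.tsv
mipm evaluate --published --expr expr.tsv --cohort clinical.tsv --out report.json
```

## Layout

| module | contents |
| --- | --- |
| `mipm.simulate` | synthetic single-cell (NB counts, patient blocks, planted markers) and bulk (Gaussian log2, exponential survival) generators |
| `mipm.preprocess` | cell QC (<300 expressed genes, >15% mito), gene QC (mito/ribo/<3 cells/non-coding), library-size log-normalization |
| `mipm.signature` | SNR ranking, weighted voting, LOOCV / leave-one-patient-out CV, signature transfer |
| `mipm.immune` | ssGSEA scoring, median split, random-forest Gini selection |
| `mipm.model` | gene intersection, univariate Cox screen, Lasso-Cox, risk scoring, maximally selected cutpoints, the frozen published model |
| `mipm.evaluate` | KM / log-rank / Cox HRs / horizon ROC / calibration / decision curves / nomograms |
| `mipm.io`, `mipm.cli`, `mipm.pipeline` | text-format IO (MTX/TSV/GMT/JSON), command-line interface, end-to-end orchestration |

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
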