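# dysmark

Paired tumor/normal biomarker evaluation for a dysregulated marker gene:
differential expression on matched pairs, promoter-methylation analysis,
correlated ROC/AUC comparison, marker-quartile survival stratification,
composite immunohistochemistry scoring, and quantification of the
cell-based assays (adhesion, wound healing, invasion, colony formation,
qPCR) that accompany such studies. A synthetic cohort/image generator
with known ground truth makes every stage testable without external
data.

The package is aimed at computational biologists who want the desk
statistics of a tumor-vs-matched-normal biomarker study as tested,
scriptable building blocks rather than spreadsheet/Prism one-offs.

## The statistics at the core

For a marker measured on the same n_pos tumors and n_neg normals, the
empirical AUC is the Mann–Whitney probability that a random tumor
outscores a random normal (ties half-credited), with the Hanley–McNeil
standard error

    SE² = [A(1−A) + (n_pos−1)(Q1−A²) + (n_neg−1)(Q2−A²)] / (n_pos·n_neg),
    Q1 = A/(2−A),  Q2 = 2A²/(1+A).

Two markers on the same subjects give *correlated* AUC estimates, so
their difference is tested with

    z = (AUC₁ − AUC₂) / √(SE₁² + SE₂² − 2·r·SE₁·SE₂),   |z| > 2 ⇒ significant,

where r is the correlation between the two AUC estimates, looked up
from the average Kendall tau-b between the markers, τ̄ = (τ_N + τ_T)/2,
and the average AUC. The bundled r table is computed from an equal-AUC
bivariate binormal model (see `docs/methods.md` for the closed form and
its verification).

Around that sit: paired Wilcoxon/t tests with fold changes and
per-patient overexpression calls; paired-t probe filtering (p < 0.001)
with single-linkage clustering and promoter-region beta aggregation;
Kaplan–Meier + log-rank + Gehan–Breslow–Wilcoxon comparison of top vs
bottom marker quartiles; composite IHC scores (percent category ×
intensity, 1–16) with a staining-vs-diagnosis chi-square; and
ImageJ-style analyze-particles image metrics plus 2^−ΔΔCt qPCR fold
changes.

## Worked example

```python
from dysmark import CohortConfig, generate_cohort
from dysmark.expression import paired_diff_test, overexpression_calls
from dysmark.roc import empirical_auc, compare_auc
from dysmark.survival import survival_strata
from dysmark.pipeline import _promoter_scores

syn = generate_cohort(CohortConfig(seed=7))   # 72 pairs + 88 unpaired tumors

res = paired_diff_test(syn.expression, syn.cohort, "MARKER")
_, n_non = overexpression_calls(syn.expression, syn.cohort, "MARKER")

row = syn.expression.feature("MARKER")
tumors  = syn.expression.samples_where(tissue="tumor")
normals = syn.expression.samples_where(tissue="normal")
auc = empirical_auc(row[tumors], row[normals])

surv = survival_strata(syn.expression, syn.clinical, "MARKER")
```

printing, for seed 7:

```
paired Wilcoxon p = 4.33e-13, fold change = 4.00, non-overexpressing pairs = 5/72
marker mRNA AUC = 0.966 ± 0.011  (n = 160 tumors / 72 normals)
beta-promoter AUC = 0.810 ± 0.036, alpha-promoter AUC = 0.674 ± 0.045
avg Kendall tau = 0.275, r = 0.385, z = 2.989, significant = True
log-rank p = 0.0608, Wilcoxon p = 0.0764, median difference = 1666 days
```

Reading it: the marker is ~4-fold overexpressed in tumors (all but the
5 pairs the generator deliberately made non-overexpressing), and as an
mRNA biomarker it separates tumor from normal with AUC 0.966. Of the
two promoter hypomethylation markers, the beta promoter is the better
biomarker — the correlated z of 2.99 exceeds the |z| > 2 cutoff even
after accounting for the r = 0.385 correlation between the two AUC
estimates. High-marker patients trend toward shorter survival (the
generator's built-in hazard ratio of 2 between extreme quartiles),
with a 1666-day difference in median survival at this seed.

The promoter comparison in the snippet comes from
`compare_auc(beta_scores_tumor, beta_scores_normal, alpha_scores_tumor,
alpha_scores_normal)` on per-sample hypomethylation scores (1 − mean
region beta); see `dysmark/pipeline.py` for the exact call.

## Command line

```sh
dysmark simulate cohort --seed 0 --out cohort/        # synthetic inputs + truth.json
dysmark diffexp  --matrix cohort/expression.tsv --clinical cohort/clinical.tsv \
                 --feature MARKER --mode paired
dysmark roc      --matrix cohort/expression.tsv --clinical cohort/clinical.tsv \
                 --feature MARKER
dysmark survival --matrix cohort/expression.tsv --clinical cohort/clinical.tsv \
                 --feature VIM --pct 25
dysmark run      --seed 0 --out run/                  # full pipeline + MANIFEST
```

`dysmark run` writes per-stage TSVs, a `summary.json` with the headline
numbers, and a `MANIFEST.json` hashing every output; re-running with
the same seed reproduces every hash byte-for-byte.

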