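# Methods

`dysmark` re-implements, as a reusable and tested pipeline, the desk
statistics used to evaluate a dysregulated gene (expression + promoter
methylation + protein) as a tumor biomarker in a paired tumor/normal
cohort, together with the downstream survival stratification, IHC
scoring, and cell-assay quantification that typically accompany such a
study. This note records the models, the defaults and why, and the
choices made where the design was genuinely open.

## Paired and group-wise differential expression

Paired comparisons (tumor vs matched adjacent normal of the same
patient) use the Wilcoxon signed-rank test by default, with the paired t
test available; unpaired comparisons (stage-wise, metastasis) default to
the tie-corrected Mann–Whitney U with Welch's t as the parametric
option. Both nonparametric tests delegate to `scipy.stats` (exact null
distributions for small tie-free samples, tie-corrected asymptotics
otherwise). Fold change is the ratio of group means, kept on the input
abundance scale.

Degenerate inputs follow an explicit convention, since the textbook
statistics are undefined there: all-zero paired differences give p = 1
(no evidence whatsoever), a constant nonzero shift gives p = 0 with a
warning (infinitely strong evidence in the zero-noise limit). The
zero-variance check uses a relative tolerance (`sd ≤ 1e-12 + 1e-9·|mean|`)
so that float summation dust on exactly-constant differences does not
defeat it.

Per-patient overexpression calls use a strict ratio rule: a pair is
overexpressing iff tumor/normal > `min_ratio` (default 1.0). Ties count
as *not* overexpressing. A zero normal with a nonzero tumor is reported
as +inf and called overexpressing, with a logged warning.

## Methylation pipeline

Inputs are 450k-style beta values in [0, 1] with a BED-like probe
annotation carrying a region label (`alpha_promoter`, `beta_promoter`,
`body`, `background`). Probes are abstract features; no Infinium
chemistry, SNP masking, or genome-wide probe geography is modelled.

* **Probe selection** — paired two-sided t-test per probe, vectorized
  over probes; probes with p < 0.001 (configurable) are kept. Probes
  with fewer than 3 complete pairs are excluded and logged. An empty
  selection is a warning, not an error.
* **Clustering** — single-linkage agglomerative clustering
  (`scipy.cluster.hierarchy`, euclidean distance on betas by default,
  1 − Pearson optionally). The merge history is exposed and checked for
  monotone non-decreasing distances on every run (a mathematical
  guarantee of single linkage, asserted as a sanity invariant). Missing
  betas are imputed per-probe by the cohort median first — the simplest
  defensible rule. The distance and linkage software of the original
  analysis are unstated anywhere we could check, so euclidean + betas is
  an explicit assumption, flagged here.
* **Region aggregation** — per region, the mean over probes of the mean
  over pairs of (tumor − normal) beta; direction `hypo` iff negative.
* **Methylation–expression correlation** — Pearson r with the
  t-transform p-value. Expression is log2(x+1)-transformed by default:
  normalized RNA-Seq abundances are approximately log-normal, so the
  linear association of interest lives on the log scale; the flag
  `log2_expression=False` gives the raw-scale correlation.

## ROC and the correlated-AUC comparison

The empirical AUC is computed via midranks and equals the Mann–Whitney
U statistic divided by n_pos·n_neg (ties half-credited); this identity
is tested exhaustively. Positives are tumors by convention, and a
marker with AUC < 0.5 is reported as-is (no auto-flip). Promoter
methylation markers are oriented as *hypomethylation scores*
(1 − mean beta over the region's probes) so that tumors, which lose
promoter methylation, score high.

Each AUC gets the Hanley–McNeil (1982) standard error

    SE² = [A(1−A) + (n_pos−1)(Q1−A²) + (n_neg−1)(Q2−A²)] / (n_pos·n_neg),
    Q1 = A/(2−A),  Q2 = 2A²/(1+A).

Two markers measured on the same subjects are compared with

    z = (AUC1 − AUC2) / sqrt(SE1² + SE2² − 2·r·SE1·SE2),

with |z| > 2 called significant. The coefficient r — the correlation
between the two AUC estimates induced by measuring both markers on the
same subjects — is looked up from the average Kendall tau-b between the
markers (within negatives and within positives, averaged) and the
average AUC.

**The r table.** `data/hm_r_table.tsv` is a computed table, not a scan
transcription: it tabulates corr(Â1, Â2) under an equal-AUC bivariate
binormal model in the equal-group-size asymptotic limit,

    r(τ, A) = [Φ₂(b, b; ρ/2) − A²] / [Φ₂(b, b; ½) − A²],
    b = Φ⁻¹(A),  ρ = sin(πτ/2),

where Φ₂ is the bivariate normal CDF and Greiner's relation maps the
observed Kendall tau to the latent Pearson correlation. The generating
closed form ships in the package (`roc.binormal_auc_correlation`) and
the tests verify the table against it at grid points, its monotonicity
in τ, and its endpoints (r→0 as τ→0, r→1 as τ→1). Queries are
bilinearly interpolated; AUC < 0.5 is reflected to 1−AUC, negative
average tau floors r at 0, and out-of-range queries clamp to the table
boundary with a warning. `r_mode="avg_tau"` (r = τ̄ directly) is
available as a sensitivity alternative.

A widely printed version of this z formula omits the radical and
flips signs in the denominator; that is a typographical casualty, and
the canonical form above is what is implemented.

When a marker is compared against itself the denominator is 0 together
with the numerator; this is reported as z = 0 (not significant) rather
than an error. A zero denominator with a nonzero AUC difference is a
degenerate-comparison error.

## Survival stratification

Patients are ranked by a numeric marker (tumor-sample value); the top
and bottom 25th percentiles (configurable) form the high/low groups.
Percentiles are nearest-rank, and ties at the boundary value are
included in the group (groups can exceed n/4; logged). All marker
values identical is a degenerate-stratification error. Patients missing
survival time or vital status are dropped with a logged count.

Kaplan–Meier estimation, the log-rank (Mantel–Cox) test and the
Gehan–Breslow–Wilcoxon test (log-rank weighted by n at risk, so early
differences count more) delegate to `lifelines`. The median survival is
the earliest time with S(t) ≤ 0.5, undefined (NaN) if never reached;
the headline effect size is |median_high − median_low|, undefined if
either median is. P-values are two-sided via chi-square with 1 df. No
Cox regression or multivariable adjustment is attempted.

## IHC scoring

Each micro-section gets a percent-stained category (<10% → 1,
[10, 35) → 2, [35, 60] → 3, >60% → 4) and a pathologist intensity
category 1–4; the composite is their product (1–16). Only the outer
percent bounds are standard; the interior cut-points 35/60 are a
package default and configurable. Two pathologists' intensity columns,
if present, are averaged and rounded half-up.

Staining vs diagnosis association is a Pearson chi-square without
continuity correction (a Yates-corrected variant exists). The
dichotomization of "stained" is a parameter (`composite_gt_1` default,
`any_staining`, `composite_gt_k`) because no single convention is
canonical. Stage/grade-wise composite comparisons are pairwise
Mann–Whitney tests.

## Assay quantification

Image metrics follow the ImageJ analyze-particles workflow: Otsu
threshold (fixed-value optionally), 8-connected components (the ImageJ
default; 4-connectivity available), per-particle pixel areas scaled by
microns_per_pixel² (default 1 µm/px, matching 4× 1280×960 acquisition).
Total particle area plus unoccupied intercellular space equals the
image area exactly — a bookkeeping identity the tests enforce.

Wound healing: one threshold is derived from the baseline image and
applied to every timepoint (so a fully healed, uniform follow-up is
still scored); the wound is the largest cell-free connected component;
the readout is wound_area(t)/wound_area(baseline), floored at 0. The
original workflow detected "migrating edges"; the largest-background-
component rule is an approximation with the same normalized endpoint.
Replicate fields are aggregated by mean.

ΔΔCt: fold = 2^−ΔΔCt with amplification efficiency fixed at 2.0;
replicate Cts are averaged on the Ct scale and SEMs combined in
quadrature on the log2 scale. `normalize_to_control` (value / control
mean, ×100 optionally) serves invasion counts, resazurin fluorescence,
colony metrics, and Western densitometry ratios alike.

## The synthetic cohort generator

The generator defines the study conditions the tests assume; its
defaults are fixed once and are not tuning knobs.

* **Cohort size** — 72 matched pairs plus 88 unpaired tumors (a
  several-hundred-tumor cohort with a ~70-pair matched subset is the
  typical shape of such a study); methylation covers the paired samples
  only.
* **Expression** — per-patient baseline log2 abundance ~ N(8, σ²) with
  σ = `noise_sd_expr` = 0.5; the tumor adds the gene's log2 fold change
  plus independent N(0, σ²) noise (log-normal multiplicative noise on
  the abundance scale). The marker defaults to log2FC = 2; two isoform
  rows track it, an EMT panel (VIM +1, CDH2 +0.7, CDH1 −1) and 20 null
  background genes round out the matrix. A designated fraction of pairs
  (5/72 by default) receives the *negated* fold change, making them
  non-overexpressing by construction (exactly so in the zero-noise
  limit). Tumors of metastatic patients get an extra ×1.3 on the
  marker. Stage frequencies default to (0.50, 0.11, 0.23, 0.16) for
  I–IV; metastasis is stage IV.
* **Methylation** — probe baselines ~ U(0.40, 0.70), Gaussian beta
  noise (sd 0.05) plus a small global per-sample offset (sd 0.02,
  emulating purity/composition, which also induces the positive
  between-region score correlation the correlated-AUC stage consumes),
  clipped to [0, 1]. Promoter probes in tumors shift by
  `delta_beta_promoter` (−0.15) on average; one alpha-promoter probe
  runs against the trend (+|δ|/3, the hypermethylated sub-region seen
  in practice) with the others compensating so the region mean is
  exactly δ. Per-patient, region-level random effects (sd 0.12 for the
  beta region, 2× for alpha, sharing a common factor) make tumors
  heterogeneous in methylation loss; the alpha promoter is thereby the
  markedly weaker biomarker. Much larger effect sds would push betas
  into the [0,1] clip and bias the region means, which is why the
  defaults stop where they do.
* **Methylation–expression coupling** — with z the standardized log2
  marker expression and ε an independent standard normal, the
  designated body probe's beta is
  0.5 + c·(ρ·z + √(1−ρ²)·ε), c = 0.08, ρ = `meth_expr_corr_target`
  (−0.25), giving Pearson correlation ρ with log2 expression in
  expectation (clipping is negligible at c = 0.08). The target is
  defined on the log2-expression scale, matching the pipeline's default
  correlation transform.
* **Survival** — exponential with quartile-dependent rate
  λ_q = ln2/1500 d⁻¹ · HR^(q/3), q = 0..3 the marker quartile, HR = 2
  between extreme quartiles. With probability `censor_rate` (0.6) the
  time is replaced by a uniform draw below the death time (dropout
  censoring); times beyond a 10-year horizon are administratively
  censored. The realized censoring fraction therefore approximates,
  not exactly equals, `censor_rate`.
* **IHC tables** — per-stratum categorical distributions over
  (percent category, intensity) whose expected composite products put
  tumors at ≈2× normal sections, with stage II+ above stage I; section
  counts default to a 192-section microarray (20 normal, 64/76/30/2
  stage I–IV).
* **Assay images** — bright disks (16-bit fg 40000, bg 5000, Gaussian
  noise sd 1500) on 1280×960 frames by default: overlapping disks for
  cell fields, a central dark stripe for wound pairs (follow-up width =
  `remaining_frac` × baseline), disjoint jittered-grid disks for colony
  plates (integer centers, so same-radius colonies rasterize to
  identical pixel areas). Ground truth records occupied/wound/colony
  pixel areas from the noiseless mask.
* **Determinism** — one global seed; sub-generators (expression,
  methylation, clinical, images) derive child streams via
  `numpy.random.SeedSequence.spawn`, so adding an output stream cannot
  perturb existing ones. Identical config ⇒ bit-identical output.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: genome-wide probe geography and Infinium
chemistry; count-level RNA-Seq noise (abundances are ideal log-normal);
non-proportional or time-varying hazards; informative censoring;
batch/plate effects; inter-pathologist disagreement beyond a simple
average; uneven illumination, debris or focus artifacts in images.
Recovery results certify the statistics, not robustness to those
real-data pathologies.

## Problem sizes used in the checks

The statistical acceptance checks run at sizes chosen to make their
Monte-Carlo error comfortably smaller than the tolerance being checked:
1000 enumerated AUC configurations; 200 replicates at n=200/200 for the
correlated-z size/power; 500 binormal replicates per AUC for the SE
check; 200 cohorts × 100 null probes for the filter's type-I error
(tolerance ±4 binomial SDs around 0.001); 500 random 6–10-point
instances against the clustering oracle; 20–100 seeded cohorts for
parameter recovery (log2FC within 3 MC-SEs, promoter δβ within ±0.02 on
the across-seed mean, correlation within ±0.08, hazard ordering in
≥95/100 seeds); 500 null replicates for log-rank size in [0.03, 0.07].

## Known limitations

* The r table assumes equal AUCs, equal group sizes and binormal scores;
  for very unequal designs the interpolated r is an approximation (the
  `avg_tau` mode brackets the sensitivity).
* The Hanley–McNeil SE is an approximation built on exponential-model
  Q1/Q2; the tests show it tracks the binormal sampling SD within ~3%
  at n=50/50, but it is not the DeLong estimator (deliberately out of
  scope).
* Wound detection by largest background component fails on images whose
  largest cell-free region is not the wound (e.g. sparse monolayers).
* `percentile_groups` can return overlapping groups when pct = 50 and
  the two boundary values coincide; it errors only when all values tie.
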