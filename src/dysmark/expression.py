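"""Paired and group-wise differential expression and per-patient
overexpression calls.

The paired route compares each patient's tumor against the matched adjacent
normal (Wilcoxon signed-rank by default, paired t available); the group
route compares arbitrary sample sets (tie-corrected Mann–Whitney by default,
Welch t available).  Fold changes are ratios of group means, so they stay on
the abundance scale the input matrix uses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError
from .matrix import FeatureMatrix, PairedCohort, paired_values

log = logging.getLogger(__name__)

PAIRED_METHODS = ("paired_t", "wilcoxon_signed_rank")
GROUP_METHODS = ("mann_whitney", "t_test")


@dataclass
class DiffResult:
    feature_id: str
    statistic: float
    p_value: float
    fold_change: float
    n_used: int
    method: str


def _fold_change(numer: np.ndarray, denom: np.ndarray) -> float:
    dm = float(np.mean(denom))
    nm = float(np.mean(numer))
    if dm == 0.0:
        return float("inf") if nm > 0 else float("nan")
    return nm / dm


def paired_diff_test(
    matrix: FeatureMatrix,
    cohort: PairedCohort,
    feature_id: str,
    method: str = "wilcoxon_signed_rank",
) -> DiffResult:
    """Two-sided paired test of tumor vs matched normal for one feature.

    Pairs with a missing value are dropped (``n_used`` reports the
    remainder).  Zero-variance differences are handled by convention:
    all-zero differences give p=1, a constant nonzero shift gives p=0 with
    a degenerate-data warning (the textbook statistic is undefined).
    """
    if method not in PAIRED_METHODS:
        raise ValueError(f"method must be one of {PAIRED_METHODS}")
    tumor, normal, kept = paired_values(matrix, cohort, feature_id)
    if len(kept) < 3:
        raise InsufficientDataError(
            f"{feature_id}: only {len(kept)} complete pairs (need >= 3)"
        )
    diffs = tumor - normal
    fold = _fold_change(tumor, normal)

    mean_d, sd_d = float(np.mean(diffs)), float(np.std(diffs))
    if sd_d <= 1e-12 + 1e-9 * abs(mean_d):  # constant differences (within
        # float summation dust)
        if abs(mean_d) <= 1e-12:
            return DiffResult(feature_id, 0.0, 1.0, fold, len(kept), method)
        warnings.warn(
            f"{feature_id}: zero-variance nonzero paired differences; "
            "reporting p=0 by convention",
            stacklevel=2,
        )
        return DiffResult(feature_id, float("inf"), 0.0, fold, len(kept), method)

    if method == "paired_t":
        stat, p = stats.ttest_rel(tumor, normal)
    else:
        stat, p = stats.wilcoxon(tumor, normal, zero_method="wilcox", method="auto")
    return DiffResult(feature_id, float(stat), float(p), fold, len(kept), method)


def rank_sum_test(
    a: np.ndarray, b: np.ndarray, method: str = "mann_whitney"
) -> tuple[float, float]:
    """Two-sided two-sample test on raw value arrays.

    Mann–Whitney uses the exact null distribution for small tie-free
    samples and the tie-corrected normal approximation otherwise; ``t_test``
    is Welch's unequal-variance t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if np.std(a) == 0 and np.std(b) == 0:
        # two constant groups: identical -> p=1; separated -> p=0 by the
        # same degeneracy convention as the paired tests
        if a[0] == b[0]:
            return float(len(a) * len(b) / 2) if method == "mann_whitney" else 0.0, 1.0
        warnings.warn("two constant, distinct groups; reporting p=0", stacklevel=2)
        return float("inf"), 0.0
    if method == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if method == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"method must be one of {GROUP_METHODS}")


def group_diff_test(
    matrix: FeatureMatrix,
    feature_id: str,
    group_a_samples: list[str],
    group_b_samples: list[str],
    method: str = "mann_whitney",
) -> DiffResult:
    """Two-sided unpaired comparison of one feature between two sample sets.

    fold_change = mean(group A) / mean(group B).
    """
    row = matrix.feature(feature_id)
    a = row.loc[group_a_samples].to_numpy(dtype=float)
    b = row.loc[group_b_samples].to_numpy(dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    stat, p = rank_sum_test(a, b, method=method)
    return DiffResult(
        feature_id, stat, p, _fold_change(a, b), len(a) + len(b), method
    )


def overexpression_calls(
    matrix: FeatureMatrix,
    cohort: PairedCohort,
    feature_id: str,
    min_ratio: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Per-pair overexpression calls: tumor/normal ratio strictly above
    ``min_ratio`` counts as overexpressing (ties do not).

    Returns the per-pair table and the count of non-overexpressing pairs.
    A zero normal with nonzero tumor yields a ratio of +inf (overexpressing,
    with a logged warning).
    """
    if len(cohort) == 0:
        raise InsufficientDataError("cohort is empty")
    tumor, normal, kept = paired_values(matrix, cohort, feature_id)
    ratios = np.empty(len(kept))
    for i, (t, n) in enumerate(zip(tumor, normal)):
        if n == 0.0:
            ratios[i] = np.inf if t > 0 else np.nan
            if t > 0:
                log.warning(
                    "%s pair %s: zero normal value, ratio reported as +inf",
                    feature_id,
                    kept[i].patient_id,
                )
        else:
            ratios[i] = t / n
    over = ratios > min_ratio
    table = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in kept],
            "tumor_value": tumor,
            "normal_value": normal,
            "ratio": ratios,
            "overexpressing": over,
        }
    )
    return table, int((~over).sum())


def stagewise_tests(
    matrix: FeatureMatrix,
    feature_id: str,
    method: str = "mann_whitney",
) -> pd.DataFrame:
    """Each tumor stage vs all normal samples (unpaired), one row per stage."""
    normals = matrix.samples_where(tissue="normal")
    rows = []
    for stage in ("I", "II", "III", "IV"):
        tumors = matrix.samples_where(tissue="tumor", stage=stage)
        if len(tumors) < 2:
            continue
        r = group_diff_test(matrix, feature_id, tumors, normals, method=method)
        rows.append(
            {
                "stage": stage,
                "n_tumor": len(tumors),
                "n_normal": len(normals),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "fold_change": r.fold_change,
            }
        )
    return pd.DataFrame(rows)


def metastasis_test(
    matrix: FeatureMatrix, feature_id: str, method: str = "mann_whitney"
) -> DiffResult:
    """Tumors of metastatic vs non-metastatic patients (unpaired)."""
    met = matrix.samples_where(tissue="tumor", metastasis="yes")
    nonmet = matrix.samples_where(tissue="tumor", metastasis="no")
    if len(met) < 2 or len(nonmet) < 2:
        raise InsufficientDataError("need >= 2 tumors in each metastasis group")
    return group_diff_test(matrix, feature_id, met, nonmet, method=method)
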