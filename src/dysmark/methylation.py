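"""Promoter-methylation analysis on paired tumor/normal beta values.

Stages: probe-level paired t filtering (p < 0.001 by default, the filter
used to isolate a tumor-specific methylation signature), single-linkage
hierarchical clustering of the selected submatrix, promoter-region
aggregation of tumor−normal beta shifts, and methylation–expression
Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import DegenerateDataError, FormatError, InsufficientDataError
from .matrix import FeatureMatrix, PairedCohort

log = logging.getLogger(__name__)

REGION_LABELS = ("alpha_promoter", "beta_promoter", "body", "background")


@dataclass
class ClusterResult:
    """Agglomerative merge history plus the dendrogram leaf order.

    ``merges`` has one row per agglomeration: (node_a, node_b, distance,
    size), scipy convention (leaves 0..n−1, merge i creates node n+i).
    Single linkage guarantees the distances are non-decreasing; this is
    asserted on every run.
    """

    merges: np.ndarray
    leaf_order: list[int]
    item_ids: list[str]

    def __post_init__(self) -> None:
        d = self.merges[:, 2]
        if np.any(np.diff(d) < -1e-12):
            raise AssertionError("single-linkage merge distances decreased")


@dataclass
class RegionMethylation:
    region_label: str
    mean_delta_beta: float  # tumor − normal
    direction: str  # hypo | hyper
    n_probes: int


def paired_t_pvalues(
    meth: FeatureMatrix, cohort: PairedCohort, min_pairs: int = 3
) -> pd.Series:
    """Vectorized paired two-sided t-test p-value per probe.

    Pairs with a missing beta are dropped per probe; probes with fewer
    than ``min_pairs`` usable pairs get NaN (and are logged).  The
    zero-variance convention matches the expression stage: all-zero
    differences -> p=1, constant nonzero shift -> p=0.
    """
    t_mat = meth.values[cohort.tumor_ids].to_numpy(dtype=float)
    n_mat = meth.values[cohort.normal_ids].to_numpy(dtype=float)
    diffs = t_mat - n_mat
    valid = np.isfinite(diffs)
    n_used = valid.sum(axis=1)

    with np.errstate(invalid="ignore"):
        res = stats.ttest_rel(t_mat, n_mat, axis=1, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)

    mean_d = np.nanmean(np.where(valid, diffs, np.nan), axis=1)
    sd_d = np.nanstd(np.where(valid, diffs, np.nan), axis=1)
    # tolerance absorbs float summation dust on genuinely constant diffs
    zero_var = sd_d <= 1e-12 + 1e-9 * np.abs(mean_d)
    zero_mean = np.abs(mean_d) <= 1e-12
    p[zero_var & zero_mean] = 1.0
    p[zero_var & ~zero_mean] = 0.0
    p[n_used < min_pairs] = np.nan
    n_dropped = int((n_used < min_pairs).sum())
    if n_dropped:
        log.warning("%d probes excluded: fewer than %d complete pairs", n_dropped, min_pairs)
    return pd.Series(p, index=meth.values.index, name="p_value")


def select_probes(
    meth: FeatureMatrix,
    cohort: PairedCohort,
    alpha: float = 0.001,
) -> tuple[list[str], pd.Series]:
    """Probes whose paired t-test p-value is below ``alpha``.

    Returns (selected probe ids, per-probe p-values).  An empty selection
    is a warning, not an error.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    p = paired_t_pvalues(meth, cohort)
    selected = list(p.index[(p < alpha).fillna(False)])
    if not selected:
        log.warning("no probe passed the paired t filter at alpha=%g", alpha)
    return selected, p


def single_linkage_cluster(
    submatrix: pd.DataFrame,
    axis: str = "probes",
    distance: str = "euclidean",
) -> ClusterResult:
    """Single-linkage agglomerative clustering of rows (probes) or columns
    (samples) of a beta submatrix.

    Missing values are imputed per-probe by the cohort median first.
    ``one_minus_pearson`` uses 1 − Pearson correlation as the distance.
    """
    if axis not in ("probes", "samples"):
        raise ValueError("axis must be 'probes' or 'samples'")
    if distance not in ("euclidean", "one_minus_pearson"):
        raise ValueError("distance must be 'euclidean' or 'one_minus_pearson'")

    data = submatrix.copy()
    med = data.median(axis=1)
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        raise FormatError(
            f"items with all-missing rows: {list(data.index[all_missing])}"
        )
    data = data.apply(lambda row: row.fillna(med[row.name]), axis=1)

    mat = data.to_numpy(dtype=float) if axis == "probes" else data.to_numpy(dtype=float).T
    ids = list(data.index) if axis == "probes" else list(data.columns)
    if len(ids) < 2:
        raise InsufficientDataError("need at least 2 items to cluster")

    metric = "euclidean" if distance == "euclidean" else "correlation"
    dvec = pdist(mat, metric=metric)
    merges = linkage(dvec, method="single")
    order = [int(i) for i in leaves_list(merges)]
    return ClusterResult(merges=merges, leaf_order=order, item_ids=ids)


def aggregate_regions(
    meth: FeatureMatrix,
    cohort: PairedCohort,
    annotation: pd.DataFrame,
) -> list[RegionMethylation]:
    """Mean tumor−normal beta shift per annotated region.

    ``annotation`` must carry columns ``probe_id`` and ``region_label``
    covering every probe of the matrix.  Per region the statistic is the
    mean over probes of the mean over pairs of (tumor − normal) beta;
    direction is ``hypo`` when negative, ``hyper`` otherwise.  Regions
    with no probes in the matrix are omitted with a warning.
    """
    ann = annotation.set_index("probe_id")["region_label"]
    missing = set(meth.values.index) - set(ann.index)
    if missing:
        raise FormatError(f"probes without annotation: {sorted(missing)[:5]}")

    t_mat = meth.values[cohort.tumor_ids].to_numpy(dtype=float)
    n_mat = meth.values[cohort.normal_ids].to_numpy(dtype=float)
    probe_delta = pd.Series(
        np.nanmean(t_mat - n_mat, axis=1), index=meth.values.index
    )

    out = []
    for region in REGION_LABELS:
        probes = [p for p in meth.values.index if ann[p] == region]
        if not probes:
            log.warning("region %s has no probes; omitted", region)
            continue
        delta = float(probe_delta[probes].mean())
        out.append(
            RegionMethylation(
                region_label=region,
                mean_delta_beta=delta,
                direction="hypo" if delta < 0 else "hyper",
                n_probes=len(probes),
            )
        )
    return out


def meth_expr_correlation(
    meth: FeatureMatrix,
    expr: FeatureMatrix,
    probe_id: str,
    feature_id: str,
    samples: list[str] | None = None,
    log2_expression: bool = True,
) -> tuple[float, float, int]:
    """Pearson correlation between one probe's beta and one feature's
    expression over the common samples.

    Expression is log2(x+1)-transformed by default (normalized abundances
    are log-normal-ish; the linear association of interest lives on the
    log scale).  Returns (r, two-sided p from the t transform, n).
    """
    beta = meth.feature(probe_id)
    ex = expr.feature(feature_id)
    common = [s for s in (samples or beta.index) if s in beta.index and s in ex.index]
    b = beta.loc[common].to_numpy(dtype=float)
    x = ex.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(b) & np.isfinite(x)
    b, x = b[ok], x[ok]
    if len(b) < 4:
        raise InsufficientDataError(f"only {len(b)} common samples (need >= 4)")
    if log2_expression:
        x = np.log2(x + 1.0)
    if np.std(b) == 0 or np.std(x) == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    res = stats.pearsonr(b, x)
    return float(res.statistic), float(res.pvalue), int(len(b))
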