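"""Marker-quartile survival stratification.

Patients are split at the top and bottom 25th percentiles of a numeric
marker (nearest-rank percentiles, boundary ties included), survival in the
two extreme groups is estimated by Kaplan–Meier, and the groups are
compared with the log-rank (Mantel–Cox) and Gehan–Breslow–Wilcoxon tests.
The headline effect size is the difference of median survivals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DegenerateDataError, InsufficientDataError, NoEventsError
from .matrix import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class KMResult:
    """Product-limit survival estimate evaluated at the event times."""

    times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) just after each time
    n_at_risk: np.ndarray
    median: float  # earliest t with S(t) <= 0.5; nan if never reached


@dataclass
class SurvivalGroupResult:
    km_high: KMResult
    km_low: KMResult
    logrank_chi2: float
    logrank_p: float
    wilcoxon_chi2: float
    wilcoxon_p: float
    median_high: float
    median_low: float
    median_difference: float  # |median_high − median_low|; nan if undefined
    high_ids: list[str]
    low_ids: list[str]


def percentile_groups(
    values: pd.Series, pct: float = 25.0
) -> tuple[list[str], list[str]]:
    """Top/bottom pct-th percentile patient groups by marker value.

    Nearest-rank percentiles; patients tied with the boundary value are
    included (groups may exceed n·pct/100, which is logged).  Returns
    (high ids, low ids).
    """
    if not 0.0 < pct <= 50.0:
        raise ValueError("pct must be in (0, 50]")
    v = values.dropna()
    n = len(v)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 patients, got {n}")
    if v.nunique() == 1:
        raise DegenerateDataError("all marker values identical; cannot stratify")
    s = np.sort(v.to_numpy())
    k = math.ceil(pct / 100.0 * n)  # nearest-rank
    low_thr, high_thr = s[k - 1], s[n - k]
    low = list(v.index[v <= low_thr])
    high = list(v.index[v >= high_thr])
    if len(low) > k or len(high) > k:
        log.info(
            "boundary ties enlarged the percentile groups to %d/%d (nominal %d)",
            len(low), len(high), k,
        )
    return high, low


def kaplan_meier(times, events) -> KMResult:
    """Kaplan–Meier product-limit estimate.

    ``times`` are positive follow-up durations; ``events`` is 1 for death,
    0 for censoring.  The median is the earliest time with S(t) <= 0.5,
    NaN if the curve never reaches 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise InsufficientDataError("no survival records")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("survival times must be finite and positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.iloc[:, 0]
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    keep = grid > 0  # drop the t=0 anchor row
    grid, surv = grid[keep], surv[keep]
    at_risk = np.array([(t >= g).sum() for g in grid])
    med = kmf.median_survival_time_
    return KMResult(
        times=grid,
        survival=surv,
        n_at_risk=at_risk,
        median=float("nan") if np.isinf(med) else float(med),
    )


def _two_group_test(t1, e1, t2, e2, weightings=None) -> tuple[float, float]:
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    if e1.sum() + e2.sum() == 0:
        raise NoEventsError("no events in either group")
    if len(t1) == len(t2):
        s1 = sorted(zip(t1.tolist(), e1.tolist()))
        s2 = sorted(zip(t2.tolist(), e2.tolist()))
        if s1 == s2:
            return 0.0, 1.0  # identical groups: O == E at every event time
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2,
                      weightings=weightings)
    return float(res.test_statistic), float(res.p_value)


def logrank_test(times1, events1, times2, events2) -> tuple[float, float]:
    """Log-rank (Mantel–Cox) chi-square (1 df) and two-sided p-value."""
    return _two_group_test(times1, events1, times2, events2, weightings=None)


def gehan_wilcoxon_test(times1, events1, times2, events2) -> tuple[float, float]:
    """Gehan–Breslow–Wilcoxon test: log-rank weighted by n at risk, so
    early survival differences count more."""
    return _two_group_test(times1, events1, times2, events2, weightings="wilcoxon")


def survival_strata(
    matrix: FeatureMatrix,
    clinical: pd.DataFrame,
    feature_id: str,
    pct: float = 25.0,
) -> SurvivalGroupResult:
    """Full stratified analysis of one marker against overall survival.

    Marker values are taken from each patient's tumor sample; patients
    missing survival time or vital status are dropped (logged).
    ``clinical`` needs columns patient_id, survival_days, vital_status
    (``deceased``/``alive``) — one row per patient or per sample.
    """
    row = matrix.feature(feature_id)
    meta = matrix.sample_meta
    tumor_ids = [s for s in matrix.sample_ids if meta.loc[s, "tissue"] == "tumor"]
    by_patient = pd.Series(
        {meta.loc[s, "patient_id"]: float(row[s]) for s in tumor_ids}
    )

    clin = clinical.drop_duplicates(subset="patient_id").set_index("patient_id")
    usable = clin["survival_days"].notna() & clin["vital_status"].notna()
    dropped = int((~usable).sum())
    if dropped:
        log.warning("%d patients dropped: missing survival time or status", dropped)
    clin = clin[usable]
    by_patient = by_patient[by_patient.index.isin(clin.index)]

    high, low = percentile_groups(by_patient, pct=pct)

    def arrs(ids):
        sub = clin.loc[ids]
        return (
            sub["survival_days"].to_numpy(dtype=float),
            (sub["vital_status"] == "deceased").to_numpy(dtype=int),
        )

    th, eh = arrs(high)
    tl, el = arrs(low)
    km_h, km_l = kaplan_meier(th, eh), kaplan_meier(tl, el)
    lr_chi2, lr_p = logrank_test(th, eh, tl, el)
    w_chi2, w_p = gehan_wilcoxon_test(th, eh, tl, el)
    if np.isnan(km_h.median) or np.isnan(km_l.median):
        med_diff = float("nan")
    else:
        med_diff = abs(km_h.median - km_l.median)
    return SurvivalGroupResult(
        km_high=km_h,
        km_low=km_l,
        logrank_chi2=lr_chi2,
        logrank_p=lr_p,
        wilcoxon_chi2=w_chi2,
        wilcoxon_p=w_p,
        median_high=km_h.median,
        median_low=km_l.median,
        median_difference=med_diff,
        high_ids=high,
        low_ids=low,
    )
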