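"""ROC biomarker evaluation and the correlated-AUC z comparison.

Two markers measured on the same subjects yield correlated AUC estimates,
so the naive two-sample z test overstates the variance of their difference.
The comparison implemented here follows Hanley & McNeil's correlated-ROC
approach: each AUC gets the Hanley–McNeil (1982) standard error, the
between-marker association is summarized by the average Kendall tau-b
within negatives and within positives, and a coefficient r — the induced
correlation between the two AUC estimates — is looked up from (average tau,
average AUC).  The comparison statistic is

    z = (AUC1 − AUC2) / sqrt(SE1² + SE2² − 2·r·SE1·SE2)

with |z| > 2 called significant.

The r lookup table shipped with the package (``data/hm_r_table.tsv``) is
computed, not transcribed: it tabulates the asymptotic equal-group-size
correlation between the two empirical AUCs under a bivariate equal-AUC
binormal model, with the tau row index mapped to a latent Pearson
correlation via Greiner's relation rho = sin(pi*tau/2).  The generating
closed form is :func:`binormal_auc_correlation`.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .errors import DegenerateDataError, InsufficientDataError

Z_SIGNIFICANCE_CUTOFF = 2.0  # |z| above this is called significant


@dataclass
class RocResult:
    """Empirical AUC with its Hanley–McNeil standard error."""

    auc: float
    se: float
    n_pos: int
    n_neg: int


@dataclass
class RocComparison:
    """Correlated comparison of two markers' AUCs on the same subjects."""

    auc1: float
    se1: float
    auc2: float
    se2: float
    tau_n: float  # Kendall tau-b between markers within negatives
    tau_t: float  # ... within positives
    avg_tau: float
    avg_auc: float
    r: float  # Hanley–McNeil coefficient
    z: float
    significant: bool


def empirical_auc(scores_pos, scores_neg) -> RocResult:
    """Empirical (trapezoidal) AUC of positives vs negatives.

    Equals the probability a random positive outscores a random negative,
    ties half-credited — i.e. the Mann–Whitney U statistic divided by
    n_pos·n_neg.  Computed via midranks, so it is O((m+n) log(m+n)).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("both score groups must be non-empty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("scores must be finite")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m, n = pos.size, neg.size
    auc = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return RocResult(float(auc), hanley_mcneil_se(float(auc), m, n), m, n)


def roc_curve_points(scores_pos, scores_neg) -> np.ndarray:
    """(FPR, TPR) coordinates of the empirical ROC curve, one row per
    distinct threshold, endpoints (0,0) and (1,1) included."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pts.append((float(np.mean(neg >= t)), float(np.mean(pos >= t))))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.asarray(pts)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil (1982) standard error of an empirical AUC.

    With A the AUC, Q1 = A/(2−A) and Q2 = 2A²/(1+A):

        SE² = [A(1−A) + (n_pos−1)(Q1−A²) + (n_neg−1)(Q2−A²)] / (n_pos·n_neg)
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc must be in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def kendall_tau(x, y) -> float:
    """Kendall tau-b (tie-corrected) between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("Kendall tau undefined for an all-tied vector")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def binormal_auc_correlation(tau: float, auc: float) -> float:
    """Correlation r between two empirical AUC estimates, binormal model.

    Both markers are given the same AUC; scores share a latent Pearson
    correlation rho = sin(pi*tau/2) within each class (Greiner's relation,
    so the table can be entered with the observed Kendall tau).  In the
    equal-group-size limit the correlation between the two Mann–Whitney
    AUC estimates reduces to

        r = [Phi2(b, b; rho/2) − A²] / [Phi2(b, b; 1/2) − A²],

    b = Phi^{-1}(A), where Phi2(·,·; c) is the standard bivariate normal
    CDF with correlation c.  The numerator is the shared-subject
    cross-moment; the denominator is the same quantity at rho = 1.
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError("tau must be in [-1, 1]")
    if not 0.5 <= auc < 1.0:
        raise ValueError("auc must be in [0.5, 1)")
    if tau <= 0.0:
        return 0.0
    rho = math.sin(math.pi * tau / 2.0)
    b = stats.norm.ppf(auc)
    a2 = auc * auc

    def phi2(c: float) -> float:
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, c], [c, 1.0]])
        return float(mvn.cdf([b, b]))

    num = phi2(rho / 2.0) - a2
    den = phi2(0.5) - a2
    return float(min(max(num / den, 0.0), 1.0))


@lru_cache(maxsize=1)
def _r_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tau grid, auc grid, r grid) from the shipped TSV asset."""
    ref = importlib.resources.files("dysmark").joinpath("data/hm_r_table.tsv")
    with ref.open() as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    aucs = np.array([float(c) for c in header[1:]])
    taus, rows = [], []
    for ln in lines[1:]:
        cells = ln.rstrip("\n").split("\t")
        taus.append(float(cells[0]))
        rows.append([float(c) for c in cells[1:]])
    return np.array(taus), aucs, np.array(rows)


def hm_coefficient(avg_tau: float, avg_auc: float, mode: str = "table") -> float:
    """Hanley–McNeil coefficient r from average tau and average AUC.

    ``table`` (default) bilinearly interpolates the shipped r table; AUCs
    below 0.5 are reflected to 1−AUC first, out-of-range queries are
    clamped to the table boundary with a warning, and a negative average
    tau floors r at 0.  ``avg_tau`` uses r = max(avg_tau, 0) directly, as
    a sensitivity alternative.
    """
    if not -1.0 <= avg_tau <= 1.0:
        raise ValueError("avg_tau must be in [-1, 1]")
    if not 0.0 <= avg_auc <= 1.0:
        raise ValueError("avg_auc must be in [0, 1]")
    if avg_auc < 0.5:
        avg_auc = 1.0 - avg_auc
    if avg_tau <= 0.0:
        return 0.0
    if mode == "avg_tau":
        return float(min(avg_tau, 1.0))
    if mode != "table":
        raise ValueError("mode must be 'table' or 'avg_tau'")
    taus, aucs, _ = _r_table()
    t, a = avg_tau, avg_auc
    if t > taus[-1] or a > aucs[-1]:
        warnings.warn(
            f"(tau={t:.3f}, auc={a:.3f}) outside r table; clamped to boundary",
            stacklevel=2,
        )
        t, a = min(t, taus[-1]), min(a, aucs[-1])
    return float(np.clip(_r_interpolator()([[t, a]])[0], 0.0, 1.0))


@lru_cache(maxsize=1)
def _r_interpolator() -> RegularGridInterpolator:
    taus, aucs, grid = _r_table()
    return RegularGridInterpolator((taus, aucs), grid, method="linear")


def compare_auc(
    scores1_pos,
    scores1_neg,
    scores2_pos,
    scores2_neg,
    r_mode: str = "table",
) -> RocComparison:
    """Correlated z comparison of two markers on the same subjects.

    The positive score lists must be aligned subject-by-subject, and
    likewise the negatives (the Kendall taus are within-class, between
    markers).  Significance is the |z| > 2 rule.
    """
    r1 = empirical_auc(scores1_pos, scores1_neg)
    r2 = empirical_auc(scores2_pos, scores2_neg)
    if len(scores1_pos) != len(scores2_pos) or len(scores1_neg) != len(scores2_neg):
        raise ValueError("markers must be measured on the same subjects")
    tau_t = kendall_tau(scores1_pos, scores2_pos)
    tau_n = kendall_tau(scores1_neg, scores2_neg)
    avg_tau = (tau_n + tau_t) / 2.0
    avg_auc = (r1.auc + r2.auc) / 2.0
    r = hm_coefficient(avg_tau, avg_auc, mode=r_mode)
    var = r1.se**2 + r2.se**2 - 2.0 * r * r1.se * r2.se
    if var <= 0.0:
        if r1.auc == r2.auc:
            # e.g. a marker compared against itself: no difference, and the
            # correlation soaks up all the variance
            z = 0.0
        else:
            raise DegenerateDataError(
                f"non-positive variance of the AUC difference ({var:.3g}); "
                "the comparison is degenerate"
            )
    else:
        z = (r1.auc - r2.auc) / math.sqrt(var)
    return RocComparison(
        auc1=r1.auc,
        se1=r1.se,
        auc2=r2.auc,
        se2=r2.se,
        tau_n=tau_n,
        tau_t=tau_t,
        avg_tau=avg_tau,
        avg_auc=avg_auc,
        r=r,
        z=float(z),
        significant=abs(z) > Z_SIGNIFICANCE_CUTOFF,
    )
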