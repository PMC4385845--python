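"""Composite immunohistochemistry scoring and staining/diagnosis association.

Each tissue micro-section gets a percent-stained category (1: <10% ...
4: >60%) and an intensity category (1–4, pathologist-assigned); their
product is the composite score (1–16).  Association between staining and
diagnosis is a Pearson chi-square on the 2×2 stained/unstained table;
stage- or grade-wise composite comparisons delegate to the rank tests of
the expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .expression import rank_sum_test

#: interior cut-points of the percent-stained bins; the outer bounds
#: (<10 -> 1, >60 -> 4) are fixed, the interior split is configurable
DEFAULT_PERCENT_CUTS = (10.0, 35.0, 60.0)


@dataclass
class CompositeScore:
    percent_category: int
    intensity_category: int
    composite: int


def percent_category(
    percent_stained: float, cuts: tuple[float, float, float] = DEFAULT_PERCENT_CUTS
) -> int:
    """Percent-stained category: <cuts[0] -> 1, [cuts[0], cuts[1]) -> 2,
    [cuts[1], cuts[2]] -> 3, >cuts[2] -> 4."""
    p = float(percent_stained)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent_stained must be in [0, 100], got {p}")
    lo, mid, hi = cuts
    if p < lo:
        return 1
    if p < mid:
        return 2
    if p <= hi:
        return 3
    return 4


def composite_score(
    percent_stained: float,
    intensity_category: int,
    cuts: tuple[float, float, float] = DEFAULT_PERCENT_CUTS,
) -> CompositeScore:
    """Composite = percent category × intensity category (range 1–16)."""
    ic = int(intensity_category)
    if ic not in (1, 2, 3, 4):
        raise ValueError(f"intensity_category must be 1-4, got {ic}")
    pc = percent_category(percent_stained, cuts)
    return CompositeScore(pc, ic, pc * ic)


def score_table(table: pd.DataFrame, cuts=DEFAULT_PERCENT_CUTS) -> pd.DataFrame:
    """Add percent_category / composite columns to an IHC record table.

    Expects columns section_id, diagnosis, stage, grade, percent_stained,
    intensity.  If two pathologists' columns are present (``intensity_a``
    and ``intensity_b``), they are averaged and rounded half-up first.
    """
    out = table.copy()
    if "intensity" not in out.columns:
        if {"intensity_a", "intensity_b"} <= set(out.columns):
            out["intensity"] = (
                np.floor((out["intensity_a"] + out["intensity_b"]) / 2.0 + 0.5)
                .astype(int)
            )
        else:
            raise ValueError("need an 'intensity' or 'intensity_a'/'intensity_b' column")
    scored = [
        composite_score(p, i, cuts)
        for p, i in zip(out["percent_stained"], out["intensity"])
    ]
    out["percent_category"] = [s.percent_category for s in scored]
    out["composite"] = [s.composite for s in scored]
    return out


def chi_square_staining(table_2x2) -> tuple[float, int, float, int]:
    """Pearson chi-square (no continuity correction) on a diagnosis ×
    stained/unstained contingency table.

    Returns (chi2, df, p, n).  A Yates-corrected variant is available via
    :func:`chi_square_staining_corrected`.
    """
    return _chi_square(table_2x2, correction=False)


def chi_square_staining_corrected(table_2x2) -> tuple[float, int, float, int]:
    """Yates continuity-corrected version of :func:`chi_square_staining`."""
    return _chi_square(table_2x2, correction=True)


def _chi_square(table, correction: bool) -> tuple[float, int, float, int]:
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise DegenerateDataError("empty contingency table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateDataError("a zero marginal makes the chi-square undefined")
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue), int(n)


def staining_contingency(
    scored: pd.DataFrame, stained_if: str = "composite_gt_1"
) -> pd.DataFrame:
    """2×2 diagnosis × stained/unstained counts from a scored IHC table.

    The dichotomization rule is a parameter: ``composite_gt_1`` (default),
    ``any_staining`` (percent_stained > 0), or ``composite_gt_<k>``.
    """
    if stained_if == "any_staining":
        stained = scored["percent_stained"] > 0
    elif stained_if.startswith("composite_gt_"):
        k = int(stained_if.rsplit("_", 1)[1])
        stained = scored["composite"] > k
    else:
        raise ValueError(f"unknown dichotomization rule: {stained_if!r}")
    return pd.crosstab(scored["diagnosis"], stained.rename("stained"))


def groupwise_score_test(
    scored: pd.DataFrame,
    by: str = "stage",
    method: str = "mann_whitney",
) -> pd.DataFrame:
    """Pairwise composite-score comparisons between strata.

    Strata are the levels of ``by`` (stage or grade) plus ``normal``
    sections as their own stratum; every pair of strata with >= 2
    observations each is tested.  Returns one row per pair with group
    means and the two-sided p-value.
    """
    df = scored.copy()
    df["_stratum"] = np.where(
        df["diagnosis"] == "normal", "normal", df[by].astype(str)
    )
    groups = {
        name: g["composite"].to_numpy(dtype=float)
        for name, g in df.groupby("_stratum")
        if name != "NA" and len(g) >= 2
    }
    rows = []
    for a, b in combinations(sorted(groups), 2):
        stat, p = rank_sum_test(groups[a], groups[b], method=method)
        rows.append(
            {
                "stratum_a": a,
                "stratum_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "mean_a": float(groups[a].mean()),
                "mean_b": float(groups[b].mean()),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
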