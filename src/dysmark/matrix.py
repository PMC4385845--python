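"""Core containers: feature-by-sample matrices and matched tumor/normal cohorts.

A :class:`FeatureMatrix` wraps a features × samples :class:`pandas.DataFrame`
(expression abundances or methylation beta values) together with per-sample
clinical metadata.  A :class:`PairedCohort` records which tumor sample is
matched to which adjacent-normal sample of the same patient — the backbone
joining the expression, methylation and survival stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_

#: columns every sample-metadata table must carry
SAMPLE_META_COLUMNS = ("patient_id", "tissue", "stage", "metastasis")

VALID_TISSUES = frozenset({"tumor", "normal"})
VALID_STAGES = frozenset({"I", "II", "III", "IV", "NA"})


class Pair(NamedTuple):
    patient_id: str
    tumor_sample_id: str
    normal_sample_id: str


@dataclass
class FeatureMatrix:
    """Features × samples numeric matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns = sample ids.  Expression
        abundances must be non-negative; methylation betas must lie in [0, 1].
    sample_meta
        DataFrame indexed by sample id with columns ``patient_id``,
        ``tissue`` (tumor/normal), ``stage`` (I–IV or NA) and ``metastasis``
        (yes/no/NA).  Every column of ``values`` must have a metadata row.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dupes)[:5]}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise FormatError(
                f"samples without metadata: {sorted(missing)[:5]}"
            )
        absent = [c for c in SAMPLE_META_COLUMNS if c not in self.sample_meta.columns]
        if absent:
            raise FormatError(f"sample_meta missing columns: {absent}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def feature(self, feature_id: str) -> pd.Series:
        """Return one feature's values across samples."""
        if feature_id not in self.values.index:
            raise LookupError_(f"unknown feature: {feature_id!r}")
        return self.values.loc[feature_id]

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose metadata match all given column=value conditions."""
        meta = self.sample_meta.loc[self.sample_ids]
        mask = np.ones(len(meta), dtype=bool)
        for col, val in conditions.items():
            mask &= (meta[col] == val).to_numpy()
        return list(meta.index[mask])


@dataclass
class PairedCohort:
    """Matched (patient, tumor sample, normal sample) triples."""

    pairs: list[Pair] = field(default_factory=list)

    def __iter__(self) -> Iterator[Pair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def tumor_ids(self) -> list[str]:
        return [p.tumor_sample_id for p in self.pairs]

    @property
    def normal_ids(self) -> list[str]:
        return [p.normal_sample_id for p in self.pairs]

    def validate_against(self, matrix: FeatureMatrix) -> None:
        """Check both samples of every pair exist, share the patient id and
        carry the expected tissue labels."""
        meta = matrix.sample_meta
        cols = set(matrix.sample_ids)
        for p in self.pairs:
            for sid, tissue in (
                (p.tumor_sample_id, "tumor"),
                (p.normal_sample_id, "normal"),
            ):
                if sid not in cols:
                    raise LookupError_(f"pair sample {sid!r} not in matrix")
                if meta.loc[sid, "patient_id"] != p.patient_id:
                    raise FormatError(
                        f"sample {sid!r} does not belong to patient {p.patient_id!r}"
                    )
                if meta.loc[sid, "tissue"] != tissue:
                    raise FormatError(
                        f"sample {sid!r}: expected tissue {tissue!r}, "
                        f"got {meta.loc[sid, 'tissue']!r}"
                    )

    @classmethod
    def from_sample_meta(cls, sample_meta: pd.DataFrame) -> "PairedCohort":
        """Build the cohort of all patients that have exactly one tumor and
        one normal sample in the metadata table."""
        pairs = []
        for pid, grp in sample_meta.groupby("patient_id", sort=True):
            tum = grp.index[grp["tissue"] == "tumor"]
            nrm = grp.index[grp["tissue"] == "normal"]
            if len(tum) == 1 and len(nrm) == 1:
                pairs.append(Pair(str(pid), tum[0], nrm[0]))
        return cls(pairs)


def paired_values(
    matrix: FeatureMatrix, cohort: PairedCohort, feature_id: str
) -> tuple[np.ndarray, np.ndarray, list[Pair]]:
    """Aligned (tumor, normal) value arrays for one feature.

    Pairs with a missing (NaN) value on either side are dropped; the
    surviving pairs are returned alongside the arrays.
    """
    row = matrix.feature(feature_id)
    tumor, normal, kept = [], [], []
    for p in cohort:
        t, n = row.get(p.tumor_sample_id, np.nan), row.get(p.normal_sample_id, np.nan)
        if np.isfinite(t) and np.isfinite(n):
            tumor.append(float(t))
            normal.append(float(n))
            kept.append(p)
    return np.asarray(tumor), np.asarray(normal), kept
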