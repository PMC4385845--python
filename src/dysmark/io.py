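"""Readers and writers for the package's file formats.

Matrices are TSV with feature ids in the first column and sample ids in
the header; clinical, IHC, annotation and result tables are plain TSV;
ground truth and run summaries are JSON; images are PNG or TIFF.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .matrix import FeatureMatrix

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = (
    "sample_id",
    "patient_id",
    "tissue",
    "stage",
    "metastasis",
    "survival_days",
    "vital_status",
)


def read_feature_matrix(path, clinical_path=None) -> FeatureMatrix | pd.DataFrame:
    """Read a features × samples TSV (header = sample ids, first column =
    feature ids).

    Returns a bare DataFrame when no clinical table is given, else a
    :class:`FeatureMatrix` joined with the clinical metadata.  Non-numeric
    cells are reported with their coordinates; "NA" cells become missing
    values (counted in a warning).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique()
        raise FormatError(f"{path}: duplicate feature ids {list(dupes)[:5]}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique()
        raise FormatError(f"{path}: duplicate sample ids {list(dupes)[:5]}")

    na_tokens = ("", "NA", "NaN", "nan")
    is_na = raw.isin(na_tokens)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & ~is_na
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {raw.iloc[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    n_missing = int(is_na.to_numpy().sum())
    if n_missing:
        log.warning("%s: %d missing values", path, n_missing)

    if clinical_path is None:
        return values
    clinical = read_clinical(clinical_path)
    return FeatureMatrix(values=values, sample_meta=clinical.set_index("sample_id"))


def write_feature_matrix(values: pd.DataFrame | FeatureMatrix, path) -> None:
    if isinstance(values, FeatureMatrix):
        values = values.values
    values.to_csv(path, sep="\t", index_label="feature_id")


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {missing}")
    return clin


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """BED-like probe annotation: chrom, start, end, probe_id, region_label."""
    ann = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "probe_id", "region_label"],
        header=None,
        comment="#",
    )
    if ann["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids in annotation")
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["chrom", "start", "end", "probe_id", "region_label"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_ihc_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_image(image, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), image.pixels)


def read_image(path, bit_depth=None, microns_per_pixel: float = 1.0):
    import imageio.v3 as iio

    from .assays import AssayImage

    px = iio.imread(Path(path))
    if px.ndim == 3:  # collapse accidental RGB to grayscale
        px = px.mean(axis=2).astype(px.dtype)
    if bit_depth is None:
        bit_depth = 16 if px.dtype.itemsize > 1 else 8
    return AssayImage(px, bit_depth=bit_depth, microns_per_pixel=microns_per_pixel)
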