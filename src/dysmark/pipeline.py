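"""End-to-end orchestration: chain the analysis stages on one cohort and
write a machine-readable summary plus a hashed output MANIFEST.

Every run is fully determined by its configuration (including the seed);
re-running with the same config reproduces every output hash.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression, ihc, methylation, roc, survival
from .errors import ConfigurationError
from .io import (
    read_annotation,
    read_clinical,
    read_feature_matrix,
    read_ihc_table,
    write_annotation,
    write_clinical,
    write_feature_matrix,
    write_json,
)
from .matrix import FeatureMatrix, PairedCohort
from .synthetic import CohortConfig, config_to_dict, generate_cohort, generate_ihc_table

log = logging.getLogger(__name__)

STAGES = ("diffexp", "methylation", "roc", "survival", "ihc")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    With ``simulate`` true (default) the cohort is generated from
    ``cohort_config``; otherwise the four input paths must point at
    existing files.
    """

    out_dir: str = "dysmark_run"
    seed: int = 0
    simulate: bool = True
    cohort_config: CohortConfig | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    methylation_path: str | None = None
    annotation_path: str | None = None
    ihc_path: str | None = None
    stages: tuple[str, ...] = STAGES
    marker: str = "MARKER"
    survival_marker: str = "MARKER"
    corr_probe: str | None = None  # default: truth's designated probe
    alpha: float = 0.001  # probe-selection threshold
    pct: float = 25.0  # survival percentile
    min_ratio: float = 1.0  # overexpression call threshold
    r_mode: str = "table"
    ihc_stained_if: str = "composite_gt_1"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if not self.simulate:
            for name in ("expression_path", "clinical_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"{name} missing or nonexistent: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _promoter_scores(meth: FeatureMatrix, annotation: pd.DataFrame,
                     region: str, samples: list[str]) -> np.ndarray:
    """Per-sample promoter hypomethylation score: 1 − mean beta over the
    region's probes (oriented so tumors, which lose methylation, score
    high)."""
    probes = annotation.loc[annotation["region_label"] == region, "probe_id"]
    probes = [p for p in probes if p in meth.values.index]
    return 1.0 - meth.values.loc[probes, samples].mean(axis=0).to_numpy(dtype=float)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the report directory.

    Writes per-stage TSVs, a ``summary.json`` with the headline numbers,
    and a ``MANIFEST.json`` hashing every output file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    # ---- inputs -------------------------------------------------------
    if config.simulate:
        cc = config.cohort_config or CohortConfig(seed=config.seed)
        syn = generate_cohort(cc)
        expr, meth = syn.expression, syn.methylation
        annotation, clinical, cohort = syn.annotation, syn.clinical, syn.cohort
        ihc_table = generate_ihc_table(seed=config.seed)
        corr_probe = config.corr_probe or syn.truth.correlated_probe_id
        summary["cohort_config"] = config_to_dict(cc)
        write_feature_matrix(expr, out / "expression.tsv")
        write_feature_matrix(meth, out / "methylation.tsv")
        write_clinical(clinical, out / "clinical.tsv")
        write_annotation(annotation, out / "probes.bed")
        ihc_table.to_csv(out / "ihc.tsv", sep="\t", index=False)
    else:
        expr = read_feature_matrix(config.expression_path, config.clinical_path)
        clinical = read_clinical(config.clinical_path)
        meth = annotation = ihc_table = None
        if config.methylation_path:
            meth = read_feature_matrix(config.methylation_path, config.clinical_path)
        if config.annotation_path:
            annotation = read_annotation(config.annotation_path)
        if config.ihc_path:
            ihc_table = read_ihc_table(config.ihc_path)
        cohort = PairedCohort.from_sample_meta(expr.sample_meta)
        corr_probe = config.corr_probe

    marker = config.marker
    try:
        # ---- paired/group differential expression --------------------
        if "diffexp" in config.stages:
            paired = expression.paired_diff_test(expr, cohort, marker)
            calls, n_non = expression.overexpression_calls(
                expr, cohort, marker, min_ratio=config.min_ratio
            )
            calls.to_csv(out / "overexpression_calls.tsv", sep="\t", index=False)
            stage_tbl = expression.stagewise_tests(expr, marker)
            stage_tbl.to_csv(out / "stagewise_tests.tsv", sep="\t", index=False)
            summary["diffexp"] = {
                "marker": marker,
                "paired_p": paired.p_value,
                "paired_fold_change": paired.fold_change,
                "n_pairs_used": paired.n_used,
                "n_non_overexpressing": n_non,
            }
            try:
                met = expression.metastasis_test(expr, marker)
                summary["diffexp"]["metastasis_fold_change"] = met.fold_change
                summary["diffexp"]["metastasis_p"] = met.p_value
            except Exception as exc:  # too few metastatic tumors, etc.
                log.info("metastasis comparison skipped: %s", exc)

        # ---- methylation ---------------------------------------------
        if "methylation" in config.stages and meth is not None:
            meth_cohort = PairedCohort.from_sample_meta(meth.sample_meta)
            selected, pvals = methylation.select_probes(
                meth, meth_cohort, alpha=config.alpha
            )
            pvals.to_frame().assign(selected=pvals.index.isin(selected)).to_csv(
                out / "probe_selection.tsv", sep="\t", index_label="probe_id"
            )
            if len(selected) >= 2:
                clus = methylation.single_linkage_cluster(
                    meth.values.loc[selected], axis="probes"
                )
                pd.DataFrame(
                    clus.merges, columns=["node_a", "node_b", "distance", "size"]
                ).to_csv(out / "probe_cluster_merges.tsv", sep="\t", index=False)
            regions = methylation.aggregate_regions(meth, meth_cohort, annotation)
            pd.DataFrame([vars(r) for r in regions]).to_csv(
                out / "region_methylation.tsv", sep="\t", index=False
            )
            summary["methylation"] = {
                "n_probes_selected": len(selected),
                "regions": {
                    r.region_label: {
                        "mean_delta_beta": r.mean_delta_beta,
                        "direction": r.direction,
                    }
                    for r in regions
                },
            }
            if corr_probe is not None:
                r_, p_, n_ = methylation.meth_expr_correlation(
                    meth, expr, corr_probe, marker
                )
                summary["methylation"]["meth_expr_pearson_r"] = r_
                summary["methylation"]["meth_expr_pearson_p"] = p_
                summary["methylation"]["meth_expr_n"] = n_

        # ---- ROC / correlated AUC comparison -------------------------
        if "roc" in config.stages:
            tumors = expr.samples_where(tissue="tumor")
            normals = expr.samples_where(tissue="normal")
            row = expr.feature(marker)
            res = roc.empirical_auc(row[tumors], row[normals])
            pts = roc.roc_curve_points(row[tumors], row[normals])
            pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
                out / "roc_curve_marker.tsv", sep="\t", index=False
            )
            summary["roc"] = {
                "marker_auc": res.auc,
                "marker_auc_se": res.se,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
            }
            if meth is not None and annotation is not None:
                mt = [s for s in meth.sample_ids
                      if meth.sample_meta.loc[s, "tissue"] == "tumor"]
                mn = [s for s in meth.sample_ids
                      if meth.sample_meta.loc[s, "tissue"] == "normal"]
                cmp_ = roc.compare_auc(
                    _promoter_scores(meth, annotation, "beta_promoter", mt),
                    _promoter_scores(meth, annotation, "beta_promoter", mn),
                    _promoter_scores(meth, annotation, "alpha_promoter", mt),
                    _promoter_scores(meth, annotation, "alpha_promoter", mn),
                    r_mode=config.r_mode,
                )
                summary["roc"]["promoter_comparison"] = {
                    "beta_promoter_auc": cmp_.auc1,
                    "beta_promoter_se": cmp_.se1,
                    "alpha_promoter_auc": cmp_.auc2,
                    "alpha_promoter_se": cmp_.se2,
                    "avg_tau": cmp_.avg_tau,
                    "hm_r": cmp_.r,
                    "z": cmp_.z,
                    "significant": cmp_.significant,
                }

        # ---- survival -------------------------------------------------
        if "survival" in config.stages:
            sres = survival.survival_strata(
                expr, clinical, config.survival_marker, pct=config.pct
            )
            for name, km in (("high", sres.km_high), ("low", sres.km_low)):
                pd.DataFrame(
                    {
                        "time": km.times,
                        "survival": km.survival,
                        "n_at_risk": km.n_at_risk,
                    }
                ).to_csv(out / f"km_{name}.tsv", sep="\t", index=False)
            summary["survival"] = {
                "marker": config.survival_marker,
                "logrank_chi2": sres.logrank_chi2,
                "logrank_p": sres.logrank_p,
                "wilcoxon_chi2": sres.wilcoxon_chi2,
                "wilcoxon_p": sres.wilcoxon_p,
                "median_high": sres.median_high,
                "median_low": sres.median_low,
                "median_difference": sres.median_difference,
                "n_high": len(sres.high_ids),
                "n_low": len(sres.low_ids),
            }

        # ---- IHC ------------------------------------------------------
        if "ihc" in config.stages and ihc_table is not None:
            scored = ihc.score_table(ihc_table)
            scored.to_csv(out / "ihc_scored.tsv", sep="\t", index=False)
            table = ihc.staining_contingency(scored, stained_if=config.ihc_stained_if)
            chi2, df_, p, n = ihc.chi_square_staining(table.to_numpy())
            pairwise = ihc.groupwise_score_test(scored, by="stage")
            pairwise.to_csv(out / "ihc_groupwise.tsv", sep="\t", index=False)
            tum = scored.loc[scored["diagnosis"] == "tumor", "composite"]
            nrm = scored.loc[scored["diagnosis"] == "normal", "composite"]
            summary["ihc"] = {
                "chi2": chi2,
                "df": df_,
                "p": p,
                "n": n,
                "mean_composite_tumor": float(tum.mean()),
                "mean_composite_normal": float(nrm.mean()),
            }
    except Exception as exc:
        manifest = _manifest(out, complete=False, failed_stage=str(exc))
        write_json(manifest, out / "MANIFEST.json")
        raise

    write_json(summary, out / "summary.json")
    write_json(_manifest(out, complete=True), out / "MANIFEST.json")
    return out


def _manifest(out: Path, complete: bool, failed_stage: str | None = None) -> dict:
    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "MANIFEST.json"
    )
    entry = {
        "complete": complete,
        "files": {name: _sha256(out / name) for name in files},
    }
    if failed_stage:
        entry["error"] = failed_stage
    return entry
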