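"""Synthetic paired tumor/normal cohorts and assay images with known truth.

The cohort generator emulates the statistical structure of a kidney-cancer
RNA-Seq + 450k-methylation cohort: per-patient paired tumor overexpression
of a marker gene (with a small non-overexpressing fraction), promoter
hypomethylation on the beta scale, a designated probe whose methylation is
negatively coupled to marker expression, stage labels, and exponential
survival whose hazard depends on marker quartile.  Every emitted quantity
is recorded in a :class:`SyntheticTruth` so downstream stages can be tested
for parameter recovery without external data.

Expression noise is log-normal (multiplicative on the abundance scale);
methylation noise is Gaussian on the beta scale, clipped to [0, 1].  The
methylation–expression coupling uses a shared latent Gaussian factor: with
z the standardized log2 marker expression and eps an independent standard
normal, the designated probe's beta is

    beta = clip(0.5 + c * (rho * z + sqrt(1 - rho^2) * eps), 0, 1)

which has Pearson correlation rho with log2 expression in expectation
(c = 0.08 keeps clipping negligible).

A single global seed drives everything; sub-generators derive child
streams via ``numpy.random.SeedSequence.spawn`` so adding an output does
not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import FeatureMatrix, Pair, PairedCohort

MARKER = "MARKER"
#: features emitted beyond the marker: two promoter-driven isoforms, the
#: EMT panel (mesenchymal up, epithelial down), then background genes
NAMED_FEATURES_LOG2FC = {
    MARKER: None,  # filled from config
    "MARKER_ISO1": None,  # alpha-promoter isoform, tracks the marker
    "MARKER_ISO4": None,  # beta-promoter isoform, tracks the marker
    "VIM": 1.0,
    "CDH2": 0.7,
    "CDH1": -1.0,
}
N_BACKGROUND_GENES = 20
BASELINE_LOG2_MEAN = 8.0  # ~256 on the abundance scale
BETA_COUPLING_SCALE = 0.08
GLOBAL_BETA_OFFSET_SD = 0.02  # per-sample purity/composition offset
SURVIVAL_HORIZON_DAYS = 3650.0
BASE_MEDIAN_SURVIVAL_DAYS = 1500.0
METASTASIS_FOLD = 1.3  # extra marker fold in tumors of metastatic patients


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults are the study
    conditions the downstream tests assume."""

    n_pairs: int = 72
    n_unpaired_tumors: int = 88
    marker_log2fc: float = 2.0
    frac_non_overexpressing: float = 5.0 / 72.0
    n_probes_promoter_alpha: int = 8
    n_probes_promoter_beta: int = 6
    n_probes_background: int = 20
    delta_beta_promoter: float = -0.15
    meth_expr_corr_target: float = -0.25
    noise_sd_expr: float = 0.5  # log2-scale sd, baseline and tumor noise
    noise_sd_beta: float = 0.05
    patient_effect_sd_beta: float = 0.12  # per-patient tumor methylation shift
    hazard_ratio_highlow: float = 2.0
    censor_rate: float = 0.6
    stage_probs: tuple[float, float, float, float] = (0.50, 0.11, 0.23, 0.16)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 4:
            raise ConfigurationError("n_pairs must be >= 4")
        if self.n_unpaired_tumors < 0:
            raise ConfigurationError("n_unpaired_tumors must be >= 0")
        for name in ("frac_non_overexpressing", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_probes_promoter_alpha",
            "n_probes_promoter_beta",
            "n_probes_background",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.hazard_ratio_highlow > 0:
            raise ConfigurationError("hazard_ratio_highlow must be > 0")
        if not -1.0 <= self.meth_expr_corr_target <= 1.0:
            raise ConfigurationError("meth_expr_corr_target must be in [-1, 1]")
        if self.noise_sd_expr < 0 or self.noise_sd_beta < 0:
            raise ConfigurationError("noise sds must be >= 0")
        if self.patient_effect_sd_beta < 0:
            raise ConfigurationError("patient_effect_sd_beta must be >= 0")
        if len(self.stage_probs) != 4 or any(p < 0 for p in self.stage_probs):
            raise ConfigurationError("stage_probs must be 4 non-negative values")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigurationError("stage_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    gene_log2fc: dict[str, float]
    probe_delta_beta: dict[str, float]
    non_overexpressing_pairs: list[str]
    hazard_ratio_highlow: float
    correlated_probe_id: str
    meth_expr_corr_target: float


@dataclass
class SyntheticCohort:
    expression: FeatureMatrix
    methylation: FeatureMatrix
    annotation: pd.DataFrame  # BED-like: chrom, start, end, probe_id, region_label
    clinical: pd.DataFrame
    truth: SyntheticTruth
    cohort: PairedCohort


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one paired cohort (expression, methylation, clinical, truth).

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng_expr, rng_meth, rng_clin = _child_rngs(config.seed, 3)

    n_pairs, n_unp = config.n_pairs, config.n_unpaired_tumors
    n_patients = n_pairs + n_unp
    patient_ids = [f"P{i:04d}" for i in range(n_patients)]
    paired_patients = patient_ids[:n_pairs]

    pairs = [Pair(pid, f"{pid}-T", f"{pid}-N") for pid in paired_patients]
    cohort = PairedCohort(pairs)
    tumor_ids = [f"{pid}-T" for pid in patient_ids]
    normal_ids = [f"{pid}-N" for pid in paired_patients]
    sample_ids = tumor_ids + normal_ids

    # --- clinical covariates -------------------------------------------
    stages = rng_clin.choice(
        ["I", "II", "III", "IV"], size=n_patients, p=list(config.stage_probs)
    )
    metastasis = np.where(stages == "IV", "yes", "no")

    # --- designated non-overexpressing pairs ---------------------------
    n_non = round(config.frac_non_overexpressing * n_pairs)
    non_over_idx = rng_expr.choice(n_pairs, size=n_non, replace=False) if n_non else []
    non_over = sorted(paired_patients[i] for i in np.asarray(non_over_idx, dtype=int))

    # --- expression ----------------------------------------------------
    gene_fc = dict(NAMED_FEATURES_LOG2FC)
    gene_fc[MARKER] = config.marker_log2fc
    gene_fc["MARKER_ISO1"] = config.marker_log2fc
    gene_fc["MARKER_ISO4"] = config.marker_log2fc
    for i in range(N_BACKGROUND_GENES):
        gene_fc[f"GENE{i + 1:03d}"] = 0.0
    features = list(gene_fc)

    sd = config.noise_sd_expr
    expr = np.empty((len(features), len(sample_ids)))
    non_over_set = set(non_over)
    for gi, gene in enumerate(features):
        base = BASELINE_LOG2_MEAN + sd * rng_expr.standard_normal(n_patients)
        fc = np.full(n_patients, gene_fc[gene])
        if gene in (MARKER, "MARKER_ISO1", "MARKER_ISO4"):
            flip = np.array([pid in non_over_set for pid in patient_ids])
            fc = np.where(flip, -fc, fc)
        if gene == MARKER:
            fc = fc + np.where(metastasis == "yes", math.log2(METASTASIS_FOLD), 0.0)
        tum_log2 = base + fc + sd * rng_expr.standard_normal(n_patients)
        expr[gi, :n_patients] = 2.0**tum_log2
        expr[gi, n_patients:] = 2.0 ** base[:n_pairs]

    # --- survival driven by marker quartile ----------------------------
    marker_tumor = pd.Series(expr[features.index(MARKER), :n_patients],
                             index=patient_ids)
    quart = pd.qcut(marker_tumor.rank(method="first"), 4, labels=False).to_numpy()
    base_rate = math.log(2.0) / BASE_MEDIAN_SURVIVAL_DAYS
    rates = base_rate * config.hazard_ratio_highlow ** (quart / 3.0)
    death = rng_clin.exponential(1.0 / rates)
    u = rng_clin.uniform(size=n_patients)
    drop_frac = rng_clin.uniform(size=n_patients)
    times = death.copy()
    events = np.ones(n_patients, dtype=int)
    dropout = u < config.censor_rate
    times[dropout] = np.maximum(death[dropout] * drop_frac[dropout], 1e-6)
    events[dropout] = 0
    over_horizon = times > SURVIVAL_HORIZON_DAYS
    times[over_horizon] = SURVIVAL_HORIZON_DAYS
    events[over_horizon] = 0

    surv = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "stage": stages,
            "metastasis": metastasis,
            "survival_days": times,
            "vital_status": np.where(events == 1, "deceased", "alive"),
        }
    )

    meta_rows = []
    for sid in sample_ids:
        pid, tissue = sid.rsplit("-", 1)
        prow = surv.loc[surv["patient_id"] == pid].iloc[0]
        meta_rows.append(
            {
                "sample_id": sid,
                "patient_id": pid,
                "tissue": "tumor" if tissue == "T" else "normal",
                "stage": prow["stage"],
                "metastasis": prow["metastasis"],
                "survival_days": prow["survival_days"],
                "vital_status": prow["vital_status"],
            }
        )
    clinical = pd.DataFrame(meta_rows)
    sample_meta = clinical.set_index("sample_id")

    expression = FeatureMatrix(
        values=pd.DataFrame(expr, index=features, columns=sample_ids),
        sample_meta=sample_meta,
    )

    # --- methylation (paired samples only) -----------------------------
    meth_samples = [p.tumor_sample_id for p in pairs] + [
        p.normal_sample_id for p in pairs
    ]
    probes, regions, deltas = [], [], []

    n_a = config.n_probes_promoter_alpha
    alpha_deltas = np.full(n_a, config.delta_beta_promoter)
    if n_a >= 2:
        # one alpha sub-region runs against the promoter-wide trend
        alpha_deltas[0] = abs(config.delta_beta_promoter) / 3.0
        alpha_deltas[1:] = (
            config.delta_beta_promoter * n_a - alpha_deltas[0]
        ) / (n_a - 1)
    for i, d in enumerate(alpha_deltas):
        probes.append(f"probe_alpha_{i + 1:02d}")
        regions.append("alpha_promoter")
        deltas.append(float(d))
    for i in range(config.n_probes_promoter_beta):
        probes.append(f"probe_beta_{i + 1:02d}")
        regions.append("beta_promoter")
        deltas.append(config.delta_beta_promoter)
    corr_probe = "probe_body_corr"
    probes.append(corr_probe)
    regions.append("body")
    deltas.append(0.0)
    for i in range(config.n_probes_background):
        probes.append(f"probe_bg_{i + 1:03d}")
        regions.append("background")
        deltas.append(0.0)

    baseline_beta = rng_meth.uniform(0.40, 0.70, size=len(probes))

    # per-patient tumor methylation effects, shared across a region's probes:
    # tumors differ in how much promoter methylation they lose.  The alpha
    # region is twice as heterogeneous as the beta region (making it the
    # markedly weaker biomarker of the two; much wider and clipping at the
    # beta-value bounds would bias the region means) and the regions share
    # a common factor, so their per-sample scores are positively correlated.
    s = config.patient_effect_sd_beta
    shared = rng_meth.normal(0.0, 0.6 * s, size=n_pairs)
    eff_alpha = shared + rng_meth.normal(
        0.0, math.sqrt(max((2.0 * s) ** 2 - (0.6 * s) ** 2, 0.0)), size=n_pairs
    )
    eff_beta = shared + rng_meth.normal(
        0.0, math.sqrt(max(s**2 - (0.6 * s) ** 2, 0.0)), size=n_pairs
    )
    region_effect = {"alpha_promoter": eff_alpha, "beta_promoter": eff_beta}

    # a small global per-sample offset (tissue composition / purity) that
    # moves every probe of a sample together, tumor and normal alike
    global_offset = GLOBAL_BETA_OFFSET_SD * rng_meth.standard_normal(len(meth_samples))

    beta = np.empty((len(probes), len(meth_samples)))
    for pi in range(len(probes)):
        noise = config.noise_sd_beta * rng_meth.standard_normal(len(meth_samples))
        shift = np.zeros(len(meth_samples))
        shift[:n_pairs] = deltas[pi]  # tumors first
        shift[:n_pairs] += region_effect.get(regions[pi], 0.0)
        beta[pi] = baseline_beta[pi] + shift + global_offset + noise

    # couple the designated probe to log2 marker expression
    marker_log2 = np.log2(
        expression.values.loc[MARKER, meth_samples].to_numpy(dtype=float)
    )
    z = (marker_log2 - marker_log2.mean()) / (marker_log2.std() or 1.0)
    rho = config.meth_expr_corr_target
    eps = rng_meth.standard_normal(len(meth_samples))
    beta[probes.index(corr_probe)] = 0.5 + BETA_COUPLING_SCALE * (
        rho * z + math.sqrt(max(1.0 - rho**2, 0.0)) * eps
    )
    beta = np.clip(beta, 0.0, 1.0)

    methylation = FeatureMatrix(
        values=pd.DataFrame(beta, index=probes, columns=meth_samples),
        sample_meta=sample_meta.loc[meth_samples],
    )

    # BED-like annotation: alpha/beta promoter blocks then body/background
    pos = {
        "alpha_promoter": 36700000,
        "beta_promoter": 36650000,
        "body": 36553414,
        "background": 1000000,
    }
    ann_rows = []
    counters = dict.fromkeys(pos, 0)
    for probe, region in zip(probes, regions):
        start = pos[region] + 500 * counters[region]
        counters[region] += 1
        chrom = "chr13" if region != "background" else f"chr{1 + counters[region] % 22}"
        ann_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + 2,
                "probe_id": probe,
                "region_label": region,
            }
        )
    annotation = pd.DataFrame(ann_rows)

    truth = SyntheticTruth(
        gene_log2fc={g: float(fc) for g, fc in gene_fc.items()},
        probe_delta_beta=dict(zip(probes, map(float, deltas))),
        non_overexpressing_pairs=non_over,
        hazard_ratio_highlow=config.hazard_ratio_highlow,
        correlated_probe_id=corr_probe,
        meth_expr_corr_target=config.meth_expr_corr_target,
    )
    return SyntheticCohort(expression, methylation, annotation, clinical, truth, cohort)


# ---------------------------------------------------------------------------
# IHC table generator
# ---------------------------------------------------------------------------

#: per-stratum categorical distributions over (percent category, intensity);
#: chosen so the mean tumor composite is ~2x the mean normal composite and
#: stage II/III sections score above stage I
_IHC_DISTS = {
    "normal": {"pc": (0.40, 0.40, 0.20, 0.00), "ic": (0.40, 0.40, 0.20, 0.00)},
    "I": {"pc": (0.15, 0.40, 0.35, 0.10), "ic": (0.10, 0.45, 0.40, 0.05)},
    "II": {"pc": (0.15, 0.40, 0.35, 0.10), "ic": (0.00, 0.25, 0.50, 0.25)},
    "III": {"pc": (0.15, 0.40, 0.35, 0.10), "ic": (0.00, 0.25, 0.50, 0.25)},
    "IV": {"pc": (0.15, 0.40, 0.35, 0.10), "ic": (0.00, 0.25, 0.50, 0.25)},
}
_PC_BINS = ((0.0, 10.0), (10.0, 35.0), (35.0, 60.0), (60.0, 100.0))


def generate_ihc_table(
    n_normal: int = 20,
    stage_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic pathologist-scored IHC table (one row per micro-section).

    Defaults mirror a 192-section tissue microarray (20 normal, 64/76/30/2
    stage I–IV tumors).  Percent-stained values are drawn uniformly inside
    the sampled percent category's bin, so category recovery is exact.
    """
    stage_counts = stage_counts or {"I": 64, "II": 76, "III": 30, "IV": 2}
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    rows = []
    strata = [("normal", "NA")] * n_normal + [
        ("tumor", st) for st, k in stage_counts.items() for _ in range(k)
    ]
    for i, (diagnosis, stage) in enumerate(strata):
        d = _IHC_DISTS["normal" if diagnosis == "normal" else stage]
        pc = int(rng.choice(4, p=d["pc"])) + 1
        ic = int(rng.choice(4, p=d["ic"])) + 1
        lo, hi = _PC_BINS[pc - 1]
        pct = float(rng.uniform(lo, hi - 1e-9))
        rows.append(
            {
                "section_id": f"S{i + 1:03d}",
                "diagnosis": diagnosis,
                "stage": stage,
                "grade": "NA" if diagnosis == "normal" else str(int(rng.integers(1, 4))),
                "percent_stained": pct,
                "intensity": ic,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Assay image generators
# ---------------------------------------------------------------------------

BG_LEVEL_16 = 5000
FG_LEVEL_16 = 40000
DEFAULT_IMAGE_NOISE_SD = 1500.0


@dataclass
class ImageParams:
    """Shared geometry/noise parameters of the image generators."""

    width: int = 1280
    height: int = 960
    noise_sd: float = DEFAULT_IMAGE_NOISE_SD
    bit_depth: int = 16

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("image dimensions must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class CellFieldParams(ImageParams):
    n_cells: int = 150
    radius_min: int = 8
    radius_max: int = 16


@dataclass
class WoundPairParams(ImageParams):
    wound_frac: float = 0.30  # baseline wound width / image width
    remaining_frac: float = 0.5  # follow-up wound width / baseline width

    def validate(self) -> None:
        super().validate()
        if not 0.0 < self.wound_frac <= 1.0:
            raise ConfigurationError("wound_frac must be in (0, 1]")
        if not 0.0 <= self.remaining_frac <= 1.0:
            raise ConfigurationError("remaining_frac must be in [0, 1]")


@dataclass
class ColonyPlateParams(ImageParams):
    n_colonies: int = 10
    radius: int = 10


def _finalize(canvas: np.ndarray, params: ImageParams,
              rng: np.random.Generator) -> np.ndarray:
    if params.noise_sd > 0:
        canvas = canvas + params.noise_sd * rng.standard_normal(canvas.shape)
    hi = 2**params.bit_depth - 1
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return np.clip(np.round(canvas), 0, hi).astype(dtype)


def _disk_mask(shape: tuple[int, int], cx: int, cy: int, r: int) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def generate_assay_images(kind: str, params=None, seed: int = 0):
    """Generate grayscale assay image(s) with a ground-truth record.

    ``kind`` is ``cell_field`` (adhesion/intercellular-space fields),
    ``wound_pair`` (scratch-assay baseline + follow-up) or
    ``colony_plate`` (disjoint colonies).  Returns (list of
    :class:`~dysmark.assays.AssayImage`, truth dict).
    """
    from .assays import AssayImage  # local import to avoid a cycle

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    if kind == "cell_field":
        params = params or CellFieldParams()
        params.validate()
        shape = (params.height, params.width)
        mask = np.zeros(shape, dtype=bool)
        placed = []
        for _ in range(params.n_cells):
            r = int(rng.integers(params.radius_min, params.radius_max + 1))
            cx = int(rng.integers(0, params.width))
            cy = int(rng.integers(0, params.height))
            mask |= _disk_mask(shape, cx, cy, r)
            placed.append((cx, cy, r))
        canvas = np.where(mask, FG_LEVEL_16, BG_LEVEL_16).astype(float)
        img = AssayImage(_finalize(canvas, params, rng), params.bit_depth)
        from skimage.measure import label as _label

        truth = {
            "occupied_px": int(mask.sum()),
            "unoccupied_px": int(mask.size - mask.sum()),
            "n_cells_drawn": params.n_cells,
            "n_components": int(_label(mask, connectivity=2).max()),
            "cells": placed,
        }
        return [img], truth

    if kind == "wound_pair":
        params = params or WoundPairParams()
        params.validate()
        shape = (params.height, params.width)
        w_base = max(int(round(params.wound_frac * params.width)), 1)
        w_follow = int(round(w_base * params.remaining_frac))
        imgs, areas = [], []
        for w in (w_base, w_follow):
            canvas = np.full(shape, FG_LEVEL_16, dtype=float)
            if w > 0:
                lo = (params.width - w) // 2
                canvas[:, lo : lo + w] = BG_LEVEL_16
            areas.append(w * params.height)
            imgs.append(AssayImage(_finalize(canvas, params, rng), params.bit_depth))
        truth = {
            "baseline_wound_px": areas[0],
            "followup_wound_px": areas[1],
            "true_relative_remaining": areas[1] / areas[0],
        }
        return imgs, truth

    if kind == "colony_plate":
        params = params or ColonyPlateParams()
        params.validate()
        shape = (params.height, params.width)
        r = params.radius
        # jittered grid placement keeps colonies pairwise disjoint
        step = 2 * r + 6
        cols = max((params.width - 2 * r - 2) // step, 1)
        rows_n = max((params.height - 2 * r - 2) // step, 1)
        if params.n_colonies > cols * rows_n:
            raise ConfigurationError(
                f"cannot place {params.n_colonies} disjoint colonies of radius {r}"
            )
        cells = rng.choice(cols * rows_n, size=params.n_colonies, replace=False)
        mask = np.zeros(shape, dtype=bool)
        per_colony = []
        for c in np.sort(cells):
            gy, gx = divmod(int(c), cols)
            cx = r + 1 + gx * step + int(rng.integers(0, 3))
            cy = r + 1 + gy * step + int(rng.integers(0, 3))
            d = _disk_mask(shape, cx, cy, r)
            per_colony.append(int(d.sum()))
            mask |= d
        canvas = np.where(mask, FG_LEVEL_16, BG_LEVEL_16).astype(float)
        img = AssayImage(_finalize(canvas, params, rng), params.bit_depth)
        truth = {
            "count": params.n_colonies,
            "per_colony_px": per_colony,
            "total_px": int(mask.sum()),
        }
        return [img], truth

    raise ConfigurationError(f"unknown image kind: {kind!r}")


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["stage_probs"] = list(d["stage_probs"])
    return d
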