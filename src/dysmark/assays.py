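"""Quantification of cell-based assay readouts.

Image metrics follow the ImageJ analyze-particles workflow: threshold a
grayscale field (Otsu by default), label 8-connected components, and
report per-particle pixel areas in µm² (1 px = 1 µm at the 4× / 1280×960
acquisition these assays use, so areas default to px² = µm²).  On top of
that sit the scalar assay statistics: unoccupied intercellular space,
relative wound area remaining, colony count/size, normalization to a
scrambled-siRNA control, ΔΔCt qPCR fold changes, and densitometry ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import DegenerateDataError, NoWoundError


@dataclass
class AssayImage:
    """2-D grayscale assay image with a physical pixel size."""

    pixels: np.ndarray
    bit_depth: int = 16
    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError("pixel values exceed the stated bit depth")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.size) * self.microns_per_pixel**2


@dataclass
class Particle:
    id: int
    pixel_area: int
    centroid: tuple[float, float]


@dataclass
class ParticleSet:
    particles: list[Particle] = field(default_factory=list)
    total_area_um2: float = 0.0
    image_area_um2: float = 0.0

    @property
    def count(self) -> int:
        return len(self.particles)


def threshold_image(img: AssayImage, method: str = "otsu",
                    value: float | None = None) -> np.ndarray:
    """Binary foreground mask: pixels strictly above the threshold.

    ``otsu`` maximizes between-class variance on the histogram; ``fixed``
    uses the supplied ``value``.  A constant image has no Otsu threshold
    (degenerate-threshold error); fixed mode still works.
    """
    px = img.pixels
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding needs a value")
        return px > value
    if method != "otsu":
        raise ValueError("method must be 'otsu' or 'fixed'")
    if px.min() == px.max():
        raise DegenerateDataError("constant image: Otsu threshold undefined")
    return px > threshold_otsu(px)


def analyze_particles(
    mask: np.ndarray,
    min_area_px: int = 1,
    connectivity: int = 8,
    microns_per_pixel: float = 1.0,
) -> ParticleSet:
    """Connected components of a binary mask, ImageJ-style.

    8-connectivity by default (diagonal touch joins); components smaller
    than ``min_area_px`` are discarded.  Areas are pixel counts scaled by
    microns_per_pixel².
    """
    mask = np.asarray(mask, dtype=bool)
    conn = {4: 1, 8: 2}[connectivity]
    labeled = label(mask, connectivity=conn)
    scale = microns_per_pixel**2
    particles = [
        Particle(id=p.label, pixel_area=int(p.area), centroid=tuple(p.centroid))
        for p in regionprops(labeled)
        if p.area >= min_area_px
    ]
    total = sum(p.pixel_area for p in particles) * scale
    return ParticleSet(
        particles=particles,
        total_area_um2=float(total),
        image_area_um2=float(mask.size) * scale,
    )


def intercellular_space(
    img: AssayImage,
    method: str = "otsu",
    value: float | None = None,
    min_area_px: int = 1,
) -> float:
    """Unoccupied intercellular area in µm²: total image area minus the
    summed area of all thresholded particles (cells)."""
    mask = threshold_image(img, method=method, value=value)
    ps = analyze_particles(
        mask, min_area_px=min_area_px, microns_per_pixel=img.microns_per_pixel
    )
    return img.area_um2 - ps.total_area_um2


def _wound_area_px(img: AssayImage, threshold: float) -> int:
    """Pixel area of the wound: the largest cell-free (background)
    connected component at the given fixed threshold."""
    cells = img.pixels > threshold
    bg = label(~cells, connectivity=2)
    if bg.max() == 0:
        return 0
    areas = np.bincount(bg.ravel())[1:]
    return int(areas.max())


def wound_area_remaining(
    baseline: AssayImage,
    followups: list[AssayImage],
    method: str = "otsu",
    value: float | None = None,
) -> list[float]:
    """Relative wound area remaining at each follow-up timepoint.

    One threshold is derived from the baseline image (Otsu by default)
    and applied to every timepoint, so a fully healed, uniformly
    confluent follow-up is still scored.  The wound is the largest
    cell-free component of each thresholded image; each follow-up area
    is divided by the baseline area (floored at 0 for reporting).  A
    baseline with no detectable wound is an error.
    """
    for f in followups:
        if f.pixels.shape != baseline.pixels.shape:
            raise ValueError("follow-up images must match the baseline dimensions")
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding needs a value")
        thr = float(value)
    elif method == "otsu":
        px = baseline.pixels
        if px.min() == px.max():
            raise NoWoundError("baseline image is constant: no wound detectable")
        thr = float(threshold_otsu(px))
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")
    base = _wound_area_px(baseline, thr)
    if base == 0:
        raise NoWoundError("baseline image has no detectable wound region")
    return [max(_wound_area_px(f, thr) / base, 0.0) for f in followups]


def normalize_to_control(values, control_values, as_percent: bool = True):
    """Normalize assay readouts to the mean of a control group.

    Serves invasion counts, resazurin fluorescence, colony metrics, and
    Western densitometry ratios alike; ``as_percent`` multiplies by 100
    (the %-of-scrambled-control convention).
    """
    ctrl = np.asarray(control_values, dtype=float)
    vals = np.asarray(values, dtype=float)
    cm = ctrl.mean()
    if not cm > 0:
        raise DegenerateDataError("control mean must be positive")
    out = vals / cm
    return (out * 100.0).tolist() if as_percent else out.tolist()


def colony_metrics(
    plate: AssayImage | ParticleSet,
    min_area_px: int = 1,
    method: str = "otsu",
    value: float | None = None,
) -> tuple[int, float | None]:
    """Colony count and mean colony area in µm² (None for an empty plate)."""
    if isinstance(plate, AssayImage):
        mask = threshold_image(plate, method=method, value=value)
        ps = analyze_particles(
            mask, min_area_px=min_area_px, microns_per_pixel=plate.microns_per_pixel
        )
    else:
        ps = ParticleSet(
            particles=[p for p in plate.particles if p.pixel_area >= min_area_px],
            image_area_um2=plate.image_area_um2,
        )
        ps.total_area_um2 = float(sum(p.pixel_area for p in ps.particles))
    if ps.count == 0:
        return 0, None
    return ps.count, ps.total_area_um2 / ps.count


@dataclass
class DdctResult:
    fold_change: float
    ddct: float
    sem_log2: float  # SEM of −ΔΔCt, propagated on the log2 scale


def ddct_fold_change(
    ct_target_treated,
    ct_ref_treated,
    ct_target_control,
    ct_ref_control,
) -> DdctResult:
    """Relative qPCR quantification: fold = 2^−ΔΔCt.

    ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control.
    Arguments may be scalars or replicate vectors; replicates are averaged
    on the Ct scale and their SEMs combined in quadrature on the log2
    scale (amplification efficiency fixed at 2.0).
    """
    groups = [
        np.atleast_1d(np.asarray(g, dtype=float))
        for g in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    ]
    if any(not np.all(np.isfinite(g)) for g in groups):
        raise ValueError("all Ct values must be finite")
    means = [g.mean() for g in groups]
    sems = [
        g.std(ddof=1) / math.sqrt(len(g)) if len(g) > 1 else 0.0 for g in groups
    ]
    ddct = (means[0] - means[1]) - (means[2] - means[3])
    sem = math.sqrt(sum(s**2 for s in sems))
    return DdctResult(fold_change=2.0 ** (-ddct), ddct=float(ddct), sem_log2=sem)
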