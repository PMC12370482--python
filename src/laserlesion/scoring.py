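"""Automated binary lesion scoring and well-exclusion quality control.

Photochemical positives need an identifiably circular cluster of at least
five dead cells centred in, and not exceeding, the beam footprint.
Photothermal positives need a contiguous central dead region; a sublethal
halo without central red staining is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import QCError
from .fileio import TwoChannelImage
from .synthetic import BeamProfile

__all__ = [
    "ScoreReport",
    "ScoringConfig",
    "detect_dead_cells",
    "score_photochemical",
    "score_photothermal",
    "qc_exclusion",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Quantified proxies for the qualitative scoring criteria.

    All cutoffs are documented choices (the original scoring was a human
    two-scorer consensus); they are validated only against generator truth.
    """

    min_dead_cells: int = 5
    central_radius_fraction: float = 0.5
    min_circularity: float = 0.6
    footprint_tolerance: float = 1.05
    red_mad_factor: float = 5.0
    nucleus_area_um2: tuple[float, float] = (20.0, 400.0)
    nominal_nucleus_area_um2: float = 110.0
    min_region_cell_areas: float = 10.0
    nominal_cell_area_um2: float = 500.0
    saturation_level: float = 0.95 * 65535.0
    monolayer_min_coverage: float = 0.6
    foreign_object_nucleus_areas: float = 10.0


@dataclass
class ScoreReport:
    outcome: str                 # positive | negative | excluded
    phenotype: str               # photothermal | photochemical
    dead_cell_count_in_footprint: int = 0
    damage_extent_diameter: float = 0.0  # µm
    circularity: float = 0.0
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dead-cell detection
# ---------------------------------------------------------------------------

def detect_dead_cells(
    img: TwoChannelImage, config: ScoringConfig = ScoringConfig()
) -> list[tuple[float, float]]:
    """Centroids of red-nucleus connected components.

    Threshold = median + ``red_mad_factor`` × 1.4826·MAD of the red
    channel; components are kept if their area falls in the configured
    nucleus-scale window (µm², converted with the pixel pitch).
    """
    from skimage.feature import peak_local_max

    red = np.asarray(img.red, dtype=float)
    med = np.median(red)
    mad = 1.4826 * np.median(np.abs(red - med))
    thr = med + config.red_mad_factor * max(mad, 1e-12)
    if (red >= config.saturation_level).mean() >= 0.5:
        raise QCError("red channel saturated over >= 50% of the frame")
    above = red > thr
    if not above.any():
        return []
    labels, n = ndimage.label(above, structure=np.ones((3, 3), dtype=bool))
    px_area = img.pixel_pitch ** 2
    lo = config.nucleus_area_um2[0] / px_area
    hi = config.nucleus_area_um2[1] / px_area
    areas = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))

    centroids: list[tuple[float, float]] = []
    singles = np.nonzero((areas >= lo) & (areas <= hi))[0] + 1
    if singles.size:
        centroids.extend(
            tuple(c) for c in
            ndimage.center_of_mass(above, labels, index=singles)
        )
    # touching nuclei merge into one component; split by intensity peaks
    merged = np.nonzero(areas > hi)[0] + 1
    if merged.size:
        smooth = ndimage.gaussian_filter(red, 1.0)
        nucleus_px = math.sqrt(config.nucleus_area_um2[1] / math.pi) \
            / img.pixel_pitch
        sel = np.isin(labels, merged)
        peaks = peak_local_max(
            smooth, min_distance=max(int(round(nucleus_px)), 1),
            labels=labels * sel, exclude_border=False,
        )
        centroids.extend((float(r), float(c)) for r, c in peaks)
    return centroids


def _beam_center_px(img: TwoChannelImage, beam: BeamProfile):
    if beam.center is not None:
        return beam.center
    meta = img.metadata.get("beam_center")
    if meta is not None:
        return tuple(meta)
    return ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)


def _hull_stats(points_um: np.ndarray):
    """(circularity 4πA/P², max diameter µm) of the convex hull."""
    if len(points_um) < 3:
        return 0.0, 0.0
    try:
        hull = ConvexHull(points_um)
    except QhullError:  # collinear
        span = points_um.max(axis=0) - points_um.min(axis=0)
        return 0.0, float(np.hypot(*span))
    area = hull.volume  # 2-D: volume is area, area is perimeter
    perim = hull.area
    circ = 4.0 * math.pi * area / (perim ** 2) if perim > 0 else 0.0
    verts = points_um[hull.vertices]
    diffs = verts[:, None, :] - verts[None, :, :]
    diam = float(np.sqrt((diffs ** 2).sum(axis=2)).max())
    return circ, diam


# ---------------------------------------------------------------------------
# phenotype scorers
# ---------------------------------------------------------------------------

def score_photochemical(
    img: TwoChannelImage,
    beam: BeamProfile,
    config: ScoringConfig = ScoringConfig(),
) -> ScoreReport:
    """Positive iff >= ``min_dead_cells`` dead cells sit centrally, their
    hull is identifiably circular, and it does not exceed the footprint."""
    center = _beam_center_px(img, beam)
    centroids = np.asarray(detect_dead_cells(img, config), dtype=float)
    reasons: list[str] = []

    if centroids.size == 0:
        return ScoreReport(outcome="negative", phenotype="photochemical",
                           reasons=["no dead cells"])

    r_um = np.hypot(centroids[:, 0] - center[0],
                    centroids[:, 1] - center[1]) * img.pixel_pitch
    in_fp = r_um <= beam.radius
    central = r_um <= beam.radius * config.central_radius_fraction
    n_central = int(central.sum())
    n_in = int(in_fp.sum())

    fp_points_um = centroids[in_fp] * img.pixel_pitch
    circ, diam = _hull_stats(fp_points_um)

    if n_central < config.min_dead_cells:
        reasons.append("min dead cells")
    if circ < config.min_circularity and n_central >= config.min_dead_cells:
        reasons.append("not circular")
    # the lesion exceeds the footprint when substantially more dead cells
    # sit in the surrounding annulus than spontaneous background explains
    annulus = (r_um > beam.radius * config.footprint_tolerance) & (
        r_um <= 2.0 * beam.radius)
    n_out = int(annulus.sum())
    if n_out >= max(config.min_dead_cells, 0.2 * n_in):
        reasons.append("exceeds footprint")

    outcome = "positive" if not reasons else "negative"
    return ScoreReport(
        outcome=outcome, phenotype="photochemical",
        dead_cell_count_in_footprint=n_in,
        damage_extent_diameter=diam, circularity=circ, reasons=reasons,
    )


def score_photothermal(
    img: TwoChannelImage,
    beam: BeamProfile,
    config: ScoringConfig = ScoringConfig(),
) -> ScoreReport:
    """Positive iff a contiguous dead region overlaps the beam centre and
    exceeds the minimum area; halo-only morphology is negative."""
    center = _beam_center_px(img, beam)
    red = np.asarray(img.red, dtype=float)
    med = np.median(red)
    mad = 1.4826 * np.median(np.abs(red - med))
    above = red > med + config.red_mad_factor * max(mad, 1e-12)

    reasons: list[str] = []
    if not above.any():
        return ScoreReport(outcome="negative", phenotype="photothermal",
                           reasons=["no red signal"])

    # merge nearby nuclei into one region: close over ~a cell diameter
    cell_radius_um = math.sqrt(config.nominal_cell_area_um2 / math.pi)
    merge_px = max(int(round(1.5 * cell_radius_um / img.pixel_pitch)), 1)
    region = ndimage.binary_dilation(
        above, np.ones((3, 3), dtype=bool), iterations=merge_px
    )
    labels, n = ndimage.label(region, structure=np.ones((3, 3), dtype=bool))
    center_label = labels[int(round(center[0])), int(round(center[1]))]
    if center_label == 0:
        reasons.append("no central dead region")
        return ScoreReport(outcome="negative", phenotype="photothermal",
                           reasons=reasons)

    # measure on the undilated red support of the central component; nuclei
    # cover only part of each dead cell, so scale red area to implied cells
    component_red = above & (labels == center_label)
    red_area_um2 = float(component_red.sum()) * img.pixel_pitch ** 2
    implied_cells = red_area_um2 / config.nominal_nucleus_area_um2
    n_nuclei = int(round(implied_cells))
    if implied_cells < config.min_region_cell_areas:
        reasons.append("region too small")

    rows, cols = np.nonzero(component_red)
    if rows.size:
        extent = float(np.hypot(rows.max() - rows.min(),
                                cols.max() - cols.min())) * img.pixel_pitch
    else:
        extent = 0.0

    outcome = "positive" if not reasons else "negative"
    return ScoreReport(
        outcome=outcome, phenotype="photothermal",
        dead_cell_count_in_footprint=n_nuclei,
        damage_extent_diameter=extent,
        circularity=0.0, reasons=reasons,
    )


# ---------------------------------------------------------------------------
# QC exclusion heuristics
# ---------------------------------------------------------------------------

def qc_exclusion(
    img: TwoChannelImage,
    beam: BeamProfile | None = None,
    config: ScoringConfig = ScoringConfig(),
) -> str | None:
    """Best-effort automated well-exclusion screen.

    Flags monolayer disruption (low live coverage outside the footprint)
    or foreign material (very large bright objects outside the footprint).
    Returns the first reason found, else None.
    """
    green = np.asarray(img.green, dtype=float)
    red = np.asarray(img.red, dtype=float)
    shape = img.shape
    if beam is not None:
        center = _beam_center_px(img, beam)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        r_um = np.hypot(rr - center[0], cc - center[1]) * img.pixel_pitch
        outside = r_um > beam.radius * 1.2
    else:
        outside = np.ones(shape, dtype=bool)
    if not outside.any():
        return None

    # live coverage: fraction of outside pixels with meaningful green signal
    g_out = green[outside]
    live_thr = 0.3 * np.percentile(g_out, 95)
    coverage = float((g_out > live_thr).mean())
    if coverage < config.monolayer_min_coverage:
        return "monolayer disruption"

    # foreign material: bright connected blobs much larger than a nucleus
    max_blob_um2 = config.foreign_object_nucleus_areas * config.nucleus_area_um2[1]
    for channel in (green, red):
        med = np.median(channel)
        mad = 1.4826 * np.median(np.abs(channel - med))
        bright = (channel > med + 8.0 * max(mad, 1e-12)) & outside
        if bright.any():
            labels, n = ndimage.label(bright)
            areas = ndimage.sum_labels(
                bright, labels, index=np.arange(1, n + 1)
            ) * img.pixel_pitch ** 2
            if areas.size and areas.max() > max_blob_um2:
                return "foreign material"
    return None
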