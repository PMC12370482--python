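"""Damage-mask construction.

Pipeline: bleed-through correction → contrast enhancement → four RATS
(Robust Automatic Threshold Selection) masks at decreasing stringency →
morphological cleaning (10 erode / 10 dilate) → single-contiguous-region
finalisation with hole filling.

The mask input is the *damage signal* D = max(L) − L where L is the
bleed-through-corrected live channel: a lesion is a hole in the live-cell
carpet, so D is bright exactly where cells are missing or dead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata

from .errors import (
    DegenerateInputError,
    EmptyMaskError,
    InvalidParameterError,
    NoEdgesError,
)
from .fileio import TwoChannelImage

__all__ = [
    "DamageMask",
    "RatsParams",
    "DEFAULT_SCHEDULE",
    "correct_bleedthrough",
    "enhance_contrast",
    "estimate_noise_sd",
    "rats_threshold",
    "rats_threshold_surface",
    "clean_mask",
    "finalize_mask",
    "build_mask_set",
    "mask_pipeline",
]


@dataclass(frozen=True)
class RatsParams:
    """Parameters for one RATS thresholding pass.

    ``noise_sd`` of None means "estimate from the image border".
    ``significance`` sets the leaf validity floor
    ``significance · (λ·noise_sd)² · leaf_area``: a leaf is only allowed to
    carry its own threshold when its gradient energy exceeds what gate-level
    noise covering that fraction of the leaf would produce. (The value used
    by the original ImageJ plugin is unpublished; this is a documented
    choice, not an inference.)
    """

    noise_sd: float | None = None
    lambda_factor: float = 3.0
    min_leaf: int = 8
    significance: float = 0.5

    def __post_init__(self):
        if self.noise_sd is not None and self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not self.lambda_factor > 0:
            raise InvalidParameterError("lambda_factor must be > 0")
        if self.min_leaf < 2 or (self.min_leaf & (self.min_leaf - 1)) != 0:
            raise InvalidParameterError(
                f"min_leaf must be a power of 2 and >= 2, got {self.min_leaf}"
            )


#: Increasing ``min_leaf`` = decreasing stringency = larger minimum feature
#: size, mirroring the four-mask schedule of the original ImageJ script.
DEFAULT_SCHEDULE: tuple[RatsParams, ...] = (
    RatsParams(min_leaf=8),
    RatsParams(min_leaf=16),
    RatsParams(min_leaf=32),
    RatsParams(min_leaf=64),
)


@dataclass
class DamageMask:
    """A finalised, single-component binary lesion mask."""

    mask: np.ndarray
    stringency_index: int
    pixel_pitch: float
    provenance: dict = field(default_factory=dict)
    needs_review: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptyMaskError("DamageMask must be nonempty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# channel arithmetic
# ---------------------------------------------------------------------------

def correct_bleedthrough(img: TwoChannelImage):
    """Subtract red from green and invert into a damage signal.

    Returns ``(live, damage)``: ``live = clip(green - red, 0)`` and
    ``damage = max(live) - live``. ``damage`` is the masking input.
    """
    green = np.asarray(img.green, dtype=float)
    red = np.asarray(img.red, dtype=float)
    if not green.any() and not red.any():
        raise DegenerateInputError("both channels are identically zero")
    live = np.clip(green - red, 0.0, None)
    if live.max() == 0:
        raise DegenerateInputError("corrected live signal is identically zero")
    damage = live.max() - live
    return live, damage


def enhance_contrast(img, saturated_fraction: float = 0.0035):
    """Linear rescale to full range, clipping ``saturated_fraction`` of
    pixels at each tail. Order-preserving on unclipped pixels."""
    if not (0 <= saturated_fraction < 0.5):
        raise InvalidParameterError("saturated_fraction must be in [0, 0.5)")
    f = np.asarray(img, dtype=float)
    lo = np.quantile(f, saturated_fraction)
    hi = np.quantile(f, 1.0 - saturated_fraction)
    if hi == lo:
        warnings.warn("constant image: contrast enhancement is a no-op")
        return f.copy()
    out = (np.clip(f, lo, hi) - lo) / (hi - lo) * 65535.0
    return out


# ---------------------------------------------------------------------------
# RATS
# ---------------------------------------------------------------------------

_SOBEL_R = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)


def _sobel_magnitude(f: np.ndarray) -> np.ndarray:
    gr = ndimage.convolve(f, _SOBEL_R, mode="nearest")
    gc = ndimage.convolve(f, _SOBEL_R.T, mode="nearest")
    return np.hypot(gr, gc)


def estimate_noise_sd(img, border: int = 8) -> float:
    """Robust gradient-noise scale: 1.4826 × MAD of the Sobel magnitude
    over a border margin (assumed lesion-free)."""
    f = np.asarray(img, dtype=float)
    g = _sobel_magnitude(f)
    b = min(border, min(f.shape) // 4)
    frame = np.concatenate([
        g[:b].ravel(), g[-b:].ravel(), g[:, :b].ravel(), g[:, -b:].ravel()
    ])
    med = np.median(frame)
    return float(1.4826 * np.median(np.abs(frame - med)))


def _quadtree_leaves(f, w, wf, top, left, h, width, min_leaf, leaves):
    """Recursively tile the image; collect (center_r, center_c, sum_w,
    sum_wf, area) per leaf. Splits while both dimensions can still hold
    two leaves."""
    if h >= 2 * min_leaf and width >= 2 * min_leaf:
        h2, w2 = h // 2, width // 2
        _quadtree_leaves(f, w, wf, top, left, h2, w2, min_leaf, leaves)
        _quadtree_leaves(f, w, wf, top, left + w2, h2, width - w2,
                         min_leaf, leaves)
        _quadtree_leaves(f, w, wf, top + h2, left, h - h2, w2,
                         min_leaf, leaves)
        _quadtree_leaves(f, w, wf, top + h2, left + w2, h - h2, width - w2,
                         min_leaf, leaves)
        return
    sw = float(w[top:top + h, left:left + width].sum())
    swf = float(wf[top:top + h, left:left + width].sum())
    leaves.append((top + (h - 1) / 2.0, left + (width - 1) / 2.0, sw, swf,
                   float(h * width)))


def rats_threshold_surface(img, params: RatsParams) -> np.ndarray:
    """Per-pixel threshold surface of the quadtree RATS algorithm.

    Gradient magnitude g is a 3×3 Sobel; pixel weights are w = g² where
    g > λ·noise_sd (else 0). Each quadtree leaf whose Σw clears the
    significance floor gets the weighted mean threshold Σ(w·f)/Σw; invalid
    leaves inherit the weighted average of the valid leaves (global
    fallback), and the leaf thresholds are interpolated bilinearly between
    leaf centres.
    """
    f = np.asarray(img, dtype=float)
    if min(f.shape) < 2 * params.min_leaf and max(f.shape) < 2 * params.min_leaf:
        # a single leaf covers the image; allowed (global RATS)
        pass
    noise_sd = (estimate_noise_sd(f) if params.noise_sd is None
                else params.noise_sd)

    g = _sobel_magnitude(f)
    gate = params.lambda_factor * noise_sd
    w = np.where(g > gate, g * g, 0.0)
    if not w.any():
        raise NoEdgesError("no gradient exceeds the noise gate")
    wf = w * f

    def floor_for(area: float) -> float:
        return max(params.significance * gate * gate * area, 1e-300)

    leaves: list[tuple[float, float, float, float, float]] = []
    _quadtree_leaves(f, w, wf, 0, 0, f.shape[0], f.shape[1],
                     params.min_leaf, leaves)

    total_w = sum(l[2] for l in leaves)
    total_wf = sum(l[3] for l in leaves)
    if total_w <= floor_for(f.size):
        raise NoEdgesError("no leaf clears the significance floor")
    global_t = total_wf / total_w

    pts, vals = [], []
    for (cr, cc, sw, swf, area) in leaves:
        pts.append((cr, cc))
        vals.append(swf / sw if sw > floor_for(area) else global_t)
    pts = np.asarray(pts)
    vals = np.asarray(vals)

    if len(pts) == 1:
        return np.full(f.shape, vals[0])

    rr, cc = np.mgrid[0:f.shape[0], 0:f.shape[1]]
    surface = griddata(pts, vals, (rr, cc), method="linear")
    holes = np.isnan(surface)
    if holes.any():  # outside the convex hull of leaf centres
        surface[holes] = griddata(pts, vals, (rr[holes], cc[holes]),
                                  method="nearest")
    return surface


def rats_threshold(img, params: RatsParams) -> np.ndarray:
    """Binary mask of pixels at or above the local RATS threshold."""
    f = np.asarray(img, dtype=float)
    return f >= rats_threshold_surface(f, params)


# ---------------------------------------------------------------------------
# cleaning & finalisation
# ---------------------------------------------------------------------------

_SQUARE3 = np.ones((3, 3), dtype=bool)


def clean_mask(mask, iterations: int = 10) -> np.ndarray:
    """Morphological opening: ``iterations`` erosions then dilations with a
    3×3 square. Removes noise pixels and thin spurs without changing the
    size of large convex regions."""
    m = np.asarray(mask, dtype=bool)
    if iterations <= 0:
        return m.copy()
    eroded = ndimage.binary_erosion(m, _SQUARE3, iterations=iterations)
    if not eroded.any():
        raise EmptyMaskError(
            f"mask emptied by {iterations} erosions; retry lower stringency"
        )
    return ndimage.binary_dilation(eroded, _SQUARE3, iterations=iterations)


def finalize_mask(
    mask,
    stringency_index: int = 0,
    pixel_pitch: float = 1.0,
    provenance: dict | None = None,
) -> DamageMask:
    """Keep the principal 8-connected component and fill its holes.

    The principal component is the largest by area (ties broken by centroid
    distance to the image centre). If any secondary component exceeds 25%
    of the principal area the mask is flagged ``needs_review`` — the
    explicit replacement for a by-hand editing step.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyMaskError("cannot finalize an empty mask")
    labels, n = ndimage.label(m, structure=_SQUARE3)
    center = ((m.shape[0] - 1) / 2.0, (m.shape[1] - 1) / 2.0)
    areas = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(m, labels, index=np.arange(1, n + 1))
    dists = [math.hypot(c[0] - center[0], c[1] - center[1]) for c in centroids]
    order = sorted(range(n), key=lambda i: (-areas[i], dists[i]))
    principal = order[0]
    needs_review = n > 1 and any(
        areas[i] > 0.25 * areas[principal] for i in order[1:]
    )
    keep = labels == principal + 1
    filled = ndimage.binary_fill_holes(keep)
    return DamageMask(
        mask=filled,
        stringency_index=stringency_index,
        pixel_pitch=pixel_pitch,
        provenance=provenance or {},
        needs_review=needs_review,
    )


def build_mask_set(
    damage_signal,
    schedule=DEFAULT_SCHEDULE,
    pixel_pitch: float = 1.0,
    clean_iterations: int = 10,
) -> list[DamageMask]:
    """Run RATS → clean → finalize at each of the four stringencies.

    Per-stringency failures are tolerated; only if all four fail is an
    error raised (wrapping the first failure).
    """
    schedule = list(schedule)
    if len(schedule) != 4:
        raise InvalidParameterError("schedule must hold exactly 4 RatsParams")
    if any(b.min_leaf <= a.min_leaf for a, b in zip(schedule, schedule[1:])):
        raise InvalidParameterError("schedule min_leaf must strictly increase")

    masks: list[DamageMask] = []
    errors: list[Exception] = []
    for idx, params in enumerate(schedule):
        try:
            raw = rats_threshold(damage_signal, params)
            cleaned = clean_mask(raw, iterations=clean_iterations)
            masks.append(finalize_mask(
                cleaned, stringency_index=idx, pixel_pitch=pixel_pitch,
                provenance={
                    "min_leaf": params.min_leaf,
                    "lambda_factor": params.lambda_factor,
                    "noise_sd": params.noise_sd,
                    "clean_iterations": clean_iterations,
                },
            ))
        except (NoEdgesError, EmptyMaskError) as exc:
            errors.append(exc)
    if not masks:
        raise NoEdgesError(
            f"all {len(schedule)} stringencies failed; first error: {errors[0]}"
        )
    return masks


def mask_pipeline(
    img: TwoChannelImage,
    schedule=DEFAULT_SCHEDULE,
    saturated_fraction: float = 0.0035,
    clean_iterations: int = 10,
) -> list[DamageMask]:
    """Full path from a two-channel image to the four-mask set."""
    _, damage = correct_bleedthrough(img)
    enhanced = enhance_contrast(damage, saturated_fraction)
    return build_mask_set(
        enhanced, schedule=schedule, pixel_pitch=img.pixel_pitch,
        clean_iterations=clean_iterations,
    )
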