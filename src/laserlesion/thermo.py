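"""Fusion of damage masks with thermal video.

Registers fluorescence-space masks onto the thermogram (flip / quarter-turn
rotate / pitch-ratio scale / translate-to-hotspot), picks the mask whose
boundary ring has the smallest temperature SD, and extracts the boundary
(threshold) temperature history and peak steady-state values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateMaskError,
    InvalidParameterError,
    OutOfFrameError,
    RankDeficiencyError,
    WindowTooShortError,
)
from .fileio import ThermalVideo
from .mask import DamageMask

__all__ = [
    "Orientation",
    "RegisteredMask",
    "BoundaryRing",
    "ThresholdTemperatureResult",
    "ThermalCurve",
    "find_hotspot",
    "register_mask",
    "boundary_ring",
    "select_mask",
    "extract_threshold_history",
    "fit_thermal_curve",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)

#: fraction of the exposure window used for steady-state time averages
STEADY_STATE_FRACTION = 0.1


@dataclass(frozen=True)
class Orientation:
    """Instrument-specific mapping from fluorescence to thermal axes."""

    flip_rows: bool = False
    flip_cols: bool = False
    rot90: int = 0  # number of counter-clockwise quarter turns

    def apply(self, arr: np.ndarray) -> np.ndarray:
        out = arr
        if self.flip_rows:
            out = np.flip(out, axis=0)
        if self.flip_cols:
            out = np.flip(out, axis=1)
        if self.rot90 % 4:
            out = np.rot90(out, self.rot90 % 4)
        return out


@dataclass
class RegisteredMask:
    """A damage mask resampled into thermal-pixel coordinates."""

    mask: np.ndarray
    transform: dict
    stringency_index: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class BoundaryRing:
    """One-pixel-wide outer boundary of a registered mask."""

    pixels: np.ndarray  # (n, 2) array of (row, col)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise DegenerateMaskError("boundary ring is empty")

    def __len__(self):
        return self.pixels.shape[0]

    @property
    def index(self):
        return self.pixels[:, 0], self.pixels[:, 1]


@dataclass
class ThresholdTemperatureResult:
    """Boundary and centre temperature summaries for one exposure."""

    frame_mean: np.ndarray          # per-frame ring mean, °C
    frame_sd: np.ndarray            # per-frame ring SD, °C
    threshold_peak_temperature: float
    center_peak_temperature: float
    ambient: float
    hotspot: tuple[int, int]
    extras: dict = field(default_factory=dict)

    @property
    def threshold_peak_dT(self) -> float:
        return self.threshold_peak_temperature - self.ambient

    @property
    def center_peak_dT(self) -> float:
        return self.center_peak_temperature - self.ambient


def _steady_window(video: ThermalVideo, min_frames: int = 1) -> slice:
    start, end = video.exposure_window
    n = end - start
    k = max(int(round(n * STEADY_STATE_FRACTION)), min_frames)
    return slice(end - k, end)


def find_hotspot(video: ThermalVideo) -> tuple[int, int]:
    """Hottest (central) pixel of the time-averaged end-of-exposure frame.

    Averaging over the last 10% of the exposure suppresses single-frame
    noise. Because a flat-top heating profile leaves a noise-level plateau
    around the true centre, the hotspot is the centroid of the pixels
    within three (averaged) noise SDs of the maximum; with zero noise this
    degenerates to the exact-maximum set, whose ties resolve to the
    smallest (row, col) lexicographically.
    """
    window = _steady_window(video)
    stack = video.frames[window]
    avg = np.nanmean(stack, axis=0)
    if np.isnan(avg).all():
        raise InvalidParameterError("all-NaN steady-state window")
    k = stack.shape[0]
    noise = float(np.nanmedian(np.nanstd(stack, axis=0))) / np.sqrt(max(k, 1))
    peak = np.nanmax(avg)
    if noise == 0:
        flat = np.nanargmax(avg)
        return tuple(np.unravel_index(flat, avg.shape))
    plateau = avg >= peak - 3.0 * noise
    rows, cols = np.nonzero(plateau)
    return (int(round(rows.mean())), int(round(cols.mean())))


def register_mask(
    mask: DamageMask,
    video: ThermalVideo,
    orientation: Orientation = Orientation(),
) -> RegisteredMask:
    """Resample a fluorescence mask into thermal coordinates.

    Nearest-neighbour scaling by the pixel-pitch ratio, the configured
    flips/rotations, then translation of the mask centroid onto the
    thermogram hotspot.
    """
    scale = mask.pixel_pitch / video.pixel_pitch
    src = np.asarray(mask.mask, dtype=bool)
    out_shape = (max(int(round(src.shape[0] * scale)), 1),
                 max(int(round(src.shape[1] * scale)), 1))
    rr = np.minimum((np.arange(out_shape[0]) / scale).astype(int),
                    src.shape[0] - 1)
    cc = np.minimum((np.arange(out_shape[1]) / scale).astype(int),
                    src.shape[1] - 1)
    scaled = src[np.ix_(rr, cc)]
    oriented = orientation.apply(scaled)

    if not oriented.any():
        raise DegenerateMaskError("mask vanished during resampling")
    crow, ccol = ndimage.center_of_mass(oriented)
    hotspot = find_hotspot(video)
    frame_shape = video.frame_shape

    rows, cols = np.nonzero(oriented)
    dr = int(round(hotspot[0] - crow))
    dc = int(round(hotspot[1] - ccol))
    new_r = rows + dr
    new_c = cols + dc
    if (new_r.min() < 0 or new_c.min() < 0
            or new_r.max() >= frame_shape[0] or new_c.max() >= frame_shape[1]):
        raise OutOfFrameError(
            f"registered mask extent exceeds thermal frame {frame_shape}"
        )
    placed = np.zeros(frame_shape, dtype=bool)
    placed[new_r, new_c] = True
    return RegisteredMask(
        mask=placed,
        transform={
            "scale": scale,
            "flip_rows": orientation.flip_rows,
            "flip_cols": orientation.flip_cols,
            "rot90": orientation.rot90,
            "translation": (dr, dc),
            "hotspot": hotspot,
        },
        stringency_index=mask.stringency_index,
    )


def boundary_ring(rmask: RegisteredMask) -> BoundaryRing:
    """Single-pixel outer boundary: mask XOR its 1-iteration erosion."""
    m = rmask.mask
    if m.sum() < 9:
        raise DegenerateMaskError("mask too small for a boundary ring")
    eroded = ndimage.binary_erosion(m, _SQUARE3)
    if not eroded.any():
        raise DegenerateMaskError("mask erodes to nothing; no interior")
    ring = m ^ eroded
    return BoundaryRing(pixels=np.column_stack(np.nonzero(ring)))


def select_mask(
    masks: list[RegisteredMask], video: ThermalVideo
) -> tuple[RegisteredMask, list[dict]]:
    """Choose the registered mask with minimal boundary-temperature SD.

    SD is computed over the ring pixels of the time-averaged
    end-of-exposure frame; ties resolve to the lowest stringency index.
    """
    if not masks:
        raise InvalidParameterError("need at least one registered mask")
    window = _steady_window(video)
    avg = video.frames[window].mean(axis=0)
    report = []
    for rm in masks:
        ring = boundary_ring(rm)
        temps = avg[ring.index]
        report.append({
            "stringency_index": rm.stringency_index,
            "ring_sd": float(np.std(temps)),
            "ring_mean": float(np.mean(temps)),
            "ring_px": len(ring),
        })
    best = min(range(len(masks)),
               key=lambda i: (report[i]["ring_sd"],
                              masks[i].stringency_index))
    for i, entry in enumerate(report):
        entry["selected"] = i == best
    return masks[best], report


def extract_threshold_history(
    video: ThermalVideo, ring: BoundaryRing
) -> ThresholdTemperatureResult:
    """Per-frame boundary mean/SD plus peak steady-state summaries.

    The threshold peak temperature is the ring mean averaged over the last
    10% of the exposure window; the centre peak is the hotspot pixel over
    the same window. ΔT accessors subtract the sidecar ambient.
    """
    start, end = video.exposure_window
    if end - start < 10:
        raise WindowTooShortError(
            f"exposure window has {end - start} frames; need >= 10"
        )
    rr, cc = ring.index
    ring_series = video.frames[:, rr, cc]
    frame_mean = ring_series.mean(axis=1)
    frame_sd = ring_series.std(axis=1)

    window = _steady_window(video)
    hotspot = find_hotspot(video)
    threshold_peak = float(frame_mean[window].mean())
    center_peak = float(video.frames[window, hotspot[0], hotspot[1]].mean())
    return ThresholdTemperatureResult(
        frame_mean=frame_mean,
        frame_sd=frame_sd,
        threshold_peak_temperature=threshold_peak,
        center_peak_temperature=center_peak,
        ambient=video.ambient,
        hotspot=hotspot,
        extras={"steady_window": (window.start, window.stop),
                "ring_px": len(ring)},
    )


# ---------------------------------------------------------------------------
# irradiance → temperature standard curve
# ---------------------------------------------------------------------------

@dataclass
class ThermalCurve:
    """OLS line T = slope·E + intercept with its algebraic inverse."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict_temperature(self, irradiance):
        return self.slope * np.asarray(irradiance, dtype=float) + self.intercept

    def predict_irradiance(self, temperature):
        return (np.asarray(temperature, dtype=float) - self.intercept) / self.slope


def fit_thermal_curve(pairs) -> ThermalCurve:
    """Fit the irradiance→peak-temperature standard curve by OLS."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise RankDeficiencyError("need at least two (irradiance, T) pairs")
    e = np.array([p[0] for p in pairs], dtype=float)
    t = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(e) == 0:
        raise RankDeficiencyError("all irradiances are equal")
    slope, intercept = np.polyfit(e, t, 1)
    resid = t - (slope * e + intercept)
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    return ThermalCurve(slope=float(slope), intercept=float(intercept),
                        r_squared=r2, n=len(pairs))
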