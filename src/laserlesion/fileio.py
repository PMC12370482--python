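"""File formats and core record types.

Conventions used across the package (stated once, here):

* pixel coordinates are ``(row, col)``, 0-based, origin at the top-left;
  windows are half-open ranges;
* physical lengths are in µm, temperatures in °C, irradiance in W cm^-2,
  durations in s;
* fluorescence images are 2-page 16-bit TIFFs (page 1 = green/live,
  page 2 = red/dead) with a JSON sidecar
  ``{pixel_pitch_um, beam_center, beam_diameter_um}``;
* thermal videos are multi-page float32 TIFFs already calibrated to °C with
  a JSON sidecar ``{fps, pixel_pitch_um, ambient_C, exposure_start_frame,
  exposure_end_frame}``;
* exposure logs are CSV with header ``wavelength_nm, irradiance_W_cm2,
  duration_s, beam_diameter_um, outcome`` (outcome 0/1 or ``excluded``).

Readers validate and reject; they never coerce malformed input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    DataValidationError,
    FormatError,
    InvalidParameterError,
    SchemaError,
)

__all__ = [
    "TwoChannelImage",
    "ThermalVideo",
    "ExposureRecord",
    "read_fluorescence",
    "write_fluorescence",
    "read_thermal",
    "write_thermal",
    "read_exposure_log",
    "write_exposure_log",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TwoChannelImage:
    """Live/dead fluorescence frame.

    ``green`` carries the calcein (live) signal and ``red`` the ethidium
    (dead) signal; both share one pixel grid of pitch ``pixel_pitch`` µm.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_pitch: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise InvalidParameterError(
                f"channel shapes differ: green {self.green.shape} vs "
                f"red {self.red.shape}"
            )
        if self.green.ndim != 2:
            raise InvalidParameterError("channels must be 2-D")
        if not self.pixel_pitch > 0:
            raise InvalidParameterError("pixel_pitch must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape


@dataclass
class ThermalVideo:
    """Calibrated temperature stack, frames[t, row, col] in °C."""

    frames: np.ndarray
    fps: float
    pixel_pitch: float
    ambient: float
    exposure_window: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be 3-D (frame, row, col)")
        if not self.fps > 0:
            raise InvalidParameterError("fps must be > 0")
        if not self.pixel_pitch > 0:
            raise InvalidParameterError("pixel_pitch must be > 0")
        start, end = self.exposure_window
        if not (0 <= start < end <= self.frames.shape[0]):
            raise InvalidParameterError(
                f"exposure_window {self.exposure_window} outside frame range "
                f"[0, {self.frames.shape[0]})"
            )
        bad = ~np.isfinite(self.frames)
        if bad.any():
            frames_bad = sorted(set(np.nonzero(bad)[0].tolist()))
            raise DataValidationError(
                f"non-finite temperatures in frames {frames_bad[:10]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


_OUTCOMES = {0, 1, "excluded"}


@dataclass
class ExposureRecord:
    """One laser exposure with its binary damage outcome."""

    wavelength: float
    irradiance: float
    duration: float
    beam_diameter: float
    outcome: object  # 0, 1 or "excluded"
    exclusion_reason: str | None = None

    def __post_init__(self):
        if self.irradiance < 0:
            raise InvalidParameterError(
                f"irradiance must be >= 0, got {self.irradiance}"
            )
        if not self.duration > 0:
            raise InvalidParameterError(
                f"duration must be > 0, got {self.duration}"
            )
        if self.outcome not in _OUTCOMES:
            raise InvalidParameterError(
                f"outcome must be 0, 1 or 'excluded', got {self.outcome!r}"
            )


# ---------------------------------------------------------------------------
# sidecar helpers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path, required: dict[str, type]) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        try:
            meta = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"sidecar {sidecar} is not valid JSON: {exc}")
    for key, typ in required.items():
        if key not in meta:
            raise SchemaError(f"sidecar {sidecar} missing field '{key}'")
        if typ in (int, float) and not isinstance(meta[key], (int, float)):
            raise SchemaError(
                f"sidecar field '{key}' must be numeric, got {meta[key]!r}"
            )
    return meta


# ---------------------------------------------------------------------------
# fluorescence I/O
# ---------------------------------------------------------------------------

def write_fluorescence(img: TwoChannelImage, path) -> Path:
    """Write a two-page 16-bit TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    stack = np.stack(
        [img.green.astype(np.uint16), img.red.astype(np.uint16)], axis=0
    )
    tifffile.imwrite(path, stack)
    meta = {"pixel_pitch_um": float(img.pixel_pitch)}
    meta.update({k: v for k, v in img.metadata.items() if _jsonable(v)})
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_fluorescence(path) -> TwoChannelImage:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise FormatError(
            f"{path}: expected a 2-page TIFF, got shape {pages.shape}"
        )
    meta = _load_sidecar(path, {"pixel_pitch_um": float})
    pitch = float(meta.pop("pixel_pitch_um"))
    if not pitch > 0:
        raise SchemaError("pixel_pitch_um must be > 0")
    return TwoChannelImage(
        green=pages[0], red=pages[1], pixel_pitch=pitch, metadata=meta
    )


# ---------------------------------------------------------------------------
# thermal I/O
# ---------------------------------------------------------------------------

_THERMAL_FIELDS = {
    "fps": float,
    "pixel_pitch_um": float,
    "ambient_C": float,
    "exposure_start_frame": int,
    "exposure_end_frame": int,
}


def write_thermal(video: ThermalVideo, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, video.frames.astype(np.float32))
    meta = {
        "fps": float(video.fps),
        "pixel_pitch_um": float(video.pixel_pitch),
        "ambient_C": float(video.ambient),
        "exposure_start_frame": int(video.exposure_window[0]),
        "exposure_end_frame": int(video.exposure_window[1]),
    }
    meta.update({k: v for k, v in video.metadata.items() if _jsonable(v)})
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_thermal(path) -> ThermalVideo:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected a frame stack, got {frames.shape}")
    meta = _load_sidecar(path, _THERMAL_FIELDS)
    fps = float(meta.pop("fps"))
    if not fps > 0:
        raise SchemaError("fps must be > 0")
    pitch = float(meta.pop("pixel_pitch_um"))
    ambient = float(meta.pop("ambient_C"))
    window = (int(meta.pop("exposure_start_frame")),
              int(meta.pop("exposure_end_frame")))
    return ThermalVideo(
        frames=frames, fps=fps, pixel_pitch=pitch, ambient=ambient,
        exposure_window=window, metadata=meta,
    )


# ---------------------------------------------------------------------------
# exposure log I/O
# ---------------------------------------------------------------------------

_LOG_COLUMNS = [
    "wavelength_nm", "irradiance_W_cm2", "duration_s",
    "beam_diameter_um", "outcome",
]


def write_exposure_log(records, path) -> Path:
    path = Path(path)
    rows = []
    for rec in records:
        rows.append({
            "wavelength_nm": rec.wavelength,
            "irradiance_W_cm2": rec.irradiance,
            "duration_s": rec.duration,
            "beam_diameter_um": rec.beam_diameter,
            "outcome": rec.outcome,
            "exclusion_reason": rec.exclusion_reason or "",
        })
    pd.DataFrame(rows, columns=_LOG_COLUMNS + ["exclusion_reason"]).to_csv(
        path, index=False
    )
    return path


def read_exposure_log(path) -> list[ExposureRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"outcome": str},
                     float_precision="round_trip")
    missing = [c for c in _LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        raw = str(row["outcome"]).strip()
        if raw in ("0", "1"):
            outcome: object = int(raw)
        elif raw == "excluded":
            outcome = "excluded"
        else:
            raise DataValidationError(
                f"{path} row {i}: invalid outcome {raw!r}"
            )
        try:
            rec = ExposureRecord(
                wavelength=float(row["wavelength_nm"]),
                irradiance=float(row["irradiance_W_cm2"]),
                duration=float(row["duration_s"]),
                beam_diameter=float(row["beam_diameter_um"]),
                outcome=outcome,
                exclusion_reason=(str(row["exclusion_reason"]) or None)
                if "exclusion_reason" in df.columns
                and not pd.isna(row.get("exclusion_reason"))
                and str(row.get("exclusion_reason"))
                else None,
            )
        except InvalidParameterError as exc:
            raise DataValidationError(f"{path} row {i}: {exc}")
        records.append(rec)
    return records


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False
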