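"""Synthetic fluorescence images, thermal videos and dose-response data.

Everything downstream of acquisition is testable against this generator:
it produces two-channel live/dead images, calibrated thermal stacks and
binary outcome logs together with their ground truth (death region, dead
cell centroids, boundary isotherm temperature).

The thermal field is a flat-top beam footprint convolved with a Gaussian
(heat-spread stand-in, width ``diffusion_sigma``), normalised so the centre
of the beam sits at the full steady-state temperature rise::

    T(r, t) = ambient + (k * E + intercept) * s(r) * (1 - exp(-t / tau)) + noise

with ``s(0) = 1``. The convolution of a disk indicator with an isotropic
Gaussian has a closed form via the noncentral chi-square CDF, so the profile
(and its inverse, the isotherm radius) is analytic — no PDE is solved, by
design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import optimize, stats

from .errors import InvalidParameterError
from .fileio import ExposureRecord, ThermalVideo, TwoChannelImage

__all__ = [
    "BeamProfile",
    "ThermalModelParams",
    "LesionPhenotypeParams",
    "GroundTruth",
    "steady_state_profile",
    "isotherm_radius",
    "thermal_params_from_anchors",
    "simulate_thermal_video",
    "simulate_viability_image",
    "simulate_dose_response",
    "make_table1_dataset",
    "TABLE1_BINS",
]


# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamProfile:
    """Flat-top laser beam and its exposure settings."""

    diameter: float           # µm
    irradiance: float         # W cm^-2
    wavelength: float = 447.0  # nm
    duration: float = 200.0   # s
    center: tuple[float, float] | None = None  # (row, col) px; None = image centre
    profile: str = "flat_top"

    def __post_init__(self):
        if not self.diameter > 0:
            raise InvalidParameterError(f"diameter must be > 0, got {self.diameter}")
        if self.irradiance < 0:
            raise InvalidParameterError("irradiance must be >= 0")
        if not self.duration > 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.profile != "flat_top":
            raise InvalidParameterError(f"unsupported profile {self.profile!r}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class ThermalModelParams:
    """Linear irradiance→temperature response with first-order rise."""

    ambient: float = 35.5            # °C
    k_slope: float = 1.25            # °C per W cm^-2
    intercept: float = 0.0           # °C rise at E = 0
    rise_time_constant: float = 0.4  # s; >99% of steady state by 2 s
    diffusion_sigma: float = 150.0   # µm
    camera_noise_sd: float = 0.1     # °C, per-pixel per-frame

    def __post_init__(self):
        if not self.rise_time_constant > 0:
            raise InvalidParameterError("rise_time_constant must be > 0")
        if self.camera_noise_sd < 0:
            raise InvalidParameterError("camera_noise_sd must be >= 0")
        if self.diffusion_sigma < 0:
            raise InvalidParameterError("diffusion_sigma must be >= 0")

    def steady_state_rise(self, irradiance: float) -> float:
        """ΔT at the beam centre for a given irradiance, °C."""
        return self.k_slope * irradiance + self.intercept


def thermal_params_from_anchors(
    anchors: list[tuple[float, float]],
    ambient: float,
    **kwargs,
) -> ThermalModelParams:
    """Fit ``k_slope``/``intercept`` through (irradiance, centre temperature)
    anchor pairs by least squares (exact for two points)."""
    if len(anchors) < 2:
        raise InvalidParameterError("need at least two anchor pairs")
    e = np.array([a[0] for a in anchors], dtype=float)
    t = np.array([a[1] for a in anchors], dtype=float)
    if np.ptp(e) == 0:
        raise InvalidParameterError("anchor irradiances must differ")
    k, c = np.polyfit(e, t - ambient, 1)
    return ThermalModelParams(ambient=ambient, k_slope=float(k),
                              intercept=float(c), **kwargs)


@dataclass(frozen=True)
class LesionPhenotypeParams:
    """Morphology parameters for rendering a lesion phenotype."""

    kind: Literal["photothermal", "photochemical"] = "photothermal"
    T_crit: float = 44.0            # °C photothermal death isotherm
    halo_width: float = 1.5         # °C sublethal band below T_crit
    p_death_max: float = 0.95       # photochemical in-footprint death prob
    background_death_rate: float = 0.005  # spontaneous death, < 1%
    cell_density: float = 1500.0    # cells mm^-2
    nucleus_radius: float = 6.0     # µm
    bleedthrough_coeff: float = 0.1  # red fraction leaking into green
    halo_intensity_factor: float = 1.3   # hyperfluorescence
    halo_radius_factor: float = 0.7      # contracted cells

    def __post_init__(self):
        if self.kind not in ("photothermal", "photochemical"):
            raise InvalidParameterError(f"unknown phenotype kind {self.kind!r}")
        if not (0 <= self.p_death_max <= 1):
            raise InvalidParameterError("p_death_max must be in [0, 1]")
        if not (0 <= self.background_death_rate < 0.01):
            raise InvalidParameterError("background_death_rate must be in [0, 0.01)")
        if self.halo_width < 0:
            raise InvalidParameterError("halo_width must be >= 0")
        if not self.cell_density > 0:
            raise InvalidParameterError("cell_density must be > 0")


@dataclass
class GroundTruth:
    """Oracle record emitted alongside every simulated artefact."""

    death_region: np.ndarray | None          # binary pixel mask
    dead_cell_centroids: list[tuple[float, float]]
    boundary_temperature: float              # °C at the death-region edge
    steady_state_center_temp: float          # °C
    temperature_at: Callable[[float], float] | None = None  # radius µm → °C
    beam_center: tuple[float, float] | None = None  # (row, col) px
    pixel_pitch: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# analytic radial profile
# ---------------------------------------------------------------------------

def _raw_profile(r_um, radius_um: float, sigma_um: float):
    """Disk indicator ⊛ Gaussian, evaluated at radius r (unnormalised).

    Equals P(|Z + r·e| <= R) for Z ~ N(0, σ² I₂), i.e. a noncentral χ²(2)
    CDF in the scaled variables.
    """
    r = np.asarray(r_um, dtype=float)
    if sigma_um <= 0:
        return (r <= radius_um).astype(float)
    q = (radius_um / sigma_um) ** 2
    nc = (r / sigma_um) ** 2
    return stats.ncx2.cdf(q, df=2, nc=nc)


def steady_state_profile(beam: BeamProfile, params: ThermalModelParams, r_um):
    """Normalised spatial shape factor s(r) with s(0) = 1."""
    raw0 = float(_raw_profile(0.0, beam.radius, params.diffusion_sigma))
    return _raw_profile(r_um, beam.radius, params.diffusion_sigma) / raw0


def steady_state_temperature(beam: BeamProfile, params: ThermalModelParams, r_um):
    """Noiseless steady-state temperature at radius r from the beam centre."""
    dT = params.steady_state_rise(beam.irradiance)
    return params.ambient + dT * steady_state_profile(beam, params, r_um)


def isotherm_radius(
    beam: BeamProfile, params: ThermalModelParams, temperature: float
) -> float:
    """Radius (µm) at which the noiseless steady-state field equals
    ``temperature``; raises if the isotherm is not reached."""
    dT = params.steady_state_rise(beam.irradiance)
    center = params.ambient + dT
    if not (params.ambient < temperature <= center):
        raise InvalidParameterError(
            f"isotherm {temperature} °C outside ({params.ambient}, {center}] °C"
        )
    if temperature == center:
        return 0.0

    def f(r):
        return float(steady_state_temperature(beam, params, r)) - temperature

    hi = beam.radius + 20.0 * max(params.diffusion_sigma, 1.0)
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# thermal video
# ---------------------------------------------------------------------------

def simulate_thermal_video(
    beam: BeamProfile,
    params: ThermalModelParams,
    fps: float,
    seed: int,
    frame_shape: tuple[int, int] = (160, 160),
    pixel_pitch: float = 6.0,
    duration: float | None = None,
) -> tuple[ThermalVideo, GroundTruth]:
    """Simulate a calibrated temperature stack for one exposure.

    ``duration`` defaults to ``beam.duration``; pass a shorter test duration
    explicitly when the physical 200 s exposure would be too many frames.
    The exposure window spans the whole stack.
    """
    if not fps > 0:
        raise InvalidParameterError(f"fps must be > 0, got {fps}")
    duration = beam.duration if duration is None else float(duration)
    if not duration > 0:
        raise InvalidParameterError("duration must be > 0")

    rng = np.random.default_rng(seed)
    n_rows, n_cols = frame_shape
    center = beam.center if beam.center is not None else (
        (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    )
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    r_um = np.hypot(rr - center[0], cc - center[1]) * pixel_pitch

    dT = params.steady_state_rise(beam.irradiance)
    shape_map = steady_state_profile(beam, params, r_um)
    ss_map = dT * shape_map  # °C rise at steady state

    n_frames = max(int(round(fps * duration)), 1)
    t = (np.arange(n_frames) + 1) / fps
    rise = 1.0 - np.exp(-t / params.rise_time_constant)
    frames = params.ambient + rise[:, None, None] * ss_map[None, :, :]
    if params.camera_noise_sd > 0:
        frames = frames + rng.normal(
            0.0, params.camera_noise_sd, size=frames.shape
        )

    video = ThermalVideo(
        frames=frames.astype(np.float32),
        fps=fps,
        pixel_pitch=pixel_pitch,
        ambient=params.ambient,
        exposure_window=(0, n_frames),
        metadata={"seed": int(seed), "irradiance_W_cm2": beam.irradiance,
                  "beam_diameter_um": beam.diameter},
    )

    center_temp = params.ambient + dT  # s(0) = 1 by normalisation

    def temperature_at(r):
        return float(steady_state_temperature(beam, params, r))

    truth = GroundTruth(
        death_region=None,
        dead_cell_centroids=[],
        boundary_temperature=center_temp,
        steady_state_center_temp=center_temp,
        temperature_at=temperature_at,
        beam_center=center,
        pixel_pitch=pixel_pitch,
        extras={"dT_ss": dT},
    )
    return video, truth


# ---------------------------------------------------------------------------
# viability image
# ---------------------------------------------------------------------------

def _draw_disk(canvas, row, col, radius_px, value):
    # additive soft disk; cheap local stamp
    r0 = max(int(math.floor(row - radius_px)), 0)
    r1 = min(int(math.ceil(row + radius_px)) + 1, canvas.shape[0])
    c0 = max(int(math.floor(col - radius_px)), 0)
    c1 = min(int(math.ceil(col + radius_px)) + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col)
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, value * (d <= radius_px), out=patch)


def simulate_viability_image(
    beam: BeamProfile,
    thermal: ThermalModelParams,
    phenotype: LesionPhenotypeParams,
    seed: int,
    shape: tuple[int, int] = (512, 512),
    pixel_pitch: float = 3.0,
    margin_um: float = 50.0,
) -> tuple[TwoChannelImage, GroundTruth]:
    """Render a live/dead image of a monolayer after one exposure.

    Cells are a Poisson point process; fate is assigned from the analytic
    steady-state temperature (photothermal) or a Bernoulli draw inside the
    footprint (photochemical). Ground truth carries the death region, the
    dead-cell centroids and the boundary isotherm temperature.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    center = beam.center if beam.center is not None else (
        (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    )
    half_extent = min(center[0], center[1],
                      n_rows - 1 - center[0], n_cols - 1 - center[1])
    if half_extent * pixel_pitch < beam.radius + margin_um:
        raise InvalidParameterError(
            f"image {shape} at {pixel_pitch} µm/px cannot contain the "
            f"{beam.diameter} µm footprint plus {margin_um} µm margin"
        )

    area_mm2 = (n_rows * pixel_pitch) * (n_cols * pixel_pitch) / 1e6
    n_cells = rng.poisson(phenotype.cell_density * area_mm2)
    pos = np.column_stack([
        rng.uniform(0, n_rows, n_cells), rng.uniform(0, n_cols, n_cells)
    ])
    r_um = np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1]) * pixel_pitch

    dT = thermal.steady_state_rise(beam.irradiance)
    cell_temp = thermal.ambient + dT * np.asarray(
        steady_state_profile(beam, thermal, r_um)
    )

    in_footprint = r_um <= beam.radius
    if phenotype.kind == "photothermal":
        dead = cell_temp > phenotype.T_crit
        halo = (~dead) & (cell_temp > phenotype.T_crit - phenotype.halo_width)
        # spontaneous background death outside any thermal involvement
        spont = rng.random(n_cells) < phenotype.background_death_rate
        dead = dead | (spont & ~halo)
    else:
        p = np.where(in_footprint, phenotype.p_death_max,
                     phenotype.background_death_rate)
        dead = rng.random(n_cells) < p
        halo = np.zeros(n_cells, dtype=bool)

    # rendering geometry: near-confluent carpet
    mean_cell_radius_um = 1.35 / math.sqrt(
        math.pi * phenotype.cell_density / 1e6
    )
    cyto_px = mean_cell_radius_um / pixel_pitch
    nuc_px = max(phenotype.nucleus_radius / pixel_pitch, 1.0)

    green = np.zeros(shape, dtype=float)
    red = np.zeros(shape, dtype=float)
    live_int = 2600.0
    dead_int = 3200.0
    jitter = 1.0 + 0.08 * rng.standard_normal(n_cells)
    for i in range(n_cells):
        row, col = pos[i]
        if dead[i]:
            _draw_disk(red, row, col, nuc_px, dead_int * jitter[i])
        elif halo[i]:
            _draw_disk(green, row, col,
                       cyto_px * phenotype.halo_radius_factor,
                       live_int * phenotype.halo_intensity_factor * jitter[i])
        else:
            _draw_disk(green, row, col, cyto_px, live_int * jitter[i])

    from scipy.ndimage import gaussian_filter

    # red is blurred less: nuclei must stay nucleus-sized after the PSF
    green = gaussian_filter(green, 1.2) + 150.0
    red = gaussian_filter(red, 0.8) + 150.0
    green_obs = green + phenotype.bleedthrough_coeff * red
    green_obs += rng.normal(0, 25.0, shape)
    red += rng.normal(0, 25.0, shape)
    green_obs = np.clip(green_obs, 0, 65535).astype(np.uint16)
    red = np.clip(red, 0, 65535).astype(np.uint16)

    img = TwoChannelImage(
        green=green_obs, red=red, pixel_pitch=pixel_pitch,
        metadata={
            "seed": int(seed),
            "beam_center": [float(center[0]), float(center[1])],
            "beam_diameter_um": beam.diameter,
            "phenotype": phenotype.kind,
        },
    )

    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    pix_r_um = np.hypot(rr - center[0], cc - center[1]) * pixel_pitch
    if phenotype.kind == "photothermal":
        center_temp = thermal.ambient + dT
        if center_temp > phenotype.T_crit:
            r_crit = isotherm_radius(beam, thermal, phenotype.T_crit)
            death_region = pix_r_um <= r_crit
            boundary_T = phenotype.T_crit
        else:
            r_crit = 0.0
            death_region = np.zeros(shape, dtype=bool)
            boundary_T = center_temp
        extras = {"r_crit_um": r_crit, "dT_ss": dT}
    else:
        death_region = pix_r_um <= beam.radius
        boundary_T = float(steady_state_temperature(beam, thermal, beam.radius))
        extras = {"r_crit_um": beam.radius, "dT_ss": dT,
                  "n_cells_in_footprint": int(in_footprint.sum()),
                  "n_dead_in_footprint": int((dead & in_footprint).sum())}

    def temperature_at(r):
        return float(steady_state_temperature(beam, thermal, r))

    truth = GroundTruth(
        death_region=death_region,
        dead_cell_centroids=[tuple(p) for p in pos[dead]],
        boundary_temperature=boundary_T,
        steady_state_center_temp=thermal.ambient + dT,
        temperature_at=temperature_at,
        beam_center=center,
        pixel_pitch=pixel_pitch,
        extras=extras,
    )
    return img, truth


# ---------------------------------------------------------------------------
# dose-response generation
# ---------------------------------------------------------------------------

def simulate_dose_response(
    ed50: float,
    probit_slope: float,
    irradiances,
    seed: int,
    wavelength: float = 447.0,
    duration: float = 200.0,
    beam_diameter: float = 825.0,
) -> list[ExposureRecord]:
    """Draw binary outcomes from P = Φ(slope · (log10 E − log10 ED50))."""
    if not ed50 > 0:
        raise InvalidParameterError(f"ed50 must be > 0, got {ed50}")
    if not probit_slope > 0:
        raise InvalidParameterError("probit_slope must be > 0")
    irr = np.asarray(list(irradiances), dtype=float)
    if np.any(irr <= 0):
        raise InvalidParameterError("all irradiances must be > 0")
    rng = np.random.default_rng(seed)
    p = stats.norm.cdf(probit_slope * (np.log10(irr) - np.log10(ed50)))
    outcomes = (rng.random(irr.size) < p).astype(int)
    return [
        ExposureRecord(
            wavelength=wavelength, irradiance=float(e), duration=duration,
            beam_diameter=beam_diameter, outcome=int(o),
        )
        for e, o in zip(irr, outcomes)
    ]


# ---------------------------------------------------------------------------
# deterministic 2-µm dataset (printed dose-response table)
# ---------------------------------------------------------------------------

# (bin low, bin high, count, positives)
TABLE1_BINS: list[tuple[float, float, int, int]] = [
    (1.0, 4.0, 6, 0),
    (4.0, 8.0, 18, 0),
    (8.0, 12.0, 15, 0),
    (12.15, 12.29, 6, 3),
    (12.4, 14.0, 15, 15),
    (14.0, 18.0, 20, 20),
    (18.0, 30.0, 9, 9),
    (30.0, 50.0, 4, 4),
]

# the six near-threshold exposures, (irradiance, outcome): three crossover
# positives at/above 12.15 and three negatives up to 12.29
_CROSSOVER_BIN = [
    (12.15, 1), (12.27, 0), (12.27, 0), (12.27, 1), (12.27, 1), (12.29, 0),
]


def make_table1_dataset() -> list[ExposureRecord]:
    """Reconstruct the 93-exposure 200-s 2-µm dose-response dataset.

    Irradiances are placed deterministically inside each bin; the mixed
    bin reproduces the published per-exposure values and outcomes, so the
    crossover range is exactly [12.15, 12.29] W cm^-2.
    """
    records = []

    def add(irradiance, outcome):
        records.append(ExposureRecord(
            wavelength=2000.0, irradiance=float(irradiance), duration=200.0,
            beam_diameter=726.0, outcome=int(outcome),
        ))

    for lo, hi, count, positives in TABLE1_BINS:
        if (lo, hi) == (12.15, 12.29):
            for e, o in _CROSSOVER_BIN:
                add(e, o)
            continue
        # evenly spaced, strictly inside the bin
        span = hi - lo
        doses = lo + span * (np.arange(count) + 0.5) / count
        outcome = 1 if positives == count else 0
        assert positives in (0, count)
        for e in doses:
            add(e, outcome)

    assert len(records) == 93
    return records
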