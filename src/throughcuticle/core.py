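"""Shared containers and error types for the through-cuticle multiphoton pipeline.

Conventions used throughout the package:

* Image stacks are ``(pages, rows, cols)`` arrays; page order is either depth
  (z-stacks) or time (movies).  Pixel coordinates are 0-based ``(row, col)``.
* Depth is page index x z-step, measured from the first acquired plane (the
  cuticle surface) in micrometres.
* All physical quantities carry unit-suffixed names (``z_step_um``,
  ``rep_rate_hz``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


# --------------------------------------------------------------------------- #
# errors
# --------------------------------------------------------------------------- #

class PipelineError(Exception):
    """Base class for all pipeline errors."""


class InputError(PipelineError):
    """Missing or unusable input (file absent, empty data, bad geometry)."""


class FormatError(PipelineError):
    """A file exists but its contents violate the expected layout."""


class ConfigError(PipelineError):
    """Inconsistent run configuration (unknown stage, schedule gap, ...)."""


class DomainError(PipelineError, ValueError):
    """A value outside the mathematical domain of an operation."""


class FitError(PipelineError):
    """A model fit failed or had too few usable points."""


class TrackingError(PipelineError):
    """The landmark tracker lost its target."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


# --------------------------------------------------------------------------- #
# acquisition / image containers
# --------------------------------------------------------------------------- #

@dataclass
class AcquisitionParams:
    """Laser and scan parameters of one acquisition.

    ``excitation_order`` is the nonlinear order n of the contrast: 2 for
    two-photon fluorescence at ~920 nm, 3 for three-photon fluorescence or
    THG at ~1320 nm.
    """

    wavelength_nm: float
    excitation_order: int
    rep_rate_hz: float
    pulse_width_fs: float = 60.0
    frame_rate_hz: float | None = None
    pixel_dwell_s: float | None = None

    def __post_init__(self) -> None:
        if self.excitation_order not in (2, 3):
            raise DomainError(f"excitation order must be 2 or 3, got {self.excitation_order}")
        for name in ("wavelength_nm", "rep_rate_hz", "pulse_width_fs"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


@dataclass
class ImageStack:
    """A z- or t-ordered pixel array with its spacing metadata.

    Spacing fields are ``None`` when unknown (single-page files, missing
    sidecar).  ``channel`` labels the contrast modality.
    """

    data: np.ndarray
    z_step_um: float | None = None
    frame_rate_hz: float | None = None
    pixel_size_um: float | None = None
    channel: str = "fluorescence"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise InputError(f"stack must be 2D or 3D, got shape {arr.shape}")
        if arr.size == 0:
            raise InputError("empty stack")
        self.data = arr

    @property
    def n_pages(self) -> int:
        return self.data.shape[0]

    @property
    def depths_um(self) -> np.ndarray:
        """Depth of each page from the first plane; requires a known z-step."""
        if self.z_step_um is None:
            raise ConfigError("z-step unknown; cannot assign depths")
        return np.arange(self.n_pages) * float(self.z_step_um)

    @property
    def times_s(self) -> np.ndarray:
        if self.frame_rate_hz is None:
            raise ConfigError("frame rate unknown; cannot assign times")
        return np.arange(self.n_pages) / float(self.frame_rate_hz)


@dataclass
class PowerSchedule:
    """Surface laser power as a function of imaging depth.

    Depths must be strictly ascending (duplicates are rejected); power is
    interpolated linearly between tabulated depths and querying outside the
    tabulated range is a configuration error (a schedule "gap").
    """

    depths_um: np.ndarray
    power_mw: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_um, dtype=float)
        p = np.asarray(self.power_mw, dtype=float)
        if d.ndim != 1 or d.shape != p.shape:
            raise FormatError("depth and power columns must be 1D and equal length")
        if d.size == 0:
            raise FormatError("empty power schedule")
        if np.any(np.diff(d) < 0):
            raise FormatError("depth column must be monotone nondecreasing")
        if np.any(np.diff(d) == 0):
            raise FormatError("duplicate depths in power schedule")
        if np.any(p <= 0):
            raise DomainError("power must be positive")
        self.depths_um, self.power_mw = d, p

    def power_at(self, z_um) -> np.ndarray:
        z = np.asarray(z_um, dtype=float)
        lo, hi = self.depths_um[0], self.depths_um[-1]
        if np.any(z < lo - 1e-9) or np.any(z > hi + 1e-9):
            raise ConfigError(
                f"schedule gap: depth outside tabulated range [{lo}, {hi}] um"
            )
        return np.interp(z, self.depths_um, self.power_mw)

    def __len__(self) -> int:
        return self.depths_um.size


# --------------------------------------------------------------------------- #
# attenuation / PSF models
# --------------------------------------------------------------------------- #

@dataclass
class AttenuationProfile:
    """Piecewise-constant effective attenuation length (EAL) versus depth.

    ``layers`` is a list of ``(z_start_um, z_end_um, eal_um)``; layers must be
    contiguous and non-overlapping with positive EAL.  Excitation light
    attenuates as exp(-z/EAL) within a layer, so the accumulated exponent at
    depth z is the integral of 1/EAL over [0, z].
    """

    layers: Sequence[tuple[float, float, float]]
    excitation_order: int = 3

    def __post_init__(self) -> None:
        if self.excitation_order not in (2, 3):
            raise DomainError("excitation order must be 2 or 3")
        layers = [tuple(map(float, l)) for l in self.layers]
        if not layers:
            raise ConfigError("at least one layer required")
        for z0, z1, eal in layers:
            if z1 <= z0:
                raise ConfigError("layer end must exceed start")
            if eal <= 0:
                raise DomainError("EAL must be positive")
        for (_, z1, _), (z0n, _, _) in zip(layers, layers[1:]):
            if abs(z1 - z0n) > 1e-9:
                raise ConfigError("layers must be contiguous and non-overlapping")
        self.layers = layers

    @property
    def z_max_um(self) -> float:
        return self.layers[-1][1]

    def exponent(self, z_um) -> np.ndarray:
        """Accumulated attenuation exponent integral_0^z dz'/EAL(z')."""
        z = np.atleast_1d(np.asarray(z_um, dtype=float))
        out = np.zeros_like(z)
        for z0, z1, eal in self.layers:
            overlap = np.clip(z, z0, z1) - z0
            out += np.clip(overlap, 0.0, z1 - z0) / eal
        return out if np.ndim(z_um) else float(out[0])


@dataclass
class PSFModel:
    """Gaussian-lateral / Lorentzian-power-axial point-spread model.

    ``axial_hw_um`` is the Lorentzian half-width parameter gamma; the axial
    intensity response is [1 + (z/gamma)^2]^(-k) with k the excitation order.
    """

    lateral_sigma_um: float
    axial_hw_um: float
    axial_power: int = 3

    def __post_init__(self) -> None:
        if self.lateral_sigma_um <= 0 or self.axial_hw_um <= 0:
            raise DomainError("PSF widths must be positive")
        if self.axial_power not in (2, 3):
            raise DomainError("axial power must be 2 or 3")

    @property
    def lateral_fwhm_um(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.lateral_sigma_um

    @property
    def axial_fwhm_um(self) -> float:
        return 2.0 * self.axial_hw_um * np.sqrt(2.0 ** (1.0 / self.axial_power) - 1.0)


# --------------------------------------------------------------------------- #
# scene phantom
# --------------------------------------------------------------------------- #

@dataclass
class Sphere:
    center_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float
    weight: float = 1.0
    channel: str = "fluorescence"


@dataclass
class Tube:
    p0_um: tuple[float, float, float]
    p1_um: tuple[float, float, float]
    radius_um: float
    weight: float = 1.0
    channel: str = "fluorescence"


@dataclass
class Slab:
    z0_um: float
    z1_um: float
    weight: float = 1.0
    channel: str = "fluorescence"


@dataclass
class ScenePhantom:
    """Voxelized scene of geometric primitives standing in for brain structures
    (mushroom-body lobes, ellipsoid-body ring, tracheal branches)."""

    grid: tuple[int, int, int]  # (nz, ny, nx) voxels
    pixel_size_um: float
    z_step_um: float
    structures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise DomainError("voxel spacings must be positive")
        for s in self.structures:
            if s.weight < 0:
                raise DomainError("brightness weights must be nonnegative")


@dataclass
class GroundTruth:
    """Stage-specific generating parameters returned next to every synthetic
    data product, sufficient for the matching estimator's recovery test."""

    values: dict

    def __getitem__(self, key):
        return self.values[key]

    def __contains__(self, key) -> bool:
        return key in self.values


# --------------------------------------------------------------------------- #
# traces
# --------------------------------------------------------------------------- #

@dataclass
class Trace:
    """A uniformly sampled ROI fluorescence time series."""

    times_s: np.ndarray
    values: np.ndarray
    frame_rate_hz: float
    stim_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise InputError("times and values must be equal-length 1D arrays")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise InputError("trace sampling must be uniform")
        if self.stim_mask is not None:
            m = np.asarray(self.stim_mask, dtype=bool)
            if m.shape != t.shape:
                raise InputError("stimulus mask length mismatch")
            self.stim_mask = m
        self.times_s, self.values = t, v

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class DFFTrace:
    """Normalized fluorescence (F - F0)/F0 with its baseline provenance."""

    times_s: np.ndarray
    values: np.ndarray
    frame_rate_hz: float
    f0: np.ndarray | float
    baseline_mode: str  # "prestim" | "rolling"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("dF/F0 values must be finite")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class StimulusTimeline:
    """Stimulus onsets/durations in seconds with a modality label."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    label: str = "odor"

    def __post_init__(self) -> None:
        on = np.atleast_1d(np.asarray(self.onsets_s, dtype=float))
        du = np.atleast_1d(np.asarray(self.durations_s, dtype=float))
        if du.size == 1 and on.size > 1:
            du = np.full(on.size, du[0])
        if on.shape != du.shape:
            raise InputError("onsets and durations length mismatch")
        if np.any(np.diff(on) < 0):
            raise InputError("onsets must be ascending")
        if np.any(du <= 0):
            raise DomainError("durations must be positive")
        self.onsets_s, self.durations_s = on, du

    def mask(self, times_s: np.ndarray) -> np.ndarray:
        """Boolean mask of samples falling inside any stimulus interval."""
        t = np.asarray(times_s, dtype=float)
        m = np.zeros(t.shape, dtype=bool)
        for on, du in zip(self.onsets_s, self.durations_s):
            m |= (t >= on) & (t < on + du)
        return m


# --------------------------------------------------------------------------- #
# PMT stream
# --------------------------------------------------------------------------- #

@dataclass
class PMTStream:
    """Uniformly sampled detector record plus the 2P gate waveform, the 3P
    pulse arrival times, and the pixel clock used to bin samples into images."""

    samples: np.ndarray
    sample_rate_hz: float
    gate: np.ndarray
    pulse_times_s: np.ndarray
    pixel_dwell_s: float
    pixels_per_line: int
    lines_per_frame: int
    detector_bandwidth_hz: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.gate = np.asarray(self.gate, dtype=bool)
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=float)
        if self.samples.shape != self.gate.shape:
            raise InputError("samples and gate must be equal length")
        if np.any(np.diff(self.pulse_times_s) <= 0):
            raise InputError("pulse times must be strictly ascending")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


# --------------------------------------------------------------------------- #
# behavior
# --------------------------------------------------------------------------- #

@dataclass
class BehaviorTrace:
    """Per-frame spherical-treadmill delta rotations (rad) about the three
    ball axes, in (roll, pitch, yaw) order, with the ball radius in mm.

    Axis meaning follows the FicTrac lab-frame convention: pitch drives
    forward translation, yaw drives turning.  ``gaps`` lists frame indices
    that were missing from the source log.
    """

    times_s: np.ndarray
    deltas_rad: np.ndarray  # (n, 3) columns roll, pitch, yaw
    ball_radius_mm: float
    frame_rate_hz: float = 8.0
    gaps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        d = np.asarray(self.deltas_rad, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise FormatError("delta rotations must be an (n, 3) array")
        if d.shape[0] != self.times_s.size:
            raise FormatError("times / deltas length mismatch")
        if self.ball_radius_mm <= 0:
            raise DomainError("ball radius must be positive")
        self.deltas_rad = d

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def roll(self) -> np.ndarray:
        return self.deltas_rad[:, 0]

    @property
    def pitch(self) -> np.ndarray:
        return self.deltas_rad[:, 1]

    @property
    def yaw(self) -> np.ndarray:
        return self.deltas_rad[:, 2]


@dataclass
class SpeedTrace:
    """Forward (mm/s) and rotational (rad/s) speed time series; NaN marks
    samples flagged missing by windowed downsampling."""

    times_s: np.ndarray
    forward_mm_s: np.ndarray
    rotational_rad_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.forward_mm_s = np.asarray(self.forward_mm_s, dtype=float)
        self.rotational_rad_s = np.asarray(self.rotational_rad_s, dtype=float)
        if not (self.times_s.shape == self.forward_mm_s.shape == self.rotational_rad_s.shape):
            raise InputError("speed trace columns must be equal length")

    def __len__(self) -> int:
        return self.times_s.size
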