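"""Effective attenuation length (EAL) estimation from depth stacks.

The per-frame signal S is the mean of the brightest 0.25% of pixels, power
normalized to S/P^n for excitation order n, and regressed log-linearly
against depth.  With excitation attenuating as exp(-z/EAL), the generated
signal scales as exp(-n z/EAL), so ln(S/P^n) has slope -n/EAL and

    EAL = -n / slope.

The factor n makes 2P and 3P EALs directly comparable; the regression itself
is ordinary unweighted least squares on the natural log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    AcquisitionParams,
    DomainError,
    FitError,
    ImageStack,
    InputError,
    PowerSchedule,
)

TOP_FRACTION_DEFAULT = 0.0025  # brightest 0.25% of pixels


@dataclass
class DepthProfile:
    """Per-depth raw signal, surface power and the power-normalized signal."""

    depths_um: np.ndarray
    signal: np.ndarray
    power_mw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        for name in ("depths_um", "signal", "power_mw", "normalized"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.depths_um.size
        if not all(getattr(self, f).size == n for f in ("signal", "power_mw", "normalized")):
            raise InputError("profile columns must be equal length")
        if np.any(np.diff(self.depths_um) <= 0):
            raise InputError("depths must be strictly ascending")
        if np.any(self.power_mw <= 0):
            raise DomainError("powers must be positive")


@dataclass
class EALFit:
    """Log-linear regression result over one depth window."""

    window_um: tuple[float, float]
    slope_per_um: float
    eal_um: float | None  # None when the slope is nonnegative (undefined)
    r_squared: float
    n_points: int
    n_excluded: int = 0
    excitation_order: int = 3

    @property
    def defined(self) -> bool:
        return self.eal_um is not None


@dataclass
class PhotonCalibration:
    """Conversion between pixel intensity and detected photon number."""

    photons_per_unit: float
    pulse_energy_nj: float | None = None
    reference_pulse_width_fs: float = 60.0

    def __post_init__(self) -> None:
        if self.photons_per_unit <= 0:
            raise DomainError("calibration factor must be positive")


# --------------------------------------------------------------------------- #
# signal extraction and normalization
# --------------------------------------------------------------------------- #

def frame_signal(frame: np.ndarray, fraction: float = TOP_FRACTION_DEFAULT) -> float:
    """Mean of the brightest ``fraction`` of pixels in a frame.

    k = max(1, round(fraction * N)) with round-half-away-from-zero; ties at
    the k-th value are irrelevant to the mean since tied values are equal.
    """
    arr = np.asarray(frame, dtype=float).ravel()
    if arr.size == 0:
        raise InputError("empty frame")
    if not (0.0 < fraction <= 1.0):
        raise DomainError("fraction must lie in (0, 1]")
    k = max(1, int(math.floor(fraction * arr.size + 0.5)))
    if k >= arr.size:
        return float(arr.mean())
    top = np.partition(arr, arr.size - k)[arr.size - k:]
    return float(top.mean())


def normalize_profile(signal, power, order: int) -> np.ndarray:
    """Elementwise S / P^n: S/P^2 for 2P stacks, S/P^3 for 3P/THG stacks."""
    s = np.asarray(signal, dtype=float)
    p = np.asarray(power, dtype=float)
    if s.shape != p.shape:
        raise InputError("signal and power must be equal length")
    if np.any(p <= 0):
        raise DomainError("powers must be positive")
    if order not in (2, 3):
        raise DomainError("excitation order must be 2 or 3")
    return s / p ** order


def profile_from_stack(
    stack: ImageStack,
    schedule: PowerSchedule,
    order: int,
    fraction: float = TOP_FRACTION_DEFAULT,
    depth_offset_um: float = 0.0,
) -> DepthProfile:
    """Build a DepthProfile from a z-stack and its power schedule.

    ``depth_offset_um`` shifts the depth origin (e.g. from cuticle surface to
    brain surface).
    """
    depths = stack.depths_um + depth_offset_um
    sig = np.array([frame_signal(stack.data[i], fraction) for i in range(stack.n_pages)])
    power = schedule.power_at(stack.depths_um)
    return DepthProfile(depths, sig, power, normalize_profile(sig, power, order))


# --------------------------------------------------------------------------- #
# EAL regression
# --------------------------------------------------------------------------- #

def fit_eal(profile: DepthProfile, window_um: tuple[float, float], order: int) -> EALFit:
    """OLS regression of ln(S/P^n) on depth within a closed window.

    Points with nonpositive normalized signal are excluded (and counted)
    rather than clamped.  A nonnegative slope yields an undefined EAL flag.
    """
    z_lo, z_hi = float(window_um[0]), float(window_um[1])
    if z_hi <= z_lo:
        raise InputError("window upper bound must exceed lower bound")
    inside = (profile.depths_um >= z_lo) & (profile.depths_um <= z_hi)
    usable = inside & (profile.normalized > 0)
    n_excl = int(inside.sum() - usable.sum())
    if usable.sum() < 3:
        raise FitError(
            f"need >=3 usable points in window [{z_lo}, {z_hi}] um, have {int(usable.sum())}"
        )
    x = profile.depths_um[usable]
    y = np.log(profile.normalized[usable])
    res = stats.linregress(x, y)
    slope = float(res.slope)
    eal = (-order / slope) if slope < 0 else None
    return EALFit(
        window_um=(z_lo, z_hi),
        slope_per_um=slope,
        eal_um=eal,
        r_squared=float(res.rvalue**2),
        n_points=int(usable.sum()),
        n_excluded=n_excl,
        excitation_order=order,
    )


def piecewise_eal(
    profile: DepthProfile,
    windows: Sequence[tuple[float, float]],
    order: int,
) -> list[EALFit]:
    """One fit per depth window; windows may share endpoints but not overlap."""
    ws = sorted((float(a), float(b)) for a, b in windows)
    for (_, hi), (lo, _) in zip(ws, ws[1:]):
        if lo < hi - 1e-9:
            raise InputError("windows overlap beyond shared endpoints")
    return [fit_eal(profile, w, order) for w in ws]


def eal_ratio(a: EALFit, b: EALFit) -> float:
    """Ratio a.EAL / b.EAL, e.g. cuticle-removed over cuticle-intact (~1.5x)."""
    if not (a.defined and b.defined):
        raise DomainError("both EALs must be defined")
    return a.eal_um / b.eal_um


# --------------------------------------------------------------------------- #
# photon / pulse-energy calibration
# --------------------------------------------------------------------------- #

def photons_per_pulse(
    frame: np.ndarray,
    cal: PhotonCalibration,
    params: AcquisitionParams,
    fraction: float = TOP_FRACTION_DEFAULT,
) -> float:
    """Detected photons per laser pulse from the brightest-pixel signal.

    photons/pixel = frame_signal * calibration factor; pulses/pixel =
    pixel dwell * repetition rate; the quotient is photons per pulse.
    """
    if params.pixel_dwell_s is None or params.pixel_dwell_s * params.rep_rate_hz == 0:
        raise DomainError("pixel dwell and repetition rate must be set and positive")
    photons_px = frame_signal(frame, fraction) * cal.photons_per_unit
    pulses_px = params.pixel_dwell_s * params.rep_rate_hz
    return photons_px / pulses_px


def pulse_energy_for_target(
    measured_pp: float,
    measured_energy_nj: float,
    order: int,
    pulse_width_fs: float,
    target_pp: float = 0.1,
    reference_width_fs: float = 60.0,
) -> float:
    """Pulse energy required for a target photons-per-pulse, normalized to a
    60 fs reference pulse width.

    Signal scales as E^n / tau^(n-1), so the energy at native width tau is
    E_req = E_meas * (target/measured)^(1/n) and the width-normalized value
    is E_req * (tau0/tau)^((n-1)/n).
    """
    if measured_pp <= 0 or measured_energy_nj <= 0 or target_pp <= 0:
        raise DomainError("photon rates and energies must be positive")
    if pulse_width_fs <= 0 or reference_width_fs <= 0:
        raise DomainError("pulse widths must be positive")
    if order not in (2, 3):
        raise DomainError("excitation order must be 2 or 3")
    e_req = measured_energy_nj * (target_pp / measured_pp) ** (1.0 / order)
    return e_req * (reference_width_fs / pulse_width_fs) ** ((order - 1.0) / order)
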