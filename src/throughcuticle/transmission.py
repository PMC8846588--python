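"""Cuticle optical transmission: ballistic and total transmission fractions.

Both modes use the same ratio of transmitted power through the sample to the
reference power through the mounting resin alone; the mode only records which
detector geometry (single-mode fiber vs integrating sphere) produced the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DomainError, InputError


@dataclass
class TransmissionMeasurement:
    """One (sample, reference) power pair at a wavelength and location."""

    wavelength_nm: float
    mode: str  # "ballistic" | "total"
    p_t_mw: float
    p_t0_mw: float
    location_um: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("ballistic", "total"):
            raise InputError(f"unknown transmission mode {self.mode!r}")
        if self.p_t_mw < 0:
            raise DomainError("transmitted power must be nonnegative")


@dataclass
class TransmissionSummary:
    wavelength_nm: float
    mode: str
    mean_fraction: float
    sem: float
    n: int
    flagged_above_one: int = 0


def transmission_fraction(m: TransmissionMeasurement) -> float:
    """Power ratio P_T / P_T0 of transmitted to reference power.

    Identical formula for ballistic and total modes.  Fractions above 1 are
    returned as-is (measurement noise can exceed the reference); callers that
    summarize flag them.
    """
    if m.p_t0_mw <= 0:
        raise DomainError("reference power P_T0 must be positive")
    return m.p_t_mw / m.p_t0_mw


def summarize_wavelength(ms: Sequence[TransmissionMeasurement]) -> TransmissionSummary:
    """Mean and SEM (sample SD / sqrt(n), n-1 denominator) of the fractions.

    All measurements must share wavelength and mode.  n = 1 gives SEM 0 with
    a warning.
    """
    ms = list(ms)
    if not ms:
        raise InputError("no measurements to summarize")
    wl = {m.wavelength_nm for m in ms}
    mode = {m.mode for m in ms}
    if len(wl) > 1:
        raise InputError(f"mixed wavelengths {sorted(wl)}")
    if len(mode) > 1:
        raise InputError(f"mixed modes {sorted(mode)}")
    fr = np.array([transmission_fraction(m) for m in ms])
    n = fr.size
    if n == 1:
        warnings.warn("single measurement: SEM set to 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(np.std(fr, ddof=1) / np.sqrt(n))
    return TransmissionSummary(
        wavelength_nm=ms[0].wavelength_nm,
        mode=ms[0].mode,
        mean_fraction=float(np.mean(fr)),
        sem=sem,
        n=n,
        flagged_above_one=int(np.sum(fr > 1.0)),
    )


def transmission_map(
    ms: Sequence[TransmissionMeasurement],
    grid_spacing_um: float,
    shape: tuple[int, int] | None = None,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Nearest-bin gridding of located fractions into a 2D (y, x) map.

    Bin index = round((coord - origin)/spacing).  Multiple measurements in a
    bin are averaged; empty bins are NaN.  With an explicit ``shape``, points
    outside the grid extent are an input error; otherwise the extent is
    inferred from the points.
    """
    ms = list(ms)
    if not ms:
        raise InputError("no measurements to grid")
    if any(m.location_um is None for m in ms):
        raise InputError("all measurements must carry locations")
    if grid_spacing_um <= 0:
        raise DomainError("grid spacing must be positive")
    xy = np.array([m.location_um for m in ms], dtype=float)
    fr = np.array([transmission_fraction(m) for m in ms])
    ix = np.rint((xy[:, 0] - origin_um[0]) / grid_spacing_um).astype(int)
    iy = np.rint((xy[:, 1] - origin_um[1]) / grid_spacing_um).astype(int)
    if shape is None:
        if np.any(ix < 0) or np.any(iy < 0):
            raise InputError("point before grid origin")
        shape = (int(iy.max()) + 1, int(ix.max()) + 1)
    else:
        if (np.any(ix < 0) or np.any(iy < 0)
                or np.any(iy >= shape[0]) or np.any(ix >= shape[1])):
            raise InputError("point outside grid extent")
    total = np.zeros(shape)
    count = np.zeros(shape)
    np.add.at(total, (iy, ix), fr)
    np.add.at(count, (iy, ix), 1.0)
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out
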