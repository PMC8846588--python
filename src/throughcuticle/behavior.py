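"""Spherical-treadmill kinematics from delta-rotation logs.

Per-frame ball delta rotations (rad) are converted to forward speed
Sf = |pitch| * ball_radius / dt (mm/s) and rotational speed
Sr = |yaw| / dt (rad/s), downsampled from the 8 Hz camera rate to 5 Hz by
200 ms window averaging with linear interpolation of empty windows, and
summarized over 5 s windows before and after a stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BehaviorTrace, DomainError, InputError, SpeedTrace

AXIS_INDEX = {"roll": 0, "pitch": 1, "yaw": 2}


def speeds_from_deltas(
    trace: BehaviorTrace,
    forward_axis: str = "pitch",
    turn_axis: str = "yaw",
    signed: bool = False,
) -> SpeedTrace:
    """Forward/rotational speed magnitudes from per-frame delta rotations.

    The axis-to-meaning map is configurable; defaults follow the FicTrac
    lab-frame convention (pitch drives forward motion, yaw drives turning).
    ``signed=True`` keeps the rotation signs instead of magnitudes.
    """
    dt = 1.0 / trace.frame_rate_hz
    if dt <= 0:
        raise DomainError("frame interval must be positive")
    fwd = trace.deltas_rad[:, AXIS_INDEX[forward_axis]]
    turn = trace.deltas_rad[:, AXIS_INDEX[turn_axis]]
    if not signed:
        fwd, turn = np.abs(fwd), np.abs(turn)
    return SpeedTrace(
        trace.times_s.copy(),
        fwd * trace.ball_radius_mm / dt,
        turn / dt,
    )


def downsample_windows(
    trace: SpeedTrace,
    to_rate_hz: float = 5.0,
    window_s: float | None = None,
) -> SpeedTrace:
    """Window-average downsampling: output sample at time t is the mean of
    input samples with times in [t, t + window); empty windows are NaN
    (missing).  The window defaults to 1/to_rate (200 ms at 5 Hz)."""
    if to_rate_hz <= 0:
        raise DomainError("target rate must be positive")
    if window_s is None:
        window_s = 1.0 / to_rate_hz
    t0 = trace.times_s[0]
    span = trace.times_s[-1] - t0
    n_out = int(np.floor(span / window_s + 1e-9)) + 1
    new_t = t0 + np.arange(n_out) * window_s
    fwd = np.full(n_out, np.nan)
    rot = np.full(n_out, np.nan)
    bins = np.floor((trace.times_s - t0) / window_s + 1e-9).astype(int)
    for k in range(n_out):
        sel = bins == k
        if sel.any():
            fwd[k] = np.nanmean(trace.forward_mm_s[sel])
            rot[k] = np.nanmean(trace.rotational_rad_s[sel])
    return SpeedTrace(new_t, fwd, rot)


def interpolate_gaps(trace: SpeedTrace) -> SpeedTrace:
    """Linear interpolation of missing (NaN) samples between the nearest
    valid neighbors; leading/trailing gaps take the nearest valid value."""

    def fill(v: np.ndarray) -> np.ndarray:
        good = np.isfinite(v)
        if good.sum() < 2:
            raise InputError("need at least 2 non-missing samples")
        idx = np.arange(v.size)
        return np.interp(idx, idx[good], v[good])

    return SpeedTrace(
        trace.times_s.copy(), fill(trace.forward_mm_s), fill(trace.rotational_rad_s)
    )


def fictive_path(
    trace: BehaviorTrace,
    forward_axis: str = "pitch",
    turn_axis: str = "yaw",
) -> np.ndarray:
    """Dead-reckoning 2D fictive path in mm, starting at the origin.

    Heading accumulates the turn-axis deltas; each step advances by
    forward-delta * ball_radius along the current heading (roll ignored by
    default).  Returns an (n+1, 2) array of (x, y) positions.
    """
    fwd = trace.deltas_rad[:, AXIS_INDEX[forward_axis]]
    turn = trace.deltas_rad[:, AXIS_INDEX[turn_axis]]
    heading = np.cumsum(turn)
    step = fwd * trace.ball_radius_mm
    dx = step * np.cos(heading)
    dy = step * np.sin(heading)
    path = np.zeros((len(trace) + 1, 2))
    path[1:, 0] = np.cumsum(dx)
    path[1:, 1] = np.cumsum(dy)
    return path


@dataclass
class PrePostSummary:
    mean_before: float
    mean_after: float
    difference: float  # after - before


def prepost_summary(
    times_s: np.ndarray,
    values: np.ndarray,
    onset_s: float,
    window_s: float = 5.0,
    stimulus_duration_s: float = 0.0,
) -> PrePostSummary:
    """Mean speed over [onset - window, onset) versus
    [stim_end, stim_end + window) with stim_end = onset + stimulus duration;
    the post window is anchored after the stimulus ends."""
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    end = onset_s + stimulus_duration_s
    pre = (t >= onset_s - window_s) & (t < onset_s)
    post = (t >= end) & (t < end + window_s)
    if pre.sum() == 0 or post.sum() == 0:
        raise InputError("insufficient samples in the pre/post windows")
    before = float(np.nanmean(v[pre]))
    after = float(np.nanmean(v[post]))
    return PrePostSummary(before, after, after - before)


@dataclass
class PairedTResult:
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False  # zero-variance differences


def paired_t(diffs) -> PairedTResult:
    """Paired t-test on a list of per-trial differences (two-tailed p from
    the t distribution with n-1 df)."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise InputError("paired t needs at least 2 differences")
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        p = 0.0 if d.mean() != 0 else 1.0
        t_stat = np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
        return PairedTResult(float(t_stat), p, n, degenerate=True)
    t_stat = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    return PairedTResult(float(t_stat), float(p), n)
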