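"""Movie-to-trace functional imaging pipeline.

Implements the processing applied to GCaMP movies: block frame averaging,
disc median filtering, ROI trace extraction, the two baseline modes
(pre-stimulus mean of 10 frames; 4 s rolling average excluding stimulus
samples), (F - F0)/F0 normalization, trailing moving-mean smoothing, peak
quantification within a post-onset horizon, cubic-spline resampling,
integer-pixel translation registration, and landmark motion tracking.
"""

from __future__ import annotations

import numpy as np
from scipy import interpolate, ndimage

from .core import (
    DFFTrace,
    DomainError,
    ImageStack,
    InputError,
    Trace,
    TrackingError,
)

MEDIAN_RADIUS_DEFAULT = 10
PRESTIM_FRAMES_DEFAULT = 10
ROLLING_WINDOW_S_DEFAULT = 4.0
SMOOTH_WINDOW_DEFAULT = 8
PEAK_HORIZON_DEFAULT = 20
RESAMPLE_RATE_DEFAULT = 5.0


# --------------------------------------------------------------------------- #
# movie-level operations
# --------------------------------------------------------------------------- #

def average_frames(movie: ImageStack, k: int) -> ImageStack:
    """Average non-overlapping blocks of k frames; the trailing partial
    block is dropped and the effective frame rate becomes rate/k
    (17 Hz / 4 -> 4.25 Hz; 6.5 Hz / 5 -> 1.3 Hz)."""
    if k < 1:
        raise InputError("k must be >= 1")
    n = movie.n_pages
    if k > n:
        raise InputError(f"k={k} exceeds the {n} available frames")
    nb = n // k
    data = movie.data[: nb * k].reshape(nb, k, *movie.data.shape[1:]).mean(axis=1)
    rate = movie.frame_rate_hz / k if movie.frame_rate_hz else None
    return ImageStack(
        data,
        z_step_um=movie.z_step_um,
        frame_rate_hz=rate,
        pixel_size_um=movie.pixel_size_um,
        channel=movie.channel,
    )


def disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def median_filter_movie(
    movie: ImageStack, radius_px: int = MEDIAN_RADIUS_DEFAULT, square: bool = False
) -> ImageStack:
    """Per-frame 2D median over a disc (default) or square of the given
    radius; reflect-padded borders."""
    if radius_px < 1:
        raise InputError("radius must be >= 1")
    size = 2 * radius_px + 1
    foot = np.ones((size, size), bool) if square else disc_footprint(radius_px)
    out = np.stack(
        [
            ndimage.median_filter(f, footprint=foot, mode="reflect")
            for f in movie.data
        ]
    )
    return ImageStack(
        out,
        z_step_um=movie.z_step_um,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_size_um=movie.pixel_size_um,
        channel=movie.channel,
    )


def roi_trace(movie: ImageStack, mask: np.ndarray, stim_mask: np.ndarray | None = None) -> Trace:
    """Per-frame mean of pixels inside the boolean ROI mask."""
    m = np.asarray(mask, dtype=bool)
    if m.shape != movie.data.shape[1:]:
        raise InputError("mask shape must match the movie frames")
    if not m.any():
        raise InputError("empty ROI mask")
    vals = movie.data[:, m].mean(axis=1)
    rate = movie.frame_rate_hz if movie.frame_rate_hz else 1.0
    return Trace(np.arange(vals.size) / rate, vals, rate, stim_mask=stim_mask)


# --------------------------------------------------------------------------- #
# baselines and normalization
# --------------------------------------------------------------------------- #

def baseline_prestim(trace: Trace, onset_s: float, k_frames: int = PRESTIM_FRAMES_DEFAULT) -> float:
    """Mean of the k frames immediately preceding the stimulus-onset sample."""
    onset_idx = int(np.searchsorted(trace.times_s, onset_s - 1e-12))
    if onset_idx < k_frames:
        raise InputError(
            f"need {k_frames} pre-stimulus frames, have {onset_idx}"
        )
    return float(trace.values[onset_idx - k_frames : onset_idx].mean())


def baseline_rolling(
    trace: Trace,
    window_s: float = ROLLING_WINDOW_S_DEFAULT,
    stim_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Centered rolling-average baseline excluding stimulus samples.

    Each output sample is the mean of non-stimulus samples inside a centered
    window of ``window_s`` seconds (truncated at the edges).  Samples whose
    window contains only stimulus samples inherit the nearest valid baseline.
    """
    if stim_mask is None:
        stim_mask = trace.stim_mask
    n = len(trace)
    w = max(1, int(round(window_s * trace.frame_rate_hz)))
    if w > n:
        raise InputError("rolling window longer than the trace")
    valid = (
        np.ones(n, bool) if stim_mask is None else ~np.asarray(stim_mask, dtype=bool)
    )
    kernel = np.ones(w)
    num = np.convolve(np.where(valid, trace.values, 0.0), kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    f0 = np.full(n, np.nan)
    good = den > 0
    f0[good] = num[good] / den[good]
    if not good.all():
        if not good.any():
            raise InputError("no non-stimulus samples in any window")
        idx = np.arange(n)
        f0[~good] = np.interp(idx[~good], idx[good], f0[good])
    return f0


def dff(trace: Trace, f0) -> DFFTrace:
    """(F - F0)/F0 with a scalar or per-sample baseline."""
    f0_arr = np.asarray(f0, dtype=float)
    if np.any(f0_arr <= 0):
        raise DomainError("baseline F0 must be positive")
    values = (trace.values - f0_arr) / f0_arr
    mode = "prestim" if f0_arr.ndim == 0 else "rolling"
    return DFFTrace(trace.times_s, values, trace.frame_rate_hz, f0, mode)


def smooth_moving_mean(trace: DFFTrace, window_frames: int = SMOOTH_WINDOW_DEFAULT) -> DFFTrace:
    """Trailing moving mean with edge truncation: sample i averages the up to
    ``window_frames`` most recent samples."""
    w = int(window_frames)
    if w < 1:
        raise InputError("window must be >= 1")
    if w > len(trace):
        raise InputError("window longer than the trace")
    c = np.concatenate([[0.0], np.cumsum(trace.values)])
    idx = np.arange(len(trace))
    lo = np.clip(idx - w + 1, 0, None)
    out = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    return DFFTrace(trace.times_s, out, trace.frame_rate_hz, trace.f0, trace.baseline_mode)


def peak_dff(trace: DFFTrace, onset_s: float, horizon_frames: int = PEAK_HORIZON_DEFAULT) -> float:
    """Maximum dF/F0 within ``horizon_frames`` frames after stimulus onset."""
    start = int(np.searchsorted(trace.times_s, onset_s - 1e-12))
    if start >= len(trace):
        raise InputError("stimulus onset after the end of the trace")
    seg = trace.values[start : start + horizon_frames]
    return float(seg.max())


def resample_spline(trace, target_rate_hz: float = RESAMPLE_RATE_DEFAULT):
    """Cubic-spline resampling onto a uniform grid spanning the original
    times; returns the same trace type."""
    if target_rate_hz <= 0:
        raise DomainError("target rate must be positive")
    t = trace.times_s
    if t.size < 4:
        raise InputError("need at least 4 samples for cubic-spline resampling")
    spline = interpolate.CubicSpline(t, trace.values)
    n_new = int(np.floor((t[-1] - t[0]) * target_rate_hz)) + 1
    new_t = t[0] + np.arange(n_new) / target_rate_hz
    new_v = spline(new_t)
    if isinstance(trace, DFFTrace):
        return DFFTrace(new_t, new_v, target_rate_hz, trace.f0, trace.baseline_mode)
    return Trace(new_t, new_v, target_rate_hz)


# --------------------------------------------------------------------------- #
# registration and motion
# --------------------------------------------------------------------------- #

def _best_integer_shift(reference: np.ndarray, frame: np.ndarray) -> tuple[int, int]:
    """Integer shift (dr, dc) maximizing the circular cross-correlation of
    ``frame`` with ``reference`` (computed via FFT)."""
    f_ref = np.fft.rfft2(reference)
    f_img = np.fft.rfft2(frame)
    corr = np.fft.irfft2(f_ref * np.conj(f_img), s=reference.shape)
    dr, dc = np.unravel_index(np.argmax(corr), corr.shape)
    if dr > reference.shape[0] // 2:
        dr -= reference.shape[0]
    if dc > reference.shape[1] // 2:
        dc -= reference.shape[1]
    return int(dr), int(dc)


def register_translation(
    movie: ImageStack, reference: int = 0
) -> tuple[ImageStack, np.ndarray]:
    """Integer-pixel translation registration against one reference frame.

    Shifts are applied with zero fill and reported as (drow, dcol) pixels
    per frame (positive = the frame content was moved down/right to align).
    """
    if movie.n_pages < 2:
        raise InputError("need at least 2 frames to register")
    ref = movie.data[reference].astype(float)
    shifts = np.zeros((movie.n_pages, 2), dtype=int)
    out = np.empty_like(movie.data, dtype=float)
    for i, frame in enumerate(movie.data):
        dr, dc = (0, 0) if i == reference else _best_integer_shift(ref, frame.astype(float))
        shifts[i] = (dr, dc)
        out[i] = ndimage.shift(frame.astype(float), (dr, dc), order=0, cval=0.0)
    registered = ImageStack(
        out,
        z_step_um=movie.z_step_um,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_size_um=movie.pixel_size_um,
        channel=movie.channel,
    )
    return registered, shifts


def landmark_motion(
    movie: ImageStack,
    roi_mask: np.ndarray,
    pixel_size_um: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Track one bright landmark (e.g. a single neuron) by its
    intensity-weighted centroid, ROI recentered on the previous position.

    Returns ``(per-frame displacement um, mean displacement um, normalized
    intensity trace)``.  The intensity trace is (I - I0)/I0 with I0 the mean
    of the whole trace.  Tracking raises TrackingError (with the frame
    index) when the centroid reaches the ROI window border.
    """
    m = np.asarray(roi_mask, dtype=bool)
    if m.shape != movie.data.shape[1:]:
        raise InputError("ROI mask shape must match the movie frames")
    if not m.any():
        raise InputError("empty ROI mask")
    rows, cols = np.nonzero(m)
    hr = max((rows.max() - rows.min()) // 2, 1)
    hc = max((cols.max() - cols.min()) // 2, 1)
    cr = (rows.max() + rows.min()) / 2.0
    cc = (cols.max() + cols.min()) / 2.0

    ny, nx = movie.data.shape[1:]
    centers = np.zeros((movie.n_pages, 2))
    intens = np.zeros(movie.n_pages)
    for i, frame in enumerate(movie.data):
        r0 = int(round(cr)) - hr
        c0 = int(round(cc)) - hc
        r0 = int(np.clip(r0, 0, ny - (2 * hr + 1)))
        c0 = int(np.clip(c0, 0, nx - (2 * hc + 1)))
        win = frame[r0 : r0 + 2 * hr + 1, c0 : c0 + 2 * hc + 1].astype(float)
        w = win - win.min()
        tot = w.sum()
        if tot <= 0:
            raise TrackingError("landmark lost: flat window", frame=i)
        yy, xx = np.mgrid[0 : win.shape[0], 0 : win.shape[1]]
        wr = float((yy * w).sum() / tot)
        wc = float((xx * w).sum() / tot)
        if (
            wr < 1.0
            or wc < 1.0
            or wr > win.shape[0] - 2.0
            or wc > win.shape[1] - 2.0
        ):
            raise TrackingError("landmark centroid at ROI border", frame=i)
        cr, cc = r0 + wr, c0 + wc
        centers[i] = (cr, cc)
        intens[i] = win.sum()

    disp = np.hypot(np.diff(centers[:, 0]), np.diff(centers[:, 1])) * pixel_size_um
    i0 = intens.mean()
    norm = (intens - i0) / i0
    return disp, float(disp.mean()) if disp.size else 0.0, norm
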