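"""Temporal demultiplexing of interleaved 2P/3P excitation.

The 3P laser runs at a low repetition rate (400 kHz -> pulses 2.5 us apart)
while the 80 MHz 2P beam is gated by an EOM that transmits for 1 us centered
between consecutive 3P pulses.  A single PMT records both; samples are
assigned to the 3P channel inside a short response window after each pulse,
to the 2P channel while the gate is high and at least a guard time away from
any pulse-response window, and discarded otherwise.  Assigned samples are
summed into pixels via the pixel clock (row-major, unidirectional scan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, DomainError, GroundTruth, InputError, PMTStream

GATE_WIDTH_DEFAULT_S = 1e-6
GUARD_DEFAULT_S = 250e-9


@dataclass
class DemuxResult:
    image_2p: np.ndarray
    image_3p: np.ndarray
    discarded_fraction: float
    discarded_energy: float = 0.0


def build_gate(
    rep_rate_hz: float,
    sample_rate_hz: float,
    n_samples: int,
    gate_width_s: float = GATE_WIDTH_DEFAULT_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Gate waveform and 3P pulse times for a pulse train at ``rep_rate_hz``.

    Pulses sit at integer multiples of the period; the gate is high for
    ``gate_width_s`` centered at the midpoint between consecutive pulses.
    Returns ``(gate boolean array, pulse_times_s)``.
    """
    if rep_rate_hz <= 0 or sample_rate_hz <= 0:
        raise DomainError("rates must be positive")
    period = 1.0 / rep_rate_hz
    if gate_width_s >= period:
        raise ConfigError("gate width must be shorter than the pulse period")
    t = np.arange(n_samples) / sample_rate_hz
    phase = np.mod(t, period)
    mid = period / 2.0
    gate = np.abs(phase - mid) <= gate_width_s / 2.0 + 1e-15
    n_pulses = int(np.floor(t[-1] / period)) + 1 if n_samples else 0
    pulse_times = np.arange(n_pulses) * period
    return gate, pulse_times


def demultiplex(
    stream: PMTStream,
    guard_s: float = GUARD_DEFAULT_S,
    response_window_s: float | None = None,
) -> DemuxResult:
    """Split one PMT stream into simultaneous 2P and 3P images.

    ``response_window_s`` defaults to 3 detector time constants when the
    stream records a detector bandwidth, else to one sample period (an
    effectively rectangular response).
    """
    fs = stream.sample_rate_hz
    dwell = stream.pixel_dwell_s
    n_px = stream.pixels_per_line * stream.lines_per_frame
    frame_s = n_px * dwell
    if stream.duration_s < frame_s - 0.5 / fs:
        raise InputError("stream shorter than one frame")
    if response_window_s is None:
        if stream.detector_bandwidth_hz:
            tau = 1.0 / (2.0 * np.pi * stream.detector_bandwidth_hz)
            response_window_s = 3.0 * tau
        else:
            response_window_s = 1.0 / fs

    t = stream.times_s
    pulses = stream.pulse_times_s
    # time since the most recent pulse / until the next pulse; the half-sample
    # tolerance keeps a sample that coincides with a pulse (up to float
    # rounding) in that pulse's response window
    half = 0.5 / fs
    idx = np.searchsorted(pulses, t + half, side="right")
    dt_after = np.where(idx > 0, t - pulses[np.clip(idx - 1, 0, None)], np.inf)
    dt_before = np.where(
        idx < pulses.size, pulses[np.clip(idx, 0, pulses.size - 1)] - t, np.inf
    )
    in_3p = dt_after <= response_window_s + half
    clear_of_3p = (dt_after >= response_window_s + guard_s) & (dt_before >= guard_s)
    in_2p = stream.gate & clear_of_3p & ~in_3p
    discarded = ~(in_3p | in_2p)

    px = np.floor(t / dwell + 1e-12).astype(int)
    valid = px < n_px
    shape = (stream.lines_per_frame, stream.pixels_per_line)
    img3 = np.zeros(n_px)
    img2 = np.zeros(n_px)
    np.add.at(img3, px[in_3p & valid], stream.samples[in_3p & valid])
    np.add.at(img2, px[in_2p & valid], stream.samples[in_2p & valid])
    n_valid = int(valid.sum())
    disc_frac = float((discarded & valid).sum() / n_valid) if n_valid else 1.0
    return DemuxResult(
        image_2p=img2.reshape(shape),
        image_3p=img3.reshape(shape),
        discarded_fraction=disc_frac,
        discarded_energy=float(stream.samples[discarded & valid].sum()),
    )


def crosstalk(result: DemuxResult, truth: GroundTruth) -> tuple[float, float]:
    """Channel leakage fractions by least-squares unmixing against the true
    scenes.

    Each recovered image is regressed on the two generating scenes
    (normalized to unit total intensity); the leak fraction is the share of
    recovered linear signal attributable to the other channel's scene.
    Returns ``(fraction of the 3P image coming from the 2P scene,
    fraction of the 2P image coming from the 3P scene)``.
    """
    s2 = np.asarray(truth["scene_2p"], dtype=float).ravel()
    s3 = np.asarray(truth["scene_3p"], dtype=float).ravel()
    if s2.sum() <= 0 or s3.sum() <= 0:
        raise DomainError("true scenes must have positive total intensity")
    u2, u3 = s2 / s2.sum(), s3 / s3.sum()
    basis = np.column_stack([u2, u3])
    # collinear scenes cannot be unmixed
    if np.linalg.matrix_rank(basis, tol=1e-10) < 2:
        raise DomainError("degenerate (collinear) scenes cannot be unmixed")

    def leak(image: np.ndarray, other_col: int) -> float:
        coef, *_ = np.linalg.lstsq(basis, image.ravel(), rcond=None)
        coef = np.clip(coef, 0.0, None)  # signal is nonnegative
        total = coef.sum()
        if total == 0:
            return 0.0
        return float(coef[other_col] / total)

    frac_2p_in_3p = leak(result.image_3p, 0)
    frac_3p_in_2p = leak(result.image_2p, 1)
    return frac_2p_in_3p, frac_3p_in_2p
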