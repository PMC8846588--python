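"""Synthetic generators for every input the pipeline consumes.

Each generator returns its data product together with a :class:`GroundTruth`
carrying the generating parameters, so every estimator has a matching
parameter-recovery test with no external data.  The physics emulated:

* depth-exponential excitation attenuation with a known piecewise EAL and
  nonlinear signal order n (signal ~ P^n exp(-n z/EAL));
* Gaussian-lateral / Lorentzian^k-axial PSF blur;
* Poisson shot noise (PMT photon counting dominates; no read noise);
* GCaMP-like stimulus-locked double-exponential transients;
* interleaved 400 kHz / 80 MHz pulse trains with a 1 us EOM gate;
* Rayleigh frame-to-frame jitter of a bright landmark;
* odor-evoked gain changes in treadmill delta-rotation logs.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; identical seed and configuration give bit-identical outputs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (
    AcquisitionParams,
    AttenuationProfile,
    BehaviorTrace,
    ConfigError,
    DomainError,
    GroundTruth,
    ImageStack,
    InputError,
    PMTStream,
    PowerSchedule,
    PSFModel,
    ScenePhantom,
    Slab,
    Sphere,
    StimulusTimeline,
    Tube,
)
from .demux import build_gate
from .transmission import TransmissionMeasurement

# GCaMP6s-like kinetics: plausible slow-indicator values, free parameters
# of the generator (see docs/methods.md), not measured constants.
CA_RISE_S_DEFAULT = 0.18
CA_DECAY_S_DEFAULT = 1.2


# --------------------------------------------------------------------------- #
# phantom rasterization
# --------------------------------------------------------------------------- #

def rasterize_phantom(phantom: ScenePhantom, channel: str | None = None) -> np.ndarray:
    """Brightness-weighted occupancy volume (nz, ny, nx) of the phantom's
    primitives, optionally restricted to one channel tag."""
    nz, ny, nx = phantom.grid
    vol = np.zeros((nz, ny, nx))
    zs = np.arange(nz) * phantom.z_step_um
    ys = np.arange(ny) * phantom.pixel_size_um
    xs = np.arange(nx) * phantom.pixel_size_um
    for s in phantom.structures:
        if channel is not None and s.channel != channel:
            continue
        if isinstance(s, Slab):
            sel = (zs >= s.z0_um) & (zs <= s.z1_um)
            vol[sel] += s.weight
        elif isinstance(s, Sphere):
            cz, cy, cx = s.center_um
            d2 = (
                (zs[:, None, None] - cz) ** 2
                + (ys[None, :, None] - cy) ** 2
                + (xs[None, None, :] - cx) ** 2
            )
            vol += s.weight * (d2 <= s.radius_um**2)
        elif isinstance(s, Tube):
            p0 = np.asarray(s.p0_um, dtype=float)
            p1 = np.asarray(s.p1_um, dtype=float)
            axis = p1 - p0
            L2 = float(axis @ axis)
            if L2 == 0:
                raise InputError("tube endpoints coincide")
            Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
            pts = np.stack([Z, Y, X], axis=-1) - p0
            t = np.clip(pts @ axis / L2, 0.0, 1.0)
            nearest = t[..., None] * axis
            d2 = np.sum((pts - nearest) ** 2, axis=-1)
            vol += s.weight * (d2 <= s.radius_um**2)
        else:
            raise InputError(f"unknown primitive {type(s).__name__}")
    return vol


def _lorentzian_power_kernel(hw_um: float, k: int, z_step_um: float) -> np.ndarray:
    """Normalized 1D axial blur kernel [1 + (z/gamma)^2]^(-k)."""
    half = max(int(np.ceil(4.0 * hw_um / z_step_um)), 0)
    z = np.arange(-half, half + 1) * z_step_um
    ker = (1.0 + (z / hw_um) ** 2) ** (-float(k))
    return ker / ker.sum()


def apply_psf(volume: np.ndarray, psf: PSFModel, pixel_size_um: float, z_step_um: float) -> np.ndarray:
    """Gaussian lateral blur per plane and Lorentzian^k blur along z
    (reflect padding)."""
    sigma_px = psf.lateral_sigma_um / pixel_size_um
    out = ndimage.gaussian_filter(volume, sigma=(0.0, sigma_px, sigma_px), mode="reflect")
    ker = _lorentzian_power_kernel(psf.axial_hw_um, psf.axial_power, z_step_um)
    if ker.size > 1:
        out = ndimage.convolve1d(out, ker, axis=0, mode="reflect")
    return out


# --------------------------------------------------------------------------- #
# depth stacks
# --------------------------------------------------------------------------- #

def make_phantom_stack(
    phantom: ScenePhantom,
    params: AcquisitionParams,
    atten: AttenuationProfile,
    psf: PSFModel,
    schedule: PowerSchedule,
    photon_budget: float,
    seed: int,
    shot_noise: bool = True,
    channel: str | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Depth stack with known attenuation, PSF and power schedule.

    The expected photon count at depth z scales as

        photon_budget * (P(z)/P(0))^n * exp(-n * A(z))

    with A(z) the piecewise-accumulated attenuation exponent.  Pixels are
    independent Poisson draws around the structure-weighted expectation
    after PSF blur (``shot_noise=False`` returns the expectation itself).
    """
    if photon_budget < 0:
        raise DomainError("photon budget must be nonnegative")
    n = params.excitation_order
    vol = rasterize_phantom(phantom, channel=channel)
    blurred = apply_psf(vol, psf, phantom.pixel_size_um, phantom.z_step_um)
    depths = np.arange(phantom.grid[0]) * phantom.z_step_um
    power = schedule.power_at(depths)  # raises ConfigError on a schedule gap
    p0 = schedule.power_at(0.0)
    factor = photon_budget * (power / p0) ** n * np.exp(-n * atten.exponent(depths))
    expect = blurred * factor[:, None, None]
    rng = np.random.default_rng(seed)
    data = rng.poisson(expect).astype(float) if shot_noise else expect
    stack = ImageStack(
        data,
        z_step_um=phantom.z_step_um,
        pixel_size_um=phantom.pixel_size_um,
        channel=channel or "fluorescence",
    )
    truth = GroundTruth(
        {
            "attenuation_layers": list(atten.layers),
            "excitation_order": n,
            "psf": psf,
            "depth_factor": factor,
            "power_mw": power,
            "expectation": expect,
        }
    )
    return stack, truth


# --------------------------------------------------------------------------- #
# calcium movies
# --------------------------------------------------------------------------- #

def transient_kernel(t_s, rise_s: float = CA_RISE_S_DEFAULT, decay_s: float = CA_DECAY_S_DEFAULT) -> np.ndarray:
    """Unit-peak double-exponential indicator kernel, zero for t < 0.

    Normalizing to unit peak makes the generator's ``amplitude`` the true
    peak dF/F0 of each transient.
    """
    t = np.asarray(t_s, dtype=float)
    if rise_s <= 0 or decay_s <= 0:
        raise DomainError("kinetic constants must be positive")
    if abs(decay_s - rise_s) < 1e-12:
        tau = decay_s
        raw = np.where(t >= 0, t / tau * np.exp(1.0 - t / tau), 0.0)
        return raw
    raw = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return raw / peak


def make_calcium_movie(
    roi_layout: ScenePhantom,
    stim: StimulusTimeline,
    amplitude: float,
    duration_s: float,
    frame_rate_hz: float = 17.0,
    rise_s: float = CA_RISE_S_DEFAULT,
    decay_s: float = CA_DECAY_S_DEFAULT,
    baseline: float = 100.0,
    drift_per_s: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, list[np.ndarray], GroundTruth]:
    """GCaMP-like movie with stimulus-locked transients in each ROI.

    Each primitive of ``roi_layout`` (nz must be 1) becomes one ROI whose
    true trace is baseline * (1 + drift t) * (1 + amplitude * kernel), the
    kernel summed over stimulus onsets.  ``noise_sd`` is the Gaussian noise
    SD as a fraction of the baseline.  Returns (movie, ROI masks, truth);
    the truth stores the noiseless true dF/F0 per ROI.
    """
    if frame_rate_hz <= 0:
        raise DomainError("frame rate must be positive")
    if amplitude < 0:
        raise DomainError("amplitude must be nonnegative")
    if np.any(stim.onsets_s + stim.durations_s > duration_s) or np.any(stim.onsets_s < 0):
        raise ConfigError("stimulus outside the movie duration")
    nz, ny, nx = roi_layout.grid
    if nz != 1:
        raise InputError("calcium movies use a single-plane ROI layout")
    n_frames = int(round(duration_s * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    kernel_sum = np.zeros(n_frames)
    for onset in stim.onsets_s:
        kernel_sum += transient_kernel(t - onset, rise_s, decay_s)
    true_dff = amplitude * kernel_sum
    trend = baseline * (1.0 + drift_per_s * t)

    masks = []
    for s in roi_layout.structures:
        single = ScenePhantom(
            roi_layout.grid, roi_layout.pixel_size_um, roi_layout.z_step_um, [s]
        )
        masks.append(rasterize_phantom(single)[0] > 0)
    if not masks:
        raise InputError("ROI layout has no structures")

    rng = np.random.default_rng(seed)
    movie = np.zeros((n_frames, ny, nx))
    modulation = trend[:, None, None] * (1.0 + true_dff)[:, None, None]
    for m, s in zip(masks, roi_layout.structures):
        movie += m[None] * s.weight * modulation
    if noise_sd > 0:
        movie = movie + rng.normal(0.0, noise_sd * baseline, movie.shape)
    stack = ImageStack(movie, frame_rate_hz=frame_rate_hz, pixel_size_um=roi_layout.pixel_size_um)
    truth = GroundTruth(
        {
            "true_dff": [true_dff.copy() for _ in masks],
            "amplitude": amplitude,
            "times_s": t,
            "stim_mask": stim.mask(t),
            "baseline": baseline,
            "masks": masks,
        }
    )
    return stack, masks, truth


# --------------------------------------------------------------------------- #
# PMT streams
# --------------------------------------------------------------------------- #

def make_pmt_stream(
    scene_2p: np.ndarray,
    scene_3p: np.ndarray,
    params_3p: AcquisitionParams,
    sample_rate_hz: float,
    pixel_dwell_s: float,
    gate_width_s: float = 1e-6,
    detector_bandwidth_hz: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PMTStream, GroundTruth]:
    """Interleaved 2P/3P PMT record for two scenes scanned row-major.

    3P photon bursts land at the pulse times (period = 1/rep rate) with
    amplitude given by the current pixel of the 3P scene; the 2P scene
    contributes continuously while the EOM gate (1 us, centered between
    pulses) is high.  An optional single-pole low-pass at the detector
    bandwidth shapes both before sampling.
    """
    s2 = np.asarray(scene_2p, dtype=float)
    s3 = np.asarray(scene_3p, dtype=float)
    if s2.shape != s3.shape or s2.ndim != 2:
        raise InputError("scenes must be equal-shape 2D arrays")
    rep = params_3p.rep_rate_hz
    period = 1.0 / rep
    if sample_rate_hz < 4.0 * rep:
        raise ConfigError("sample rate must be at least 4x the pulse rate")
    if gate_width_s >= period:
        raise ConfigError("gate width must be shorter than the pulse period")
    ny, nx = s2.shape
    n_px = ny * nx
    n_samples = int(round(n_px * pixel_dwell_s * sample_rate_hz))
    gate, pulse_times = build_gate(rep, sample_rate_hz, n_samples, gate_width_s)
    t = np.arange(n_samples) / sample_rate_hz
    px = np.clip(np.floor(t / pixel_dwell_s + 1e-12).astype(int), 0, n_px - 1)

    samples = np.zeros(n_samples)
    samples[gate] += s2.ravel()[px[gate]]
    pulse_idx = np.clip(np.round(pulse_times * sample_rate_hz).astype(int), 0, n_samples - 1)
    np.add.at(samples, pulse_idx, s3.ravel()[px[pulse_idx]])

    if detector_bandwidth_hz is not None:
        tau = 1.0 / (2.0 * np.pi * detector_bandwidth_hz)
        alpha = 1.0 - np.exp(-1.0 / (sample_rate_hz * tau))
        from scipy.signal import lfilter

        samples = lfilter([alpha], [1.0, alpha - 1.0], samples)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, n_samples)

    stream = PMTStream(
        samples=samples,
        sample_rate_hz=sample_rate_hz,
        gate=gate,
        pulse_times_s=pulse_times,
        pixel_dwell_s=pixel_dwell_s,
        pixels_per_line=nx,
        lines_per_frame=ny,
        detector_bandwidth_hz=detector_bandwidth_hz,
    )
    truth = GroundTruth({"scene_2p": s2, "scene_3p": s3, "gate": gate})
    return stream, truth


# --------------------------------------------------------------------------- #
# behavior logs
# --------------------------------------------------------------------------- #

def make_behavior_log(
    duration_s: float,
    odor: StimulusTimeline | None = None,
    frame_rate_hz: float = 8.0,
    baseline_forward_mm_s: float = 2.0,
    baseline_rot_rad_s: float = 1.0,
    post_odor_gain: float = 1.0,
    post_window_s: float = 5.0,
    ball_radius_mm: float = 5.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[BehaviorTrace, GroundTruth]:
    """Treadmill delta-rotation log with odor-evoked speed gain.

    Expected forward/rotational speed magnitudes equal the baseline values
    outside the post-odor windows and gain-multiplied values within
    ``post_window_s`` after each odor offset (emulating the post-odor
    increase in walking speed and turning).  ``noise_sd`` is the fractional
    SD of the per-frame rotation magnitudes.
    """
    if duration_s <= 0:
        raise DomainError("duration must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) * dt
    gain = np.ones(n)
    if odor is not None and post_odor_gain != 1.0:
        for onset, dur in zip(odor.onsets_s, odor.durations_s):
            end = onset + dur
            gain[(t >= end) & (t < end + post_window_s)] = post_odor_gain
    sf_true = baseline_forward_mm_s * gain
    sr_true = baseline_rot_rad_s * gain
    pitch_mean = sf_true * dt / ball_radius_mm
    yaw_mean = sr_true * dt
    pitch = pitch_mean * (1.0 + noise_sd * rng.standard_normal(n)) if noise_sd > 0 else pitch_mean.copy()
    yaw_mag = yaw_mean * (1.0 + noise_sd * rng.standard_normal(n)) if noise_sd > 0 else yaw_mean.copy()
    yaw = yaw_mag * rng.choice([-1.0, 1.0], size=n)
    roll = (
        noise_sd * 0.01 * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    )
    trace = BehaviorTrace(
        times_s=t,
        deltas_rad=np.column_stack([roll, pitch, yaw]),
        ball_radius_mm=ball_radius_mm,
        frame_rate_hz=frame_rate_hz,
    )
    truth = GroundTruth(
        {
            "forward_mm_s": sf_true,
            "rotational_rad_s": sr_true,
            "gain": gain,
            "times_s": t,
        }
    )
    return trace, truth


# --------------------------------------------------------------------------- #
# jitter movies
# --------------------------------------------------------------------------- #

def make_jitter_movie(
    spot_sigma_um: float,
    n_frames: int,
    displacement_scale_um: float,
    pixel_size_um: float,
    field_px: tuple[int, int] = (384, 384),
    displacement_model: str = "rayleigh",
    amplitude: float = 1000.0,
    shot_noise: bool = False,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Movie of one bright Gaussian spot undergoing frame-to-frame jitter.

    Per-frame displacement magnitudes are drawn from the named model
    ("rayleigh": Rayleigh(scale); "fixed": constant = scale) with uniform
    random direction; the position random-walks and is reflected at a
    safety margin inside the field.  GroundTruth records the realized
    displacement magnitudes (after any reflection) and their mean.
    """
    if n_frames < 2:
        raise InputError("need at least 2 frames")
    if displacement_scale_um < 0:
        raise DomainError("displacement scale must be nonnegative")
    rng = np.random.default_rng(seed)
    ny, nx = field_px
    margin = 6.0 * spot_sigma_um
    lo_y, hi_y = margin, (ny - 1) * pixel_size_um - margin
    lo_x, hi_x = margin, (nx - 1) * pixel_size_um - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise InputError("field too small for the spot")
    pos = np.zeros((n_frames, 2))
    pos[0] = ((lo_y + hi_y) / 2.0, (lo_x + hi_x) / 2.0)

    def reflect(v, lo, hi):
        span = hi - lo
        v = np.mod(v - lo, 2 * span)
        return lo + np.where(v > span, 2 * span - v, v)

    for i in range(1, n_frames):
        if displacement_model == "rayleigh":
            mag = rng.rayleigh(displacement_scale_um) if displacement_scale_um > 0 else 0.0
        elif displacement_model == "fixed":
            mag = displacement_scale_um
        else:
            raise ConfigError(f"unknown displacement model {displacement_model!r}")
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cand = pos[i - 1] + mag * np.array([np.sin(theta), np.cos(theta)])
        pos[i] = (reflect(cand[0], lo_y, hi_y), reflect(cand[1], lo_x, hi_x))

    sig_px = spot_sigma_um / pixel_size_um
    half = int(np.ceil(6.0 * sig_px))
    data = np.zeros((n_frames, ny, nx))
    for i, (py, px_um) in enumerate(pos):
        r, c = py / pixel_size_um, px_um / pixel_size_um
        r0, c0 = int(np.floor(r)) - half, int(np.floor(c)) - half
        r0, c0 = max(r0, 0), max(c0, 0)
        r1 = min(int(np.floor(r)) + half + 2, ny)
        c1 = min(int(np.floor(c)) + half + 2, nx)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        data[i, r0:r1, c0:c1] = amplitude * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sig_px**2)
        )
    if shot_noise:
        data = rng.poisson(data).astype(float)
    disp = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    stack = ImageStack(data, pixel_size_um=pixel_size_um, frame_rate_hz=6.5)
    truth = GroundTruth(
        {
            "positions_um": pos,
            "displacements_um": disp,
            "mean_displacement_um": float(disp.mean()),
        }
    )
    return stack, truth


# --------------------------------------------------------------------------- #
# transmission samples
# --------------------------------------------------------------------------- #

def make_transmission_samples(
    true_field: np.ndarray,
    n_points: int,
    noise_sd: float = 0.0,
    spacing_um: float = 100.0,
    p_t0_mw: float = 10.0,
    wavelength_nm: float = 1300.0,
    mode: str = "ballistic",
    seed: int = 0,
) -> list[TransmissionMeasurement]:
    """Located (P_T, P_T0) pairs whose ratio scatters around the local value
    of a 2D transmission-fraction field (values in [0, 1])."""
    field = np.asarray(true_field, dtype=float)
    if np.any(field < 0) or np.any(field > 1):
        raise DomainError("transmission field values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ny, nx = field.shape
    out: list[TransmissionMeasurement] = []
    for _ in range(n_points):
        iy = int(rng.integers(ny))
        ix = int(rng.integers(nx))
        ratio = field[iy, ix]
        if noise_sd > 0:
            ratio = ratio * (1.0 + noise_sd * rng.standard_normal())
        out.append(
            TransmissionMeasurement(
                wavelength_nm=wavelength_nm,
                mode=mode,
                p_t_mw=max(ratio, 0.0) * p_t0_mw,
                p_t0_mw=p_t0_mw,
                location_um=(ix * spacing_um, iy * spacing_um),
            )
        )
    return out
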