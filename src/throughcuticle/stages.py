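"""Stage registry: every pipeline step behind one dispatch function.

``run_stage`` takes a :class:`~throughcuticle.io.RunConfig`, dispatches to
the registered stage, writes the stage's file products under the output
directory and returns a :class:`~throughcuticle.io.ResultRecord` whose
provenance echoes the config hash, seed and input hashes.  Identical config
and seed give identical records.  The CLI subcommands are thin wrappers
around this module.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import attenuation, behavior, demux, resolution, synthetic, traces
from . import transmission as tx
from .core import (
    AcquisitionParams,
    AttenuationProfile,
    ConfigError,
    ImageStack,
    InputError,
    PMTStream,
    PowerSchedule,
    PSFModel,
    ScenePhantom,
    Slab,
    Sphere,
    StimulusTimeline,
)
from .io import (
    ResultRecord,
    RunConfig,
    hash_file,
    read_power_schedule,
    read_rotation_log,
    read_stack,
    write_power_schedule,
    write_rotation_log,
    write_stack,
)

log = logging.getLogger("throughcuticle")

_REGISTRY: dict = {}


def register(name):
    def deco(fn):
        _REGISTRY[name] = fn
        return fn

    return deco


def available_stages() -> list[str]:
    return sorted(_REGISTRY)


def run_stage(config: RunConfig) -> ResultRecord:
    """Dispatch a configured stage and attach provenance."""
    if config.stage not in _REGISTRY:
        raise ConfigError(
            f"unknown stage {config.stage!r}; available: {available_stages()}"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info(
        "stage=%s config_hash=%s seed=%d", config.stage, config.config_hash(), config.seed
    )
    values = _REGISTRY[config.stage](config, outdir)
    record = ResultRecord(
        stage=config.stage,
        values=values,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "parameters": config.parameters,
            "inputs": {
                str(p): hash_file(p) for p in config.inputs if Path(str(p)).exists()
            },
        },
    )
    record.to_json(outdir / f"{config.stage}_result.json")
    return record


# --------------------------------------------------------------------------- #
# simulate
# --------------------------------------------------------------------------- #

@register("simulate")
def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    p = config.parameters
    kind = p.get("kind", "phantom_stack")
    seed = config.seed
    if kind == "phantom_stack":
        nz = int(p.get("n_planes", 21))
        ny, nx = int(p.get("ny", 64)), int(p.get("nx", 64))
        z_step = float(p.get("z_step_um", 5.0))
        layers = [tuple(l) for l in p.get("layers_um", [[0.0, nz * z_step, 60.0]])]
        order = int(p.get("order", 3))
        phantom = ScenePhantom(
            (nz, ny, nx),
            float(p.get("pixel_size_um", 0.5)),
            z_step,
            [Slab(0.0, (nz - 1) * z_step)],
        )
        atten = AttenuationProfile(layers, order)
        psf = PSFModel(
            float(p.get("lateral_sigma_um", 0.5)),
            float(p.get("axial_hw_um", 1.0)),
            order,
        )
        depths = np.array([0.0, (nz - 1) * z_step])
        schedule = PowerSchedule(depths, np.full(2, float(p.get("power_mw", 10.0))))
        params = AcquisitionParams(1320.0 if order == 3 else 920.0, order, 400e3)
        stack, truth = synthetic.make_phantom_stack(
            phantom,
            params,
            atten,
            psf,
            schedule,
            float(p.get("photon_budget", 1000.0)),
            seed,
            shot_noise=bool(p.get("shot_noise", True)),
        )
        stack_path = write_stack(stack, outdir / "stack.tif")
        sched_path = write_power_schedule(schedule, outdir / "schedule.csv")
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "layers_um": layers,
                    "order": order,
                    "depth_factor": truth["depth_factor"].tolist(),
                },
                indent=2,
            )
        )
        return {"stack": str(stack_path), "schedule": str(sched_path), "order": order}
    if kind == "jitter_movie":
        stack, truth = synthetic.make_jitter_movie(
            float(p.get("spot_sigma_um", 1.0)),
            int(p.get("n_frames", 500)),
            float(p.get("scale_um", 1.0373)),
            float(p.get("pixel_size_um", 0.25)),
            seed=seed,
        )
        path = write_stack(stack, outdir / "jitter.tif")
        return {
            "movie": str(path),
            "true_mean_displacement_um": truth["mean_displacement_um"],
        }
    if kind == "behavior_log":
        stim = StimulusTimeline(
            np.atleast_1d(p.get("odor_onset_s", 20.0)),
            np.atleast_1d(p.get("odor_duration_s", 3.0)),
        )
        trace, truth = synthetic.make_behavior_log(
            float(p.get("duration_s", 60.0)),
            odor=stim,
            post_odor_gain=float(p.get("post_odor_gain", 2.0)),
            seed=seed,
        )
        path = write_rotation_log(trace, outdir / "rotation_log.dat")
        return {"log": str(path)}
    if kind == "calcium_movie":
        ny, nx = int(p.get("ny", 32)), int(p.get("nx", 32))
        layout = ScenePhantom(
            (1, ny, nx),
            1.0,
            1.0,
            [Sphere((0.0, ny / 2.0, nx / 2.0), float(p.get("roi_radius_um", 6.0)))],
        )
        stim = StimulusTimeline(
            np.atleast_1d(p.get("odor_onset_s", 3.0)),
            np.atleast_1d(p.get("odor_duration_s", 3.0)),
        )
        movie, masks, truth = synthetic.make_calcium_movie(
            layout,
            stim,
            amplitude=float(p.get("amplitude", 0.5)),
            duration_s=float(p.get("duration_s", 10.0)),
            frame_rate_hz=float(p.get("frame_rate_hz", 17.0)),
            noise_sd=float(p.get("noise_sd", 0.0)),
            seed=seed,
        )
        mpath = write_stack(movie, outdir / "calcium.tif")
        roi_img = np.zeros((ny, nx), dtype=np.uint16)
        for i, m in enumerate(masks, start=1):
            roi_img[m] = i
        rpath = write_stack(ImageStack(roi_img[None]), outdir / "rois.tif")
        pd.DataFrame(
            {"onset_s": stim.onsets_s, "duration_s": stim.durations_s, "label": stim.label}
        ).to_csv(outdir / "stimulus.csv", index=False)
        return {"movie": str(mpath), "rois": str(rpath), "stimulus": str(outdir / "stimulus.csv")}
    if kind == "pmt_stream":
        ny, nx = int(p.get("ny", 8)), int(p.get("nx", 8))
        rng = np.random.default_rng(seed)
        s2 = rng.uniform(0.2, 1.0, (ny, nx))
        s3 = rng.uniform(0.2, 1.0, (ny, nx))
        params3p = AcquisitionParams(1320.0, 3, float(p.get("rep_rate_hz", 400e3)))
        stream, truth = synthetic.make_pmt_stream(
            s2,
            s3,
            params3p,
            sample_rate_hz=float(p.get("sample_rate_hz", 10e6)),
            pixel_dwell_s=float(p.get("pixel_dwell_s", 10e-6)),
            detector_bandwidth_hz=p.get("detector_bandwidth_hz", 1.9e6),
            seed=seed,
        )
        spath = outdir / "stream.csv"
        pd.DataFrame({"sample": stream.samples, "gate": stream.gate.astype(int)}).to_csv(
            spath, index=False
        )
        (outdir / "stream.json").write_text(
            json.dumps(
                {
                    "sample_rate_hz": stream.sample_rate_hz,
                    "rep_rate_hz": params3p.rep_rate_hz,
                    "pixel_dwell_s": stream.pixel_dwell_s,
                    "pixels_per_line": nx,
                    "lines_per_frame": ny,
                    "detector_bandwidth_hz": stream.detector_bandwidth_hz,
                },
                indent=2,
            )
        )
        return {"stream": str(spath), "sidecar": str(outdir / "stream.json")}
    if kind == "transmission_samples":
        field = np.full(
            (int(p.get("ny", 4)), int(p.get("nx", 4))), float(p.get("fraction", 0.9))
        )
        ms = synthetic.make_transmission_samples(
            field,
            int(p.get("n_points", 56)),
            noise_sd=float(p.get("noise_sd", 0.02)),
            seed=seed,
        )
        path = outdir / "transmission.csv"
        pd.DataFrame(
            {
                "wavelength_nm": [m.wavelength_nm for m in ms],
                "mode": [m.mode for m in ms],
                "p_t_mw": [m.p_t_mw for m in ms],
                "p_t0_mw": [m.p_t0_mw for m in ms],
                "x_um": [m.location_um[0] for m in ms],
                "y_um": [m.location_um[1] for m in ms],
            }
        ).to_csv(path, index=False)
        return {"samples": str(path)}
    raise ConfigError(f"unknown simulate kind {kind!r}")


# --------------------------------------------------------------------------- #
# analysis stages
# --------------------------------------------------------------------------- #

@register("transmission")
def _stage_transmission(config: RunConfig, outdir: Path) -> dict:
    if not config.inputs:
        raise ConfigError("transmission stage needs a measurement CSV input")
    df = pd.read_csv(config.inputs[0])
    ms = [
        tx.TransmissionMeasurement(
            wavelength_nm=row.wavelength_nm,
            mode=row.mode,
            p_t_mw=row.p_t_mw,
            p_t0_mw=row.p_t0_mw,
            location_um=(row.x_um, row.y_um) if "x_um" in df.columns else None,
        )
        for row in df.itertuples()
    ]
    summaries = {}
    for (wl, mode) in sorted({(m.wavelength_nm, m.mode) for m in ms}):
        group = [m for m in ms if m.wavelength_nm == wl and m.mode == mode]
        s = tx.summarize_wavelength(group)
        summaries[f"{mode}_{wl:g}nm"] = {
            "mean_fraction": s.mean_fraction,
            "sem": s.sem,
            "n": s.n,
            "flagged_above_one": s.flagged_above_one,
        }
    values: dict = {"summaries": summaries}
    spacing = config.parameters.get("grid_spacing_um")
    if spacing and all(m.location_um is not None for m in ms):
        grid = tx.transmission_map(ms, float(spacing))
        np.savetxt(outdir / "transmission_map.csv", grid, delimiter=",")
        values["map"] = str(outdir / "transmission_map.csv")
    return values


@register("eal")
def _stage_eal(config: RunConfig, outdir: Path) -> dict:
    if len(config.inputs) < 2:
        raise ConfigError("eal stage needs [stack.tif, schedule.csv] inputs")
    stack = read_stack(config.inputs[0])
    schedule = read_power_schedule(config.inputs[1])
    p = config.parameters
    order = int(p.get("order", 3))
    if stack.z_step_um is None:
        stack.z_step_um = float(p.get("z_step_um", 5.0))
    profile = attenuation.profile_from_stack(
        stack,
        schedule,
        order,
        fraction=float(p.get("top_fraction", attenuation.TOP_FRACTION_DEFAULT)),
        depth_offset_um=float(p.get("depth_offset_um", 0.0)),
    )
    pd.DataFrame(
        {
            "depth_um": profile.depths_um,
            "S": profile.signal,
            "P_mW": profile.power_mw,
            "S_norm": profile.normalized,
        }
    ).to_csv(outdir / "depth_profile.csv", index=False)
    windows = p.get("windows_um") or [
        [float(profile.depths_um[0]), float(profile.depths_um[-1])]
    ]
    fits = attenuation.piecewise_eal(profile, [tuple(w) for w in windows], order)
    return {
        "profile": str(outdir / "depth_profile.csv"),
        "fits": [
            {
                "window_um": list(f.window_um),
                "slope_per_um": f.slope_per_um,
                "eal_um": f.eal_um,
                "r_squared": f.r_squared,
                "n_points": f.n_points,
                "n_excluded": f.n_excluded,
            }
            for f in fits
        ],
    }


@register("resolution")
def _stage_resolution(config: RunConfig, outdir: Path) -> dict:
    if not config.inputs:
        raise ConfigError("resolution stage needs a stack input")
    stack = read_stack(config.inputs[0])
    p = config.parameters
    frame = stack.data[int(p.get("frame", 0))]
    profile = resolution.extract_line_profile(
        frame,
        tuple(p["p0"]),
        tuple(p["p1"]),
        pixel_size_um=float(p.get("pixel_size_um", stack.pixel_size_um or 1.0)),
        width_px=int(p.get("width_px", 1)),
        axis=p.get("axis", "lateral"),
    )
    pd.DataFrame(
        {"position_um": profile.positions_um, "intensity": profile.intensities}
    ).to_csv(outdir / "line_profile.csv", index=False)
    if profile.axis == "axial":
        fit = resolution.fit_axial_lorentzian_power(profile, int(p.get("order", 3)))
    else:
        fit = resolution.fit_lateral_gaussian(profile)
    return {
        "profile": str(outdir / "line_profile.csv"),
        "model": fit.model,
        "fwhm_um": fit.fwhm_um,
        "center_um": fit.center_um,
        "width_um": fit.width_um,
        "baseline": fit.baseline,
        "residual_rms": fit.residual_rms,
    }


@register("demux")
def _stage_demux(config: RunConfig, outdir: Path) -> dict:
    if len(config.inputs) < 2:
        raise ConfigError("demux stage needs [stream.csv|.bin, sidecar.json] inputs")
    stream_path, meta_path = Path(config.inputs[0]), Path(config.inputs[1])
    meta = json.loads(meta_path.read_text())
    if stream_path.suffix == ".bin":  # little-endian float32 samples, gate in meta
        samples = np.fromfile(stream_path, dtype="<f4").astype(float)
        gate, pulses = demux.build_gate(
            meta["rep_rate_hz"], meta["sample_rate_hz"], samples.size,
            meta.get("gate_width_s", demux.GATE_WIDTH_DEFAULT_S),
        )
    else:
        df = pd.read_csv(stream_path)
        samples = df["sample"].to_numpy(float)
        gate = df["gate"].to_numpy(bool)
        _, pulses = demux.build_gate(
            meta["rep_rate_hz"], meta["sample_rate_hz"], samples.size,
            meta.get("gate_width_s", demux.GATE_WIDTH_DEFAULT_S),
        )
    stream = PMTStream(
        samples=samples,
        sample_rate_hz=meta["sample_rate_hz"],
        gate=gate,
        pulse_times_s=pulses,
        pixel_dwell_s=meta["pixel_dwell_s"],
        pixels_per_line=meta["pixels_per_line"],
        lines_per_frame=meta["lines_per_frame"],
        detector_bandwidth_hz=meta.get("detector_bandwidth_hz"),
    )
    result = demux.demultiplex(
        stream, guard_s=float(config.parameters.get("guard_s", demux.GUARD_DEFAULT_S))
    )
    p2 = write_stack(ImageStack(result.image_2p[None]), outdir / "image_2p.tif")
    p3 = write_stack(ImageStack(result.image_3p[None]), outdir / "image_3p.tif")
    return {
        "image_2p": str(p2),
        "image_3p": str(p3),
        "discarded_fraction": result.discarded_fraction,
    }


@register("dff")
def _stage_dff(config: RunConfig, outdir: Path) -> dict:
    if len(config.inputs) < 3:
        raise ConfigError("dff stage needs [movie.tif, rois.tif, stimulus.csv] inputs")
    movie = read_stack(config.inputs[0])
    rois = read_stack(config.inputs[1]).data[0]
    stim_df = pd.read_csv(config.inputs[2])
    stim = StimulusTimeline(
        stim_df["onset_s"].to_numpy(float), stim_df["duration_s"].to_numpy(float)
    )
    p = config.parameters
    if movie.frame_rate_hz is None:
        movie.frame_rate_hz = float(p.get("frame_rate_hz", 17.0))
    k = int(p.get("average_k", 1))
    if k > 1:
        movie = traces.average_frames(movie, k)
    radius = int(p.get("median_radius_px", 0))
    if radius > 0:
        movie = traces.median_filter_movie(movie, radius)
    labels = sorted(int(v) for v in np.unique(rois) if v > 0)
    if not labels:
        raise InputError("ROI label image has no labeled pixels")
    t = movie.times_s
    stim_mask = stim.mask(t)
    mode = p.get("baseline", "prestim")
    out = {"time_s": t}
    peaks = {}
    for lab in labels:
        tr = traces.roi_trace(movie, rois == lab, stim_mask=stim_mask)
        if mode == "rolling":
            f0 = traces.baseline_rolling(
                tr, float(p.get("rolling_window_s", traces.ROLLING_WINDOW_S_DEFAULT))
            )
        else:
            f0 = traces.baseline_prestim(
                tr,
                float(stim.onsets_s[0]),
                int(p.get("prestim_frames", traces.PRESTIM_FRAMES_DEFAULT)),
            )
        d = traces.dff(tr, f0)
        w = int(p.get("smooth_frames", 0))
        if w > 1:
            d = traces.smooth_moving_mean(d, w)
        out[f"dff_roi{lab}"] = d.values
        peaks[f"roi{lab}"] = traces.peak_dff(
            d, float(stim.onsets_s[0]), int(p.get("peak_horizon_frames", traces.PEAK_HORIZON_DEFAULT))
        )
    pd.DataFrame(out).to_csv(outdir / "dff_traces.csv", index=False)
    return {"traces": str(outdir / "dff_traces.csv"), "peak_dff": peaks}


@register("motion")
def _stage_motion(config: RunConfig, outdir: Path) -> dict:
    if not config.inputs:
        raise ConfigError("motion stage needs a movie input")
    movie = read_stack(config.inputs[0])
    p = config.parameters
    pixel_size = float(p.get("pixel_size_um", movie.pixel_size_um or 1.0))
    if "roi" in p:  # [row0, col0, row1, col1] window around one neuron
        r0, c0, r1, c1 = (int(v) for v in p["roi"])
        mask = np.zeros(movie.data.shape[1:], bool)
        mask[r0:r1, c0:c1] = True
    else:
        peak = np.unravel_index(np.argmax(movie.data[0]), movie.data.shape[1:])
        half = int(p.get("roi_half_px", 24))
        mask = np.zeros(movie.data.shape[1:], bool)
        mask[
            max(peak[0] - half, 0) : peak[0] + half + 1,
            max(peak[1] - half, 0) : peak[1] + half + 1,
        ] = True
    disp, mean_disp, norm = traces.landmark_motion(movie, mask, pixel_size)
    pd.DataFrame(
        {"frame": np.arange(1, disp.size + 1), "displacement_um": disp}
    ).to_csv(outdir / "displacement.csv", index=False)
    return {
        "displacements": str(outdir / "displacement.csv"),
        "mean_displacement_um": mean_disp,
        "intensity_range": [float(norm.min()), float(norm.max())],
    }


@register("behavior")
def _stage_behavior(config: RunConfig, outdir: Path) -> dict:
    if not config.inputs:
        raise ConfigError("behavior stage needs a rotation log input")
    p = config.parameters
    trace = read_rotation_log(
        config.inputs[0],
        ball_radius_mm=float(p.get("ball_radius_mm", 5.0)),
        frame_rate_hz=float(p.get("frame_rate_hz", 8.0)),
        column_map=p.get("column_map"),
    )
    speeds = behavior.speeds_from_deltas(trace)
    down = behavior.interpolate_gaps(
        behavior.downsample_windows(speeds, float(p.get("to_rate_hz", 5.0)))
    )
    pd.DataFrame(
        {
            "time_s": down.times_s,
            "forward_mm_s": down.forward_mm_s,
            "rotational_rad_s": down.rotational_rad_s,
        }
    ).to_csv(outdir / "speeds.csv", index=False)
    path = behavior.fictive_path(trace)
    pd.DataFrame({"x_mm": path[:, 0], "y_mm": path[:, 1]}).to_csv(
        outdir / "fictive_path.csv", index=False
    )
    values: dict = {
        "speeds": str(outdir / "speeds.csv"),
        "path": str(outdir / "fictive_path.csv"),
    }
    if "odor_onset_s" in p:
        for name, v in (("forward", down.forward_mm_s), ("rotational", down.rotational_rad_s)):
            s = behavior.prepost_summary(
                down.times_s,
                v,
                float(p["odor_onset_s"]),
                window_s=float(p.get("window_s", 5.0)),
                stimulus_duration_s=float(p.get("odor_duration_s", 0.0)),
            )
            values[f"{name}_prepost"] = {
                "mean_before": s.mean_before,
                "mean_after": s.mean_after,
                "difference": s.difference,
            }
    return values
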