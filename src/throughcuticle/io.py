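"""Readers and writers for the pipeline's external formats.

* Multi-page grayscale TIFF for stacks and movies (uint16 by default;
  float stacks allowed for simulator ground truth), with an optional YAML
  sidecar (``<stack>.tif.yaml``) carrying spacing metadata.
* CSV for power schedules (``depth_um, power_mw``), traces and stimulus
  timelines.
* FicTrac-style delimited logs for rotation data; the column map is
  configurable since log layouts vary between versions.
* JSON for :class:`ResultRecord`, YAML for run configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    BehaviorTrace,
    FormatError,
    ImageStack,
    InputError,
    PowerSchedule,
)

# 0-based indices into the standard FicTrac .dat column layout: the frame
# counter and the lab-frame delta-rotation vector (columns 6-8, 1-based).
FICTRAC_COLUMNS = {"frame": 0, "roll": 5, "pitch": 6, "yaw": 7}


# --------------------------------------------------------------------------- #
# TIFF stacks
# --------------------------------------------------------------------------- #

def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".yaml")


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`, page order
    preserved.  Spacing comes from the YAML sidecar when present, else is
    left unknown (None)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if isinstance(data, np.ndarray) and data.dtype == object:
        raise FormatError("ragged page sizes in TIFF")
    if data.ndim not in (2, 3):
        raise FormatError(f"expected grayscale pages, got shape {data.shape}")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    return ImageStack(
        data,
        z_step_um=meta.get("z_step_um"),
        frame_rate_hz=meta.get("frame_rate_hz"),
        pixel_size_um=meta.get("pixel_size_um"),
        channel=meta.get("channel", "fluorescence"),
    )


def write_stack(stack: ImageStack, path) -> Path:
    """Write a multi-page TIFF (lossless round-trip for integer data) and a
    YAML sidecar with any known spacing metadata."""
    path = Path(path)
    if stack.data.size == 0:
        raise InputError("refusing to write an empty stack")
    try:
        tifffile.imwrite(path, stack.data, photometric="minisblack")
    except (OSError, PermissionError) as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
    meta = {
        k: v
        for k, v in {
            "z_step_um": stack.z_step_um,
            "frame_rate_hz": stack.frame_rate_hz,
            "pixel_size_um": stack.pixel_size_um,
            "channel": stack.channel,
        }.items()
        if v is not None
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


# --------------------------------------------------------------------------- #
# CSV formats
# --------------------------------------------------------------------------- #

def read_power_schedule(path) -> PowerSchedule:
    """CSV with columns ``depth_um, power_mw``; depths must be strictly
    ascending (duplicates rejected)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
        depths = pd.to_numeric(df["depth_um"], errors="raise").to_numpy(float)
        power = pd.to_numeric(df["power_mw"], errors="raise").to_numpy(float)
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"bad power schedule {path}: {exc}") from exc
    return PowerSchedule(depths, power)


def write_power_schedule(schedule: PowerSchedule, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"depth_um": schedule.depths_um, "power_mw": schedule.power_mw}
    ).to_csv(path, index=False)
    return path


def read_rotation_log(
    path,
    ball_radius_mm: float = 5.0,
    frame_rate_hz: float = 8.0,
    column_map: dict | None = None,
    delimiter: str | None = None,
) -> BehaviorTrace:
    """Read a FicTrac-style delimited log into a :class:`BehaviorTrace`.

    ``column_map`` gives 0-based column indices for ``frame`` and the three
    delta-rotation axes (default: the standard layout's columns 6-8).
    Frames are ordered by index; skipped indices are recorded in ``gaps``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    cmap = dict(FICTRAC_COLUMNS)
    if column_map:
        cmap.update(column_map)
    if len({cmap[a] for a in ("roll", "pitch", "yaw")}) < 3:
        raise FormatError("need 3 distinct rotation columns")
    try:
        df = pd.read_csv(path, header=None, sep=delimiter or r"[,\s]+", engine="python")
    except Exception as exc:
        raise FormatError(f"cannot parse rotation log {path}: {exc}") from exc
    needed = max(cmap.values())
    if df.shape[1] <= needed:
        raise FormatError(
            f"rotation log has {df.shape[1]} columns, need at least {needed + 1}"
        )
    try:
        frames = pd.to_numeric(df.iloc[:, cmap["frame"]], errors="raise").to_numpy(float)
        deltas = np.column_stack(
            [
                pd.to_numeric(df.iloc[:, cmap[a]], errors="raise").to_numpy(float)
                for a in ("roll", "pitch", "yaw")
            ]
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric value in rotation log: {exc}") from exc
    order = np.argsort(frames, kind="stable")
    frames, deltas = frames[order], deltas[order]
    idx = frames.astype(int)
    gaps = [int(g) for g in np.setdiff1d(np.arange(idx[0], idx[-1] + 1), idx)]
    times = (idx - idx[0]) / frame_rate_hz
    return BehaviorTrace(
        times_s=times,
        deltas_rad=deltas,
        ball_radius_mm=ball_radius_mm,
        frame_rate_hz=frame_rate_hz,
        gaps=gaps,
    )


def write_rotation_log(trace: BehaviorTrace, path, n_columns: int = 23) -> Path:
    """Write a minimal FicTrac-layout log (frame counter + delta rotations
    in the standard columns, zeros elsewhere)."""
    path = Path(path)
    n = len(trace)
    table = np.zeros((n, n_columns))
    table[:, FICTRAC_COLUMNS["frame"]] = np.arange(n)
    table[:, FICTRAC_COLUMNS["roll"]] = trace.roll
    table[:, FICTRAC_COLUMNS["pitch"]] = trace.pitch
    table[:, FICTRAC_COLUMNS["yaw"]] = trace.yaw
    pd.DataFrame(table).to_csv(path, index=False, header=False)
    return path


# --------------------------------------------------------------------------- #
# run configuration and result records
# --------------------------------------------------------------------------- #

@dataclass
class RunConfig:
    """One pipeline stage invocation: stage name, inputs, parameters, seed."""

    stage: str
    inputs: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise InputError("seed must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            stage=raw.get("stage", ""),
            inputs=raw.get("inputs", []),
            parameters=raw.get("parameters", {}),
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir", "."),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "stage": self.stage,
                "inputs": [str(p) for p in self.inputs],
                "parameters": self.parameters,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonify(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    if isinstance(value, dict):
        return {str(k): _jsonify(v) for k, v in value.items()}
    return value


@dataclass
class ResultRecord:
    """Serializable output of one stage: values plus provenance (input
    hashes and a config echo, seed included)."""

    stage: str
    values: dict
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        blob = json.dumps(
            {
                "stage": self.stage,
                "values": _jsonify(self.values),
                "provenance": _jsonify(self.provenance),
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(blob)
        return blob

    @classmethod
    def from_json(cls, text_or_path) -> "ResultRecord":
        p = Path(str(text_or_path))
        raw = json.loads(p.read_text() if p.exists() else str(text_or_path))
        return cls(stage=raw["stage"], values=raw["values"], provenance=raw.get("provenance", {}))


def hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
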