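"""File I/O: TIFF stacks with JSON sidecars, trace CSVs, fit tables, config.

Stacks round-trip losslessly (bit-exact for integer data); traces and fit
results are written at full float precision. YAML configs are validated
field by field so malformed input fails with the offending field named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, FormatError
from .fitting import FitResult
from .imaging import ImageStack
from .model import UptakeTrace

__all__ = [
    "write_stack", "read_stack", "write_traces", "read_traces",
    "write_fits", "read_fits", "read_config", "validate_config",
]

_TRACE_REQUIRED = ("cell_id", "t_s", "intensity_au")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: ImageStack,
                gain: float | None = None) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar (timestamps, calibration).

    With ``gain`` the frames are scaled and quantized to 16-bit; otherwise
    the in-memory dtype is preserved (bit-exact round-trip for integers).
    """
    path = Path(path)
    frames = stack.frames
    if gain is not None:
        frames = np.clip(frames * gain, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = {
        "pixel_size_um": stack.pixel_size,
        "timestamps_s": stack.timestamps.tolist(),
        "metadata": _jsonable(stack.metadata),
        "gain": gain,
    }
    if stack.illumination is not None:
        sidecar["illumination"] = {
            "duty_cycle": stack.illumination.duty_cycle,
            "k_dark": stack.illumination.k_dark,
            "k_laser": stack.illumination.k_laser,
            "frame_interval": stack.illumination.frame_interval,
            "duration": stack.illumination.duration,
        }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (TIFF + JSON sidecar)."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # malformed TIFF
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    for key in ("pixel_size_um", "timestamps_s"):
        if key not in sidecar:
            raise FormatError(f"sidecar {sidecar_file} lacks field {key!r}")
    illum = None
    if sidecar.get("illumination"):
        from .protocols import IlluminationProtocol
        illum = IlluminationProtocol(**sidecar["illumination"])
    return ImageStack(frames=frames, pixel_size=sidecar["pixel_size_um"],
                      timestamps=np.asarray(sidecar["timestamps_s"], dtype=float),
                      illumination=illum, metadata=sidecar.get("metadata", {}))


def write_traces(path: str | Path, traces: Sequence[UptakeTrace]) -> Path:
    """Write traces as tidy CSV: cell_id, t_s, intensity_au + condition columns."""
    path = Path(path)
    rows = []
    for trace in traces:
        condition = {k: v for k, v in trace.condition.items()
                     if np.isscalar(v) or isinstance(v, str)}
        for t, y in zip(trace.times, trace.intensities):
            rows.append({"cell_id": trace.cell_id, "t_s": t, "intensity_au": y,
                         **condition})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_traces(path: str | Path) -> list[UptakeTrace]:
    """Read a trace CSV written by :func:`write_traces`."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    for column in _TRACE_REQUIRED:
        if column not in frame.columns:
            raise FormatError(f"trace CSV {path} lacks column {column!r}")
    traces = []
    condition_cols = [c for c in frame.columns if c not in _TRACE_REQUIRED]
    for cell_id, group in frame.groupby("cell_id", sort=False):
        group = group.sort_values("t_s")
        condition = {c: group[c].iloc[0] for c in condition_cols}
        traces.append(UptakeTrace(times=group["t_s"].to_numpy(),
                                  intensities=group["intensity_au"].to_numpy(),
                                  cell_id=str(cell_id), condition=condition))
    return traces


def write_fits(path: str | Path, fits: Sequence[FitResult]) -> Path:
    """Write fit results as CSV (one row per trace); `.json` writes JSON."""
    path = Path(path)
    records = [f.to_dict() for f in fits]
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1))
    else:
        pd.DataFrame(records).to_csv(path, index=False, float_format="%.17g")
    return path


def read_fits(path: str | Path) -> list[FitResult]:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).replace({np.nan: None}).to_dict("records")
    try:
        return [FitResult(**r) for r in records]
    except TypeError as exc:
        raise FormatError(f"fit table {path} has wrong columns: {exc}") from exc


# ---------------------------------------------------------------------------
# Configuration

_CONFIG_FIELDS = {
    "condition": lambda v: v in ("usmb_fadu", "chem_fadu", "usmb_c6"),
    "concentration_uM": lambda v: np.isscalar(v) and float(v) > 0,
    "n_cells": lambda v: isinstance(v, int) and v >= 0,
    "snr": lambda v: v is None or float(v) > 0,
    "seed": lambda v: isinstance(v, int),
    "drift_um_per_s": lambda v: np.isscalar(v) or (isinstance(v, (list, tuple)) and len(v) == 2),
    "log_sd": lambda v: float(v) >= 0,
    "model": lambda v: v in ("decay", "2cm", "3cm"),
}


def validate_config(config: dict) -> dict:
    """Validate a simulation/fit config dict; raises ConfigError naming the field."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key, value in config.items():
        check = _CONFIG_FIELDS.get(key)
        if check is None:
            continue  # unknown keys are passed through untouched
        try:
            ok = check(value)
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ConfigError(f"invalid value for config field {key!r}: {value!r}")
    return config


def read_config(path: str | Path) -> dict:
    """Read and validate a YAML config file."""
    path = Path(path)
    try:
        config = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    return validate_config(config or {})
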