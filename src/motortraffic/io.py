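"""File formats: multi-page TIFF stacks, CSV schemas, JSON results.

All lengths are micrometres, times seconds and rates s^-1 on disk as in
memory; bulk concentrations cross the boundary in nM or motors/um^3 with an
explicit unit key.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .crowding_fit import SERIES_COLUMNS, validate_series
from .lattice_sim import (
    RUN_COLUMNS,
    SNAPSHOT_COLUMNS,
    KineticParams,
    LatticeConfig,
    TrajectorySet,
    nM_to_per_um3,
)
from .synthetic_imaging import ImageStack, KymographData, OpticsConfig

__all__ = [
    "SchemaError",
    "write_stack",
    "read_stack",
    "write_kymograph_csv",
    "read_kymograph_csv",
    "write_runs_csv",
    "read_runs_csv",
    "write_snapshots_csv",
    "write_series_csv",
    "read_series_csv",
    "write_json",
    "load_config",
    "load_s1_data",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """Raised when a file does not conform to its declared schema."""


# ---------------------------------------------------------------- TIFF stacks


def write_stack(path: PathLike, stack: ImageStack) -> None:
    """Write a stack as multi-page 16-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.uint16))
    meta = {
        "optics": dataclasses.asdict(stack.optics),
        "mt_axis": np.asarray(stack.mt_axis).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_stack(path: PathLike) -> ImageStack:
    """Read a multi-page TIFF stack; 8/32-bit input is converted with a warning."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype != np.uint16:
        warnings.warn(f"{path.name}: {frames.dtype} TIFF converted to 16-bit", stacklevel=2)
        frames = np.clip(frames, 0, 65535).astype(np.uint16)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        optics = OpticsConfig(**{**meta["optics"], "n_frames": frames.shape[0]})
        mt_axis = np.asarray(meta["mt_axis"], dtype=float)
    else:
        optics = OpticsConfig(n_frames=frames.shape[0])
        mt_axis = np.array(
            [[0.0, frames.shape[1] / 2.0], [frames.shape[2], frames.shape[1] / 2.0]]
        )
    return ImageStack(frames=frames, optics=optics, mt_axis=mt_axis)


# ----------------------------------------------------------------- kymographs


def write_kymograph_csv(path: PathLike, kymo: KymographData) -> None:
    """Kymograph I(x, t) as a CSV matrix (rows = positions, columns = frames)."""
    df = pd.DataFrame(kymo.intensity, index=kymo.x_um, columns=kymo.t_s)
    df.index.name = "x_um"
    df.to_csv(path)
    meta = {
        "pixel_size_um": kymo.pixel_size_um,
        "frame_interval_s": kymo.frame_interval_s,
        "background_subtracted": bool(kymo.background_subtracted),
        "background_mean": None
        if kymo.background_mean is None
        else kymo.background_mean.tolist(),
        "background_std": None
        if kymo.background_std is None
        else kymo.background_std.tolist(),
    }
    Path(path).with_suffix(".json").write_text(json.dumps(meta))


def read_kymograph_csv(path: PathLike) -> KymographData:
    df = pd.read_csv(path, index_col=0)
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    bg_mean = meta.get("background_mean")
    bg_std = meta.get("background_std")
    return KymographData(
        intensity=df.to_numpy(),
        x_um=df.index.to_numpy(dtype=float),
        t_s=df.columns.to_numpy(dtype=float),
        background_mean=None if bg_mean is None else np.asarray(bg_mean),
        background_std=None if bg_std is None else np.asarray(bg_std),
        pixel_size_um=meta.get("pixel_size_um", 0.08),
        frame_interval_s=meta.get("frame_interval_s", 0.2),
        background_subtracted=meta.get("background_subtracted", False),
    )


# ------------------------------------------------------------------ runs CSVs


def write_runs_csv(path: PathLike, trajectories: TrajectorySet) -> None:
    trajectories.runs[RUN_COLUMNS].to_csv(path, index=False)


def read_runs_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in RUN_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown runs columns: {unknown}")
    missing = [c for c in RUN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing runs columns: {missing}")
    if (df["unbind_time_s"] < 0).any() or (df["bind_time_s"] < 0).any():
        raise SchemaError("negative times in runs table")
    if (df["unbind_time_s"] < df["bind_time_s"]).any():
        raise SchemaError("unbind_time_s < bind_time_s in runs table")
    if (df["unbind_site"] < df["bind_site"]).any():
        raise SchemaError("unbind_site < bind_site in runs table (motion is unidirectional)")
    return df


def write_snapshots_csv(path: PathLike, trajectories: TrajectorySet) -> None:
    trajectories.snapshots[SNAPSHOT_COLUMNS].to_csv(path, index=False)


# ------------------------------------------------------------------- series


def write_series_csv(path: PathLike, series: pd.DataFrame) -> None:
    validate_series(series).to_csv(path, index=False)


def read_series_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in SERIES_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown series columns: {unknown}")
    try:
        return validate_series(df)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


# --------------------------------------------------------------- JSON / config


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_json(path: PathLike, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1))


def _concentration_from(cfg: dict) -> float:
    """Concentration in motors/um^3 from a value + unit config entry."""
    value = cfg.get("concentration", 0.0)
    if isinstance(value, dict):
        unit = value.get("unit", "per_um3")
        v = float(value["value"])
    else:
        unit = cfg.get("concentration_unit", "per_um3")
        v = float(value)
    if unit in ("nM", "nm"):
        return nM_to_per_um3(v)
    if unit in ("per_um3", "um-3", "motors_per_um3"):
        return v
    raise SchemaError(f"unknown concentration unit {unit!r}")


def load_config(path: PathLike) -> tuple[KineticParams, LatticeConfig]:
    """JSON config with keys mirroring the parameter dataclasses.

    Top-level keys ``params`` and ``lattice``; the lattice concentration may
    be ``{"value": 100, "unit": "nM"}`` or a bare number in motors/um^3.
    """
    raw = json.loads(Path(path).read_text())
    p_kwargs = raw.get("params", {})
    try:
        params = KineticParams(**p_kwargs)
    except TypeError as exc:
        raise SchemaError(f"bad params section: {exc}") from exc
    l_raw = dict(raw.get("lattice", {}))
    l_raw["concentration"] = _concentration_from(l_raw)
    l_raw.pop("concentration_unit", None)
    try:
        config = LatticeConfig(**l_raw)
    except TypeError as exc:
        raise SchemaError(f"bad lattice section: {exc}") from exc
    return params, config


def load_s1_data(path: PathLike) -> Optional[dict[str, pd.DataFrame]]:
    """Optionally load the published per-figure data workbook (XLSX).

    Returns a dict of sheet-name -> DataFrame, or None when the file is
    absent; used only for overlay plots, never required by analyses.
    """
    path = Path(path)
    if not path.exists():
        return None
    return pd.read_excel(path, sheet_name=None)
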