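"""File formats: TIFF stacks, tidy CSVs, YAML run configuration.

CSV outputs carry ``#``-prefixed header comments recording the package
version and a short hash of the run configuration, so any result file
can be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import AssaySimConfig, FlyTrajectory
from .tracking import ThresholdSpec, TubeGeometry

PathLike = Union[str, Path]


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    canon = yaml.safe_dump(dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def read_stack(path: PathLike) -> np.ndarray:
    """Read a grayscale frame stack.

    Accepts a multi-page TIFF (8- or 16-bit) or a directory of
    single-frame PNG images, taken in sorted filename order.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FileNotFoundError(f"no PNG frames found in {path}")
        frames = [np.asarray(iio.imread(p)) for p in files]
        stack = np.stack(frames)
    else:
        stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
    return stack


def write_stack(path: PathLike, stack: np.ndarray) -> None:
    """Write a frame stack as an 8-bit grayscale multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.dtype != np.uint8:
        raise ValueError("stacks are written as 8-bit grayscale; convert first")
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def write_trajectory_csv(path: PathLike, traj: FlyTrajectory, header: Optional[Mapping[str, Any]] = None) -> None:
    """Tidy per-fly trajectory table: time_s, fly_id, x_mm."""
    n, t = traj.positions.shape
    df = pd.DataFrame(
        {
            "time_s": np.repeat(traj.times, n),
            "fly_id": np.tile(np.arange(n), t),
            "x_mm": traj.positions.T.reshape(-1),
        }
    )
    write_csv(path, df, header or {})


def read_trajectory_csv(path: PathLike, tube_length_mm: float = 150.0) -> FlyTrajectory:
    df = pd.read_csv(path, comment="#")
    times = np.sort(df["time_s"].unique())
    wide = df.pivot(index="fly_id", columns="time_s", values="x_mm")
    return FlyTrajectory(positions=wide.to_numpy(), times=times, tube_length_mm=tube_length_mm)


def write_csv(path: PathLike, df: pd.DataFrame, header: Mapping[str, Any]) -> None:
    """Write a data frame with ``#`` header comments (incl. config hash)."""
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in header.items()]
    with path.open("w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trace(
    path: PathLike, stim_time: float, modality: str, units: str = ""
):
    """Read an evoked-response trace from CSV or two-column text.

    CSV files need ``time_s`` and ``signal`` columns; plain text files
    hold two whitespace-separated columns (time, signal).
    """
    from .evoked import Trace

    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#")
        times, signal = df["time_s"].to_numpy(), df["signal"].to_numpy()
    else:
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError(f"{path} must hold two columns (time, signal)")
        times, signal = data[:, 0], data[:, 1]
    return Trace(times=times, signal=signal, stim_time=stim_time, modality=modality, units=units)


def write_response_summary(path: PathLike, responses: Mapping[str, Any], header: Optional[Mapping[str, Any]] = None) -> None:
    """Summary CSV of peak responses keyed by trace id."""
    rows = [
        {
            "trace_id": trace_id,
            "modality": r.modality,
            "baseline": r.baseline_mean,
            "amplitude": r.amplitude,
            "excluded": r.excluded,
            "reason": r.reason or "",
        }
        for trace_id, r in responses.items()
    ]
    write_csv(path, pd.DataFrame(rows), header or {})


def load_run_config(path: PathLike) -> dict:
    with Path(path).open("r") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a YAML mapping")
    return cfg


def dump_run_config(path: PathLike, cfg: Mapping[str, Any]) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def sim_config_from_mapping(cfg: Mapping[str, Any]) -> AssaySimConfig:
    fields = {f for f in AssaySimConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in cfg.items() if k in fields}
    return AssaySimConfig(**kwargs)


def geometry_from_mapping(cfg: Mapping[str, Any]) -> TubeGeometry:
    return TubeGeometry(
        c0=int(cfg["c0"]), c1=int(cfg["c1"]), odorant_end=cfg.get("odorant_end", "low")
    )


def threshold_from_mapping(cfg: Mapping[str, Any]) -> ThresholdSpec:
    return ThresholdSpec(
        mode=cfg.get("mode", "fixed"),
        level=cfg.get("level"),
        polarity=cfg.get("polarity", "bright_flies"),
    )


def sim_config_to_mapping(config: AssaySimConfig) -> dict:
    return asdict(config)
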