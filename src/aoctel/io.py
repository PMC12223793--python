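"""Readers/writers for the on-disk scan formats.

Frame stacks are multi-page 16-bit grayscale TIFFs with a JSON sidecar
carrying the acquisition geometry and per-frame timestamps; pressure traces
and all tabular outputs are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import ScanGeometry

__all__ = [
    "read_stack",
    "read_pressure",
    "read_seed_depths",
    "write_boundary_csv",
    "write_csa_csv",
]


def read_stack(
    stack_path: str | Path, geometry_path: str | Path
) -> tuple[np.ndarray, ScanGeometry, np.ndarray]:
    """Load a TIFF frame stack plus its geometry/timestamp sidecar."""
    stack_path = Path(stack_path)
    if not stack_path.exists():
        raise FileNotFoundError(f"stack not found: {stack_path}")
    stack = tifffile.imread(stack_path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    payload = json.loads(Path(geometry_path).read_text())
    geom = ScanGeometry(**payload["geometry"])
    times = payload.get("frame_times_s")
    frame_times = (
        np.asarray(times, dtype=float) if times is not None else geom.frame_times()
    )
    if stack.shape[0] != geom.n_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames but geometry declares {geom.n_frames}"
        )
    return stack, geom, frame_times


def read_pressure(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a `time_s,pressure_cmH2O` CSV trace."""
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_cmH2O"):
        if col not in df.columns:
            raise ValueError(f"pressure CSV missing column {col!r}")
    return df["time_s"].to_numpy(float), df["pressure_cmH2O"].to_numpy(float)


def read_seed_depths(path: str | Path, geom: ScanGeometry) -> dict[int, np.ndarray]:
    """Read optional per-frame seed depths (`frame,column,depth_px` CSV)."""
    df = pd.read_csv(path)
    seeds: dict[int, np.ndarray] = {}
    for frame, grp in df.groupby("frame"):
        arr = np.full(geom.n_angles, np.nan)
        arr[grp["column"].to_numpy(int)] = grp["depth_px"].to_numpy(float)
        seeds[int(frame)] = arr
    return seeds


def write_boundary_csv(path: str | Path, boundary, geom: ScanGeometry) -> None:
    """Long-format boundary table: `frame,column,radius_mm,aliased`."""
    n_frames, n_angles = boundary.radius_px.shape
    frames = np.repeat(np.arange(n_frames), n_angles)
    cols = np.tile(np.arange(n_angles), n_frames)
    pd.DataFrame(
        {
            "frame": frames,
            "column": cols,
            "radius_mm": (boundary.radius_px * boundary.scale_mm_per_px).ravel(),
            "aliased": boundary.aliased.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def write_csa_csv(path: str | Path, csa_series) -> None:
    """Per-frame CSA table: `frame,time_s,csa_mm2`."""
    pd.DataFrame(
        {
            "frame": np.arange(len(csa_series.csa_mm2)),
            "time_s": csa_series.time_s,
            "csa_mm2": csa_series.csa_mm2,
        }
    ).to_csv(path, index=False)
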