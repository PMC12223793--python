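"""Acquisition geometry shared by the frame renderer and the segmenter."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["ScanGeometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """Constants of one rotational-catheter acquisition.

    Defaults follow the reference acquisition: 40 rotations/s, ~500 frames
    per scan, frames of 1152 depth pixels spanning 12.5 mm by 1248 angular
    columns (raw A-lines averaged in groups of 4), a 0.85 mm-OD catheter
    sheath, and a 5 kHz intraluminal pressure channel.
    """

    frame_rate: float = 40.0
    n_frames: int = 500
    depth_px: int = 1152
    range_mm: float = 12.5
    n_angles: int = 1248
    aline_group: int = 4
    sheath_od_mm: float = 0.85
    pressure_rate: float = 5000.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.range_mm <= 0:
            raise ValueError("range_mm must be > 0")
        for name in ("depth_px", "n_angles", "n_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.aline_group < 1:
            raise ValueError("aline_group must be >= 1")
        if self.sheath_od_mm <= 0:
            raise ValueError("sheath_od_mm must be > 0")
        if self.pressure_rate <= 0:
            raise ValueError("pressure_rate must be > 0")

    @property
    def mm_per_px(self) -> float:
        """Nominal depth sampling (mm per depth pixel)."""
        return self.range_mm / self.depth_px

    @property
    def duration_s(self) -> float:
        """Scan duration: number of frames over rotation rate."""
        return self.n_frames / self.frame_rate

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate

    def frame_times(self) -> np.ndarray:
        """Timestamps of rotation starts; frame f covers [t_f, t_f + 1/rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def angles(self) -> np.ndarray:
        """Column angles, uniform over [0, 2*pi), column 0 at angle 0."""
        return np.arange(self.n_angles) * (2.0 * np.pi / self.n_angles)

    def sheath_radius_px(self) -> float:
        """Nominal sheath outer radius in depth pixels."""
        return (self.sheath_od_mm / 2.0) / self.mm_per_px

    def to_json(self, path: str | Path, frame_times: np.ndarray | None = None) -> None:
        payload = {"geometry": asdict(self)}
        if frame_times is not None:
            payload["frame_times_s"] = [float(t) for t in frame_times]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanGeometry":
        payload = json.loads(Path(path).read_text())
        return cls(**payload["geometry"])
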