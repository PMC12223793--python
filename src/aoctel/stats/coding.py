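"""Covariate coding for study records.

Intensity, time and position labels are mapped to the numeric codes used by
the downstream ANOVA/regression models: intensity low/medium/high -> 1/2/3;
time before treatment -> -1, immediately after -> 0, 30 min -> 0.5, then hour
marks; position is a fraction in [0, 1] from the distal (carina) end at 0 to
the proximal (larynx) end at 1.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = ["encode_intensity", "encode_time", "encode_position", "encode"]

_INTENSITY = {"low": 1, "medium": 2, "high": 3}
_TIME_ALIASES = {
    "before": -1.0,
    "before treatment": -1.0,
    "pre": -1.0,
    "after": 0.0,
    "after treatment": 0.0,
    "after injury": 0.0,
    "post": 0.0,
    "30 min": 0.5,
    "30min": 0.5,
}
_HOURS_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*h(?:ours?)?\s*$", re.IGNORECASE)


def encode_intensity(label) -> int:
    if isinstance(label, str):
        key = label.strip().lower()
        if key in _INTENSITY:
            return _INTENSITY[key]
        raise ValueError(f"unknown intensity label: {label!r}")
    value = int(label)
    if value not in (1, 2, 3):
        raise ValueError(f"intensity code out of range: {label!r}")
    return value


def encode_time(label) -> float:
    if isinstance(label, str):
        key = label.strip().lower()
        if key in _TIME_ALIASES:
            return _TIME_ALIASES[key]
        m = _HOURS_RE.match(key)
        if m:
            return float(m.group(1))
        raise ValueError(f"unknown time label: {label!r}")
    return float(label)


def encode_position(value) -> float:
    pos = float(value)
    if not (0.0 <= pos <= 1.0):
        raise ValueError(f"position must be in [0, 1], got {value!r}")
    return pos


def encode(records: pd.DataFrame) -> pd.DataFrame:
    """Code a raw-label table into numeric study covariates.

    Expects columns ``intensity``, ``time_label`` (or ``time``) and
    ``position``; any other columns (``ncsc``, ``injury_grade``, ids) pass
    through unchanged. Unknown labels raise with the offending value.
    """
    df = records.copy()
    time_col = "time_label" if "time_label" in df.columns else "time"
    out = pd.DataFrame(index=df.index)
    out["intensity"] = df["intensity"].map(encode_intensity)
    out["time"] = df[time_col].map(encode_time)
    out["position"] = df["position"].map(encode_position)
    for col in df.columns:
        if col not in ("intensity", time_col, "position"):
            out[col] = df[col]
    return out
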