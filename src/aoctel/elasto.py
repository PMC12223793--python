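"""Compliance estimation from synchronized CSA and pressure series.

Pairs the high-rate pressure channel with frame windows, detects respiratory
cycles, extracts per-cycle extrema, and computes cross-sectional compliance
(CC = dCSA/dp) and its normalized form (nCsC = 100 * CC / mean CSA, in
percent area change per cmH2O) with uncertainty estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ScanRejectedError

__all__ = [
    "FramePressure",
    "CycleExtrema",
    "ComplianceResult",
    "frame_pressure_stats",
    "detect_cycles",
    "cycle_extrema",
    "compliance",
    "analyze_scan",
]


@dataclass
class FramePressure:
    """Mean and standard deviation of the pressure channel per frame window."""

    mean_cmH2O: np.ndarray
    sd_cmH2O: np.ndarray

    def __post_init__(self) -> None:
        if self.mean_cmH2O.shape != self.sd_cmH2O.shape:
            raise ValueError("mean/sd must have one entry per frame")
        if np.any(self.sd_cmH2O < 0):
            raise ValueError("sd must be non-negative")


@dataclass
class CycleExtrema:
    """Per-cycle CSA and pressure extrema (recorded independently)."""

    max_csa: np.ndarray
    min_csa: np.ndarray
    max_p: np.ndarray
    min_p: np.ndarray
    max_frame: np.ndarray  # frame index of the CSA maximum, per cycle
    min_frame: np.ndarray

    def __post_init__(self) -> None:
        if len(self.max_csa) < 2:
            raise ScanRejectedError("need at least 2 cycles of extrema")
        if np.any(self.max_csa < self.min_csa) or np.any(self.max_p < self.min_p):
            raise ValueError("per-cycle max must be >= min")

    @property
    def n_cycles(self) -> int:
        return len(self.max_csa)


@dataclass
class ComplianceResult:
    """Per-scan compliance summary (one row of the results table)."""

    csa_bar_mm2: float
    d_csa_mm2: float
    d_p_cmH2O: float
    cc_mm2_per_cmH2O: float
    ncsc_pct_per_cmH2O: float
    sd_min_csa: float
    sd_max_csa: float
    sd_csa_bar: float
    n_cycles: int

    def to_row(self, scan_id: str = "scan") -> dict:
        return {
            "scan_id": scan_id,
            "csa_bar_mm2": self.csa_bar_mm2,
            "d_csa_mm2": self.d_csa_mm2,
            "d_p_cmH2O": self.d_p_cmH2O,
            "cc": self.cc_mm2_per_cmH2O,
            "ncsc_pct_per_cmH2O": self.ncsc_pct_per_cmH2O,
            "sd_min_csa": self.sd_min_csa,
            "sd_max_csa": self.sd_max_csa,
            "sd_csa_bar": self.sd_csa_bar,
            "n_cycles": self.n_cycles,
        }


def frame_pressure_stats(
    pressure_time_s: np.ndarray,
    pressure_cmH2O: np.ndarray,
    frame_times_s: np.ndarray,
    frame_rate: float,
) -> FramePressure:
    """Mean/sd of the pressure samples inside each half-open frame window.

    Frame f covers ``[t_f, t_f + 1/frame_rate)``; a window containing zero
    samples is an error (pressure must cover the scan).
    """
    t = np.asarray(pressure_time_s, dtype=float)
    p = np.asarray(pressure_cmH2O, dtype=float)
    ft = np.asarray(frame_times_s, dtype=float)
    # successive frame starts bound the windows exactly; only the last window
    # end needs the frame period added
    bounds = np.concatenate([ft[1:], [ft[-1] + 1.0 / frame_rate]])
    starts = np.searchsorted(t, ft, side="left")
    ends = np.searchsorted(t, bounds, side="left")
    counts = ends - starts
    if np.any(counts <= 0):
        bad = int(np.argmax(counts <= 0))
        raise ValueError(f"frame {bad} has no pressure samples in its window")
    csum = np.concatenate([[0.0], np.cumsum(p)])
    csum2 = np.concatenate([[0.0], np.cumsum(p * p)])
    mean = (csum[ends] - csum[starts]) / counts
    var = (csum2[ends] - csum2[starts]) / counts - mean**2
    return FramePressure(mean_cmH2O=mean, sd_cmH2O=np.sqrt(np.maximum(var, 0.0)))


def detect_cycles(
    values: np.ndarray,
    times_s: np.ndarray,
    breaths_per_min: float = 20.0,
) -> list[tuple[int, int]]:
    """Respiratory cycle intervals from a periodic series (pressure or CSA).

    Cycle onsets are placed at the end of each expiratory minimum, detected
    as upward mid-level crossings with hysteresis (enter the low state below
    40% of the range, trigger above 55%) and a minimum onset separation of
    half the nominal period. Only complete cycles (between successive onsets)
    are returned; fewer than 2 is an error.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if v.size < 4:
        raise ScanRejectedError("series too short for cycle detection")
    lo_v, hi_v = float(v.min()), float(v.max())
    swing = hi_v - lo_v
    if swing <= 0:
        raise ScanRejectedError("insufficient cycles: series has no modulation")
    lo = lo_v + 0.40 * swing
    hi = lo_v + 0.55 * swing
    min_sep = 0.5 * (60.0 / breaths_per_min)
    onsets: list[int] = []
    armed = v[0] < lo
    for i in range(1, v.size):
        if not armed and v[i] < lo:
            armed = True
        elif armed and v[i] >= hi:
            if not onsets or (t[i] - t[onsets[-1]]) >= min_sep:
                onsets.append(i)
            armed = False
    if len(onsets) < 2:
        raise ScanRejectedError(
            f"insufficient cycles: {max(len(onsets) - 1, 0)} complete cycles detected"
        )
    return [(onsets[k], onsets[k + 1]) for k in range(len(onsets) - 1)]


def cycle_extrema(
    csa_mm2: np.ndarray,
    frame_pressure: FramePressure,
    cycles: list[tuple[int, int]],
    min_frames_per_cycle: int = 4,
) -> CycleExtrema:
    """Max/min CSA and frame-mean pressure over each cycle's frames.

    Extrema are taken independently per channel, which makes the result
    insensitive to sub-cycle lag between pressure and CSA. Cycles shorter
    than ``min_frames_per_cycle`` frames are dropped; fewer than 2 surviving
    cycles is an error.
    """
    csa = np.asarray(csa_mm2, dtype=float)
    p = frame_pressure.mean_cmH2O
    rows = []
    for s, e in cycles:
        if e - s < min_frames_per_cycle:
            continue
        seg_c = csa[s:e]
        seg_p = p[s:e]
        rows.append(
            (
                seg_c.max(),
                seg_c.min(),
                seg_p.max(),
                seg_p.min(),
                s + int(np.argmax(seg_c)),
                s + int(np.argmin(seg_c)),
            )
        )
    if len(rows) < 2:
        raise ScanRejectedError("fewer than 2 usable cycles after filtering")
    arr = np.array(rows, dtype=float)
    return CycleExtrema(
        max_csa=arr[:, 0],
        min_csa=arr[:, 1],
        max_p=arr[:, 2],
        min_p=arr[:, 3],
        max_frame=arr[:, 4].astype(int),
        min_frame=arr[:, 5].astype(int),
    )


def _extremum_sd(csa: np.ndarray, frames: np.ndarray, window: int) -> float:
    """CSA sd over the ``window`` frames before and after each extremum,
    averaged across cycles. Truncated (with a warning) at scan edges."""
    sds = []
    for f in frames:
        lo = f - window
        hi = f + window + 1
        if lo < 0 or hi > csa.size:
            warnings.warn(
                f"extremum frame {f} within {window} frames of the scan edge; "
                "uncertainty window truncated",
                stacklevel=3,
            )
            lo, hi = max(lo, 0), min(hi, csa.size)
        sds.append(np.std(csa[lo:hi], ddof=1))
    return float(np.mean(sds))


def compliance(
    extrema: CycleExtrema,
    csa_mm2: np.ndarray,
    sd_window_frames: int = 5,
    sd_rule: str = "rss",
) -> ComplianceResult:
    """Cross-sectional compliance and its normalized form from cycle extrema.

    dCSA and dp are averaged maxima minus averaged minima across cycles;
    the time-averaged CSA pools all per-cycle maxima and minima jointly.
    CC = dCSA/dp and nCsC = 100 * CC / CSA_bar (%/cmH2O). Uncertainties are
    the CSA sd over the ``sd_window_frames`` frames on each side of every
    extremum frame; the sd of the averaged CSA combines the max- and min-side
    terms by root-sum-of-squares (``sd_rule="rss"``, default) or by the plain
    sum of the two sds (``sd_rule="sum"``).
    """
    csa = np.asarray(csa_mm2, dtype=float)
    d_csa = float(extrema.max_csa.mean() - extrema.min_csa.mean())
    d_p = float(extrema.max_p.mean() - extrema.min_p.mean())
    if d_p <= 0:
        raise ScanRejectedError("no pressure modulation: dp <= 0")
    csa_bar = float(np.concatenate([extrema.max_csa, extrema.min_csa]).mean())
    cc = d_csa / d_p
    ncsc = 100.0 * cc / csa_bar
    sd_max = _extremum_sd(csa, extrema.max_frame, sd_window_frames)
    sd_min = _extremum_sd(csa, extrema.min_frame, sd_window_frames)
    if sd_rule == "rss":
        sd_bar = float(np.hypot(sd_max, sd_min))
    elif sd_rule == "sum":
        sd_bar = sd_max + sd_min
    else:
        raise ValueError(f"unknown sd_rule {sd_rule!r}; use 'rss' or 'sum'")
    return ComplianceResult(
        csa_bar_mm2=csa_bar,
        d_csa_mm2=d_csa,
        d_p_cmH2O=d_p,
        cc_mm2_per_cmH2O=cc,
        ncsc_pct_per_cmH2O=ncsc,
        sd_min_csa=sd_min,
        sd_max_csa=sd_max,
        sd_csa_bar=sd_bar,
        n_cycles=extrema.n_cycles,
    )


def analyze_scan(
    csa_mm2: np.ndarray,
    frame_times_s: np.ndarray,
    pressure_time_s: np.ndarray,
    pressure_cmH2O: np.ndarray,
    frame_rate: float,
    breaths_per_min: float = 20.0,
    sd_window_frames: int = 5,
    sd_rule: str = "rss",
) -> ComplianceResult:
    """Full per-scan compliance analysis from CSA and pressure series."""
    fp = frame_pressure_stats(pressure_time_s, pressure_cmH2O, frame_times_s, frame_rate)
    cycles = detect_cycles(fp.mean_cmH2O, frame_times_s, breaths_per_min)
    ext = cycle_extrema(csa_mm2, fp, cycles)
    return compliance(ext, csa_mm2, sd_window_frames=sd_window_frames, sd_rule=sd_rule)


def results_table(results: dict[str, ComplianceResult]) -> pd.DataFrame:
    """One-row-per-scan results table."""
    return pd.DataFrame([res.to_row(scan_id) for scan_id, res in results.items()])
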