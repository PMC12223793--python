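"""Synthetic airway / ventilator / rotational-OCT scan generator.

Provides ground truth for the downstream pipeline: a thick-walled linearly
elastic tube pressurised by a ventilator waveform, its lumen boundary sampled
per frame, and the boundary rendered into polar intensity frames with sheath
rings, speckle, depth-dependent sensitivity roll-off and fold-over aliasing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ScanRejectedError
from .geometry import ScanGeometry

__all__ = [
    "VentilatorParams",
    "TubeModel",
    "GroundTruth",
    "make_pressure",
    "analytic_ncsc",
    "simulate_boundary",
    "render_frames",
    "average_alines",
    "write_scan",
]

# Sensitivity roll-off anchor points (depth mm, sensitivity dB).
_SENS_NEAR = (1.0, 105.0)
_SENS_FAR = (8.5, 55.0)


@dataclass(frozen=True)
class VentilatorParams:
    """Pressure-controlled ventilator settings plus synthetic nuisance terms.

    ``attenuation`` scales the pressure modulation amplitude (proximal
    positions see a smaller swing); ``cardiac_amp`` is the fractional
    cross-sectional-area modulation at ``cardiac_hz``.
    """

    breaths_per_min: float = 20.0
    mip_cmH2O: float = 18.0
    peep_cmH2O: float = 5.0
    insp_fraction: float = 1.0 / 3.0
    attenuation: float = 1.0
    cardiac_amp: float = 0.0
    cardiac_hz: float = 1.5
    noise_sd_cmH2O: float = 1.32
    rise_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.breaths_per_min <= 0:
            raise ValueError("breaths_per_min must be > 0")
        if not (self.mip_cmH2O > self.peep_cmH2O >= 0):
            raise ValueError("require mip > peep >= 0")
        if not (0 < self.insp_fraction < 1):
            raise ValueError("insp_fraction must be in (0, 1)")
        if not (0 < self.attenuation <= 1):
            raise ValueError("attenuation must be in (0, 1]")
        if self.noise_sd_cmH2O < 0:
            raise ValueError("noise_sd_cmH2O must be >= 0")

    @property
    def period_s(self) -> float:
        return 60.0 / self.breaths_per_min


@dataclass(frozen=True)
class TubeModel:
    """Thick-walled, isotropic, linearly elastic tube (plane strain)."""

    inner_radius_mm: float
    outer_radius_mm: float
    youngs_modulus_cmH2O: float
    poisson: float = 0.45
    rest_pressure_cmH2O: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius_mm < self.outer_radius_mm):
            raise ValueError("require 0 < inner radius < outer radius")
        if self.youngs_modulus_cmH2O <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0 <= self.poisson < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")


@dataclass
class GroundTruth:
    """True boundary, area, pressure and compliance of a simulated scan."""

    boundary_mm: np.ndarray  # (n_frames, n_angles) radii from catheter axis
    csa_mm2: np.ndarray  # (n_frames,) true lumen area
    pressure_cmH2O: np.ndarray  # high-rate trace
    pressure_time_s: np.ndarray
    ncsc_true: float  # %/cmH2O
    catheter_offset_mm: tuple[float, float] = (0.0, 0.0)
    tube: TubeModel | None = None
    frame_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]


def _breath_waveform(phase: np.ndarray, vent: VentilatorParams) -> np.ndarray:
    """Smoothed-trapezoid breath cycle on phase in [0, 1).

    Cosine-smoothed rise over ``rise_fraction`` of the period, plateau until
    the end of inspiration, mirrored fall, then a baseline rest segment.
    Values are in [0, 1]; 0 = PEEP level, 1 = plateau level.
    """
    r = vent.rise_fraction
    insp_end = vent.insp_fraction
    fall_end = insp_end + r
    if fall_end >= 1.0:
        raise ValueError("insp_fraction + rise_fraction must be < 1")
    out = np.zeros_like(phase, dtype=float)
    rising = phase < r
    out[rising] = 0.5 * (1 - np.cos(np.pi * phase[rising] / r))
    plateau = (phase >= r) & (phase < insp_end)
    out[plateau] = 1.0
    falling = (phase >= insp_end) & (phase < fall_end)
    out[falling] = 0.5 * (1 + np.cos(np.pi * (phase[falling] - insp_end) / r))
    return out


def make_pressure(
    vent: VentilatorParams,
    geom: ScanGeometry,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the intraluminal pressure channel for one scan.

    Returns ``(time_s, pressure_cmH2O)`` sampled at ``geom.pressure_rate``
    over the scan duration. The noiseless waveform is periodic with period
    ``60 / breaths_per_min`` s, swings from PEEP to
    ``peep + attenuation * (mip - peep)``, and white Gaussian sensor noise of
    sd ``noise_sd_cmH2O`` is added on top.
    """
    duration = geom.duration_s
    if duration <= 0:
        raise ValueError("scan duration must be positive")
    n = int(round(duration * geom.pressure_rate))
    t = np.arange(n) / geom.pressure_rate
    phase = np.mod(t / vent.period_s, 1.0)
    swing = vent.attenuation * (vent.mip_cmH2O - vent.peep_cmH2O)
    p = vent.peep_cmH2O + swing * _breath_waveform(phase, vent)
    if vent.noise_sd_cmH2O > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, vent.noise_sd_cmH2O, size=n)
    return t, p


def analytic_ncsc(tube: TubeModel) -> float:
    """Normalised cross-sectional compliance of a thick-walled tube, %/cmH2O.

    Closed-form plane-strain solution for a cylinder with internal pressure
    and traction-free outer surface: the radial displacement is
    ``u(r) = A r + B / r`` and the inner-surface strain gives

        d(CSA)/CSA / dp = 2 (1 + nu) ((1 - 2 nu) a^2 + b^2) / (E (b^2 - a^2))

    which is dimensionless in (a, b) scale. Returned multiplied by 100 so the
    units are percent area change per cmH2O.
    """
    a = tube.inner_radius_mm
    b = tube.outer_radius_mm
    if b <= a:
        raise ValueError("outer radius must exceed inner radius")
    e = tube.youngs_modulus_cmH2O
    nu = tube.poisson
    frac = 2.0 * (1.0 + nu) * ((1.0 - 2.0 * nu) * a * a + b * b) / (e * (b * b - a * a))
    return 100.0 * frac


def _frame_mean_pressure(
    t_p: np.ndarray, p: np.ndarray, frame_times: np.ndarray, frame_period: float
) -> np.ndarray:
    """Mean pressure in each half-open frame window [t_f, t_f + period)."""
    starts = np.searchsorted(t_p, frame_times, side="left")
    ends = np.searchsorted(t_p, frame_times + frame_period, side="left")
    if np.any(ends <= starts):
        raise ValueError("frame window with zero pressure samples")
    csum = np.concatenate([[0.0], np.cumsum(p)])
    return (csum[ends] - csum[starts]) / (ends - starts)


def _offset_circle_radii(radius: float | np.ndarray, offset: tuple[float, float], angles: np.ndarray) -> np.ndarray:
    """Radii of a circle of radius R (centred at -offset from the axis) as
    seen from the catheter axis. ``radius`` may be scalar or per-frame."""
    d = float(np.hypot(*offset))
    if d == 0.0:
        radius = np.asarray(radius, dtype=float)
        return np.broadcast_to(radius[..., None], radius.shape + angles.shape).copy()
    phi = np.arctan2(offset[1], offset[0])
    radius = np.asarray(radius, dtype=float)[..., None]
    rel = angles[None, :] - phi
    under = radius**2 - (d * np.sin(rel)) ** 2
    if np.any(under <= 0):
        raise ScanRejectedError("catheter offset too large: boundary not star-shaped")
    return np.sqrt(under) + d * np.cos(rel)


def _polygon_area(radii: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Area of the closed polygon with polar vertices (r_j, theta_j).

    ``radii`` may be (n_angles,) or (n_frames, n_angles).
    """
    r_next = np.roll(radii, -1, axis=-1)
    dtheta = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
    return 0.5 * np.sum(radii * r_next * np.sin(dtheta), axis=-1)


def simulate_boundary(
    tube: TubeModel,
    pressure_time_s: np.ndarray,
    pressure_cmH2O: np.ndarray,
    geom: ScanGeometry,
    catheter_offset_mm: tuple[float, float] = (0.0, 0.0),
    cardiac_amp: float = 0.0,
    cardiac_hz: float = 1.5,
    lag_tau_s: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Quasi-static lumen boundary of the tube under the given pressure.

    Per frame, the inner radius responds linearly to the frame-mean
    transmural pressure:

        r(t) = a * (1 + 0.5 * ncsc/100 * (p_frame - p0))

    optionally multiplied by a cardiac modulation of fractional CSA amplitude
    ``cardiac_amp`` at ``cardiac_hz``, and expressed as radii from the
    (possibly offset) catheter axis. ``lag_tau_s > 0`` applies a first-order
    low-pass to the pressure drive (off by default).
    """
    ncsc = analytic_ncsc(tube)
    frame_times = geom.frame_times()
    p_frame = _frame_mean_pressure(pressure_time_s, pressure_cmH2O, frame_times, geom.frame_period_s)
    drive = p_frame - tube.rest_pressure_cmH2O
    if lag_tau_s > 0:
        alpha = 1.0 - np.exp(-geom.frame_period_s / lag_tau_s)
        filt = np.empty_like(drive)
        acc = drive[0]
        for i, x in enumerate(drive):
            acc += alpha * (x - acc)
            filt[i] = acc
        drive = filt
    a = tube.inner_radius_mm
    r_frames = a * (1.0 + 0.5 * (ncsc / 100.0) * drive)
    if cardiac_amp != 0.0:
        r_frames = r_frames * (1.0 + 0.5 * cardiac_amp * np.sin(2 * np.pi * cardiac_hz * frame_times))
    d = float(np.hypot(*catheter_offset_mm))
    if d >= np.min(r_frames):
        raise ScanRejectedError(
            "catheter offset >= minimum lumen radius: catheter would contact the wall"
        )
    angles = geom.angles()
    boundary = _offset_circle_radii(r_frames, catheter_offset_mm, angles)
    csa = _polygon_area(boundary, angles)
    return GroundTruth(
        boundary_mm=boundary,
        csa_mm2=csa,
        pressure_cmH2O=pressure_cmH2O,
        pressure_time_s=pressure_time_s,
        ncsc_true=ncsc,
        catheter_offset_mm=tuple(catheter_offset_mm),
        tube=tube,
        frame_times_s=frame_times,
    )


def sensitivity_db(depth_mm: np.ndarray | float) -> np.ndarray:
    """Log-linear sensitivity roll-off through (1 mm, 105 dB), (8.5 mm, 55 dB).

    Extrapolated linearly (in dB vs depth) beyond the anchor points.
    """
    (d0, s0), (d1, s1) = _SENS_NEAR, _SENS_FAR
    return s0 + (s1 - s0) * (np.asarray(depth_mm, dtype=float) - d0) / (d1 - d0)


def render_frames(
    gt: GroundTruth,
    geom: ScanGeometry,
    speckle: bool = True,
    tissue_thickness_mm: float = 2.0,
    noise_floor_db: float = 8.0,
    noise_db_spread: float = 2.5,
    scale_factor: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the ground-truth boundary into polar intensity frames.

    Returns ``(stack, frame_times_s)`` where ``stack`` is uint16 of shape
    ``(n_frames, depth_px, n_angles)``. Each frame holds two bright sheath
    rings near the axis, a tissue band starting at the boundary radius with
    (optional) multiplicative exponential-intensity speckle, the sensitivity
    roll-off applied at the *true* optical depth, and fold-over aliasing:
    structure at true depth z > range appears at the mirrored depth
    ``2*range - z``. ``scale_factor`` mimics a reference-arm mismatch by
    rendering everything ``scale_factor`` times larger in pixels.

    Pixel values are a log-scaled (dB-like) mapping of intensity, as in a
    standard displayed B-scan.
    """
    n_frames, n_ang = gt.boundary_mm.shape
    if n_frames != geom.n_frames or n_ang != geom.n_angles:
        raise ValueError("ground truth shape inconsistent with geometry")
    rng = np.random.default_rng(seed)
    mm_per_px = geom.mm_per_px / scale_factor
    rmax = geom.depth_px * mm_per_px  # physical depth spanned by the frame
    if np.any(gt.boundary_mm > 2.0 * rmax - geom.sheath_od_mm / 2.0):
        raise ValueError("boundary beyond 2*range - sheath radius cannot be rendered")

    depth = (np.arange(geom.depth_px) + 0.5) * mm_per_px  # pixel-centre depths
    folded = 2.0 * rmax - depth  # true depth mapping onto each pixel via fold

    # Sheath: two thin bright rings, the outer one ending at the sheath OD.
    # Ring edges fall off over symmetric 2-px ramps from peak to the noise
    # floor, so a half-maximum crossing sits exactly on the geometric edge
    # and the segmenter can localize it to sub-pixel precision.
    r_sheath = geom.sheath_od_mm / 2.0
    ring_w = max(0.08, 4.0 * mm_per_px)

    def _ring(outer_mm: float) -> np.ndarray:
        ramp_out = np.clip((outer_mm - depth) / (2.0 * mm_per_px) + 0.5, 0.0, 1.0)
        ramp_in = np.clip((depth - (outer_mm - ring_w)) / (2.0 * mm_per_px) + 0.5, 0.0, 1.0)
        return np.minimum(ramp_out, ramp_in)

    coverage = np.maximum(_ring(r_sheath), _ring(0.72 * r_sheath))
    ring_db = noise_floor_db + (100.0 - noise_floor_db) * coverage
    sheath_db = np.where(coverage > 0, ring_db, -np.inf)[:, None]

    db_span = 110.0  # display dynamic range mapped onto uint16
    stack = np.empty((n_frames, geom.depth_px, geom.n_angles), dtype=np.uint16)
    for f in range(n_frames):
        r = gt.boundary_mm[f]  # (n_angles,)
        direct = (depth[:, None] >= r[None, :]) & (depth[:, None] <= (r + tissue_thickness_mm)[None, :])
        fold = (folded[:, None] >= np.maximum(r, rmax)[None, :]) & (
            folded[:, None] <= (r + tissue_thickness_mm)[None, :]
        )
        tissue_db = np.where(direct, sensitivity_db(depth)[:, None], -np.inf)
        tissue_db = np.maximum(tissue_db, np.where(fold, sensitivity_db(folded)[:, None], -np.inf))
        if speckle:
            # fully developed speckle: exponential intensity = additive dB term
            spk = 10.0 * np.log10(rng.exponential(1.0, size=tissue_db.shape) + 1e-12)
            tissue_db = tissue_db + np.where(np.isfinite(tissue_db), spk, 0.0)
        frame_db = np.maximum(tissue_db, sheath_db)
        noise = rng.normal(noise_floor_db, noise_db_spread, size=frame_db.shape)
        frame_db = np.maximum(frame_db, noise)
        np.clip(frame_db, 0.0, db_span, out=frame_db)
        stack[f] = (frame_db * (65535.0 / db_span)).astype(np.uint16)
    return stack, gt.frame_times_s.copy()


def average_alines(raw: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Average raw A-lines in groups of ``geom.aline_group`` columns.

    ``raw`` has shape (..., depth, n_angles * aline_group); the result has
    shape (..., depth, n_angles) where each output column is the arithmetic
    mean of its group. Depth is unchanged.
    """
    g = geom.aline_group
    n_raw = raw.shape[-1]
    if n_raw % g != 0:
        raise ValueError(f"raw column count {n_raw} not divisible by group size {g}")
    shaped = raw.reshape(raw.shape[:-1] + (n_raw // g, g))
    return shaped.mean(axis=-1)


def write_scan(
    out_dir: str | Path,
    stack: np.ndarray,
    frame_times: np.ndarray,
    geom: ScanGeometry,
    pressure_time_s: np.ndarray,
    pressure_cmH2O: np.ndarray,
    gt: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write one synthetic scan to disk in the pipeline's input formats.

    Multi-page 16-bit TIFF stack + geometry/timestamps JSON sidecar +
    pressure CSV; ground truth (if given) as a per-frame CSV and a JSON of
    scalar truth values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "stack.tiff",
        "geometry": out / "geometry.json",
        "pressure": out / "pressure.csv",
    }
    tifffile.imwrite(paths["stack"], stack, photometric="minisblack")
    geom.to_json(paths["geometry"], frame_times=frame_times)
    pd.DataFrame({"time_s": pressure_time_s, "pressure_cmH2O": pressure_cmH2O}).to_csv(
        paths["pressure"], index=False
    )
    if gt is not None:
        paths["gt_csa"] = out / "ground_truth_csa.csv"
        pd.DataFrame(
            {"frame": np.arange(len(gt.csa_mm2)), "csa_mm2_true": gt.csa_mm2}
        ).to_csv(paths["gt_csa"], index=False)
        paths["gt_json"] = out / "ground_truth.json"
        truth = {
            "ncsc_true_pct_per_cmH2O": gt.ncsc_true,
            "catheter_offset_mm": list(gt.catheter_offset_mm),
            "tube": asdict(gt.tube) if gt.tube is not None else None,
        }
        paths["gt_json"].write_text(json.dumps(truth, indent=2))
    return paths
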