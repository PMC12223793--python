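"""Lumen boundary recovery from polar frames.

Recovers the air--tissue interface per angular column, calibrates the pixel
scale from the catheter sheath, detects and mirror-corrects fold-over
aliasing, and integrates the boundary into a cross-sectional area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FoldRegionError, ScanRejectedError, SheathNotDetectedError
from .geometry import ScanGeometry

__all__ = [
    "LumenBoundary",
    "CsaSeries",
    "detect_sheath",
    "calibrate_scale",
    "segment_lumen",
    "correct_aliasing",
    "boundary_to_csa",
    "segment_stack",
]


@dataclass
class LumenBoundary:
    """Per-frame, per-column surface radius (pixels from the catheter axis).

    ``radius_px`` may exceed ``depth_px`` (after fold-over correction, up to
    ``2 * depth_px``); invalid columns are NaN. ``aliased`` marks columns
    whose radius was mirror-corrected. ``scale_mm_per_px`` converts radii to
    millimetres after sheath calibration.
    """

    radius_px: np.ndarray  # (n_frames, n_angles)
    aliased: np.ndarray  # bool, same shape
    scale_mm_per_px: float

    def radius_mm(self) -> np.ndarray:
        return self.radius_px * self.scale_mm_per_px


@dataclass
class CsaSeries:
    """Per-frame lumen cross-sectional area with timestamps."""

    csa_mm2: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.csa_mm2 <= 0):
            raise ValueError("CSA must be positive")


def detect_sheath(
    frame: np.ndarray,
    geom: ScanGeometry,
    search_fraction: float = 0.25,
    min_contrast: float = 0.1,
) -> float:
    """Outer radius of the catheter sheath in depth pixels.

    Averages the near-axis part of the frame over all columns and returns the
    outer edge of the bright ring band as the deepest half-maximum crossing
    of the column-mean profile, localized to sub-pixel by linear
    interpolation across the crossing.
    """
    n_search = max(4, int(search_fraction * frame.shape[0]))
    profile = frame[:n_search, :].astype(float).mean(axis=1)
    baseline = float(np.median(profile))
    peak = float(profile.max())
    full_scale = 65535.0 if frame.dtype == np.uint16 else max(peak, 1.0)
    if peak - baseline < min_contrast * full_scale:
        raise SheathNotDetectedError("sheath not detected: no bright near-axis band")
    threshold = baseline + 0.5 * (peak - baseline)
    above = np.nonzero(profile > threshold)[0]
    i = int(above[-1])
    if i + 1 >= profile.size:
        return float(i + 0.5)
    # sub-pixel: falling crossing between pixel centres i and i+1
    frac = (profile[i] - threshold) / (profile[i] - profile[i + 1])
    return float(i + 0.5 + frac)


def calibrate_scale(detected_sheath_px: float, geom: ScanGeometry) -> float:
    """Pixel scale (mm/px) that maps the detected sheath to its known OD.

    ``scale = (sheath_od / 2) / detected_radius_px``; applying it makes the
    sheath's physical radius identical across scans regardless of
    reference-arm mismatch.
    """
    if detected_sheath_px <= 0:
        raise ValueError("detected sheath radius must be positive")
    return (geom.sheath_od_mm / 2.0) / detected_sheath_px


@dataclass
class FrameSegmentation:
    surface_px: np.ndarray  # (n_angles,) NaN where invalid
    fold_cols: np.ndarray  # bool: columns inside a detected fold-over run
    bottom_cols: np.ndarray  # bool: surface reaches the bottom margin


def _column_threshold(region: np.ndarray) -> float:
    """Adaptive intensity threshold: robust noise level plus a 6-sigma guard.

    The search region below the sheath is mostly air, so the median estimates
    the noise floor; a one-sided quantile estimates its spread without being
    dragged up by the tissue band.
    """
    p50 = float(np.percentile(region, 50))
    p70 = float(np.percentile(region, 70))
    sigma = max((p70 - p50) / 0.5244, 0.005 * 65535.0)
    return p50 + 6.0 * sigma


def _first_rise(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading edge of the first pair of consecutive above-threshold pixels.

    Returned as the row index of the first pixel of the pair, i.e. the
    sub-pixel edge coordinate of the intensity rise (error <= 0.5 px for a
    band covering pixel centres).
    """
    pair = mask[:-1, :] & mask[1:, :]
    has = pair.any(axis=0)
    first = pair.argmax(axis=0)
    return first, has


def _last_fall(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trailing edge (row index past the deepest above-threshold pair)."""
    pair = mask[:-1, :] & mask[1:, :]
    has = pair.any(axis=0)
    rev = pair[::-1, :]
    last = pair.shape[0] - 1 - rev.argmax(axis=0)
    return last + 2, has


def _first_finite(surface: np.ndarray, run: np.ndarray, lookahead: int = 30) -> float | None:
    """First finite surface value among the first ``lookahead`` run columns."""
    for col in run[:lookahead]:
        if np.isfinite(surface[col]):
            return float(surface[col])
    return None


def _edge_depth(values: np.ndarray, run: np.ndarray, lookahead: int = 30) -> float:
    """Deepest finite value among the first ``lookahead`` run columns
    (robust to per-column speckle dropouts); NaN if none."""
    window = values[run[:lookahead]]
    return float(np.nanmax(window)) if np.isfinite(window).any() else np.nan


def _circular_close(flags: np.ndarray, size: int) -> np.ndarray:
    """Binary closing on a circular boolean array (fills holes < size)."""
    k = size
    padded = np.concatenate([flags[-k:], flags, flags[:k]])
    closed = ndimage.binary_closing(padded, structure=np.ones(size, dtype=bool))
    return closed[k:-k]


def _circular_runs(flags: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of True in a circular boolean array, as index arrays."""
    n = flags.size
    if flags.all():
        return [np.arange(n)]
    if not flags.any():
        return []
    # rotate so the array starts on a False entry, then find linear runs
    start = int(np.argmin(flags))
    rolled = np.roll(flags, -start)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], rolled.view(np.int8), [0]])))
    runs = []
    for s, e in zip(edges[::2], edges[1::2]):
        runs.append((np.arange(s, e) + start) % n)
    return runs


def segment_lumen(
    frame: np.ndarray,
    geom: ScanGeometry,
    sheath_px: float | None = None,
    seed_column_depths: np.ndarray | None = None,
    contact_margin_px: int = 4,
    bottom_margin_px: int = 3,
    median_window: int = 15,
    fold_jump_px: float = 15.0,
    seed_window_px: int = 40,
    max_missing_fraction: float = 0.5,
) -> FrameSegmentation:
    """Per-column air--tissue surface depth (px) with fold-over flags.

    For every column the surface is the first intensity rise above an
    adaptive threshold beyond the sheath, smoothed by a circular median
    filter. Columns whose surface lies within ``bottom_margin_px`` of the
    bottom row are marked bottom-contact; contiguous angular runs bounded by
    bottom-contact columns in which the apparent surface jumps upward by more
    than ``fold_jump_px`` are treated as fold-over regions, and within them
    the deeper (lower) band edge is selected in preference to the upper one.
    Columns where tissue touches the sheath are invalidated (NaN).

    ``seed_column_depths`` optionally restricts the search per column to a
    window around a prior estimate (stand-in for manual seeding).

    Fold-over handling: where the lumen approaches or exceeds the imaging
    range, the mirrored tissue merges with the directly imaged band into a
    bright region attached to the bottom of the frame; in that attached
    region the interface is unresolvable column-locally, so the segmentation
    line is pinned to the bottom row and flagged bottom-contact. A detached
    band sandwiched between two bottom-attached sectors whose deep edge
    emerges from the bottom is interpreted as a fold-over region (the lumen
    lies beyond the range there); within it the deeper band edge is taken in
    preference to the upper one, ready for mirror correction.
    """
    depth_px, n_angles = frame.shape
    if depth_px != geom.depth_px or n_angles != geom.n_angles:
        raise ValueError("frame dimensions do not match geometry")
    if sheath_px is None:
        sheath_px = detect_sheath(frame, geom)
    start0 = int(np.ceil(sheath_px)) + 1
    region = frame[start0:, :].astype(float)
    threshold = _column_threshold(region)
    mask = region > threshold
    if seed_column_depths is not None:
        rows = np.arange(start0, depth_px)[:, None]
        seeds = np.asarray(seed_column_depths, dtype=float)[None, :]
        windowed = np.abs(rows - seeds) <= seed_window_px
        mask = mask & (windowed | np.isnan(seeds))

    first, has_first = _first_rise(mask)
    surface = np.where(has_first, (start0 + first).astype(float), np.nan)

    # tissue (or debris) touching the sheath: unusable columns
    contact = has_first & (surface <= sheath_px + contact_margin_px)
    surface[contact] = np.nan

    # bright region attached to the bottom of the frame (the segmentation
    # line reaches the bottom there, or the fold-back hides the interface);
    # closed circularly to bridge single-column speckle dropouts
    attached = mask[-(bottom_margin_px + 2):, :].any(axis=0) & ~contact
    attached = _circular_close(attached, 9)

    # attached columns with no detectable rise: the band starts essentially
    # at the bottom row; pin them there
    pinned = attached & np.isnan(surface)
    surface[pinned] = float(depth_px - 1)

    bottom = np.isfinite(surface) & (surface >= depth_px - 1 - bottom_margin_px)
    fold = np.zeros(n_angles, dtype=bool)
    if attached.any() and not attached.all():
        last, has_last = _last_fall(mask)
        deep = np.where(has_last & ~contact, (start0 + last).astype(float), np.nan)
        near_bottom = depth_px - 1 - max(2 * fold_jump_px, 25)
        for run in _circular_runs(~attached):
            if run.size < 3:
                continue
            # detached band between two bottom-attached sectors: fold-over if
            # its deep edge emerges from the bottom on both sides
            dl = _edge_depth(deep, run)
            dr = _edge_depth(deep, run[::-1])
            if np.isnan(dl) or np.isnan(dr):
                continue
            if dl >= near_bottom and dr >= near_bottom:
                fold[run] = True
        if fold.any():
            # lower surface preferred: inside a fold the interface is the
            # deeper edge of the mirrored band
            surface[fold] = deep[fold]
            # walk outward from each fold run over the attached sectors while
            # the apparent (mirrored) surface still rises: there the true
            # interface is hidden by the fold-back, so pin the line to the
            # bottom row and flag it
            for run in _circular_runs(fold):
                for step, edge in ((-1, run[0]), (1, run[-1])):
                    run_max = -np.inf
                    col = (edge + step) % n_angles
                    walked = 0
                    while (
                        attached[col]
                        and walked < n_angles // 2
                        and np.isfinite(surface[col])
                        and surface[col] < depth_px - 1 - bottom_margin_px
                        and surface[col] >= run_max - fold_jump_px
                    ):
                        run_max = max(run_max, surface[col])
                        surface[col] = float(depth_px - 1)
                        bottom[col] = True
                        pinned[col] = True
                        col = (col + step) % n_angles
                        walked += 1
            bottom |= np.isfinite(surface) & (surface >= depth_px - 1 - bottom_margin_px)

    valid = ~np.isnan(surface)
    if valid.mean() < (1.0 - max_missing_fraction):
        raise ScanRejectedError(
            f"scan unusable: {np.count_nonzero(~valid)}/{n_angles} columns "
            "have no detectable surface"
        )
    # circular median smoothing of the detected surface (valid columns only);
    # pinned bottom-contact columns stay hard at the bottom row
    filled = _circular_fill(surface)
    smoothed = ndimage.median_filter(filled, size=median_window, mode="wrap")
    smoothed[~valid] = np.nan
    smoothed[pinned] = float(depth_px - 1)
    return FrameSegmentation(surface_px=smoothed, fold_cols=fold, bottom_cols=bottom)


def _circular_fill(values: np.ndarray) -> np.ndarray:
    """Fill NaNs by linear interpolation in the circular column index."""
    out = values.astype(float).copy()
    bad = np.isnan(out)
    if not bad.any():
        return out
    if bad.all():
        raise ScanRejectedError("no valid columns to interpolate")
    n = out.size
    idx = np.arange(n)
    good = ~bad
    # unwrap the circle by tiling good points one period on each side
    xp = np.concatenate([idx[good] - n, idx[good], idx[good] + n])
    fp = np.tile(out[good], 3)
    out[bad] = np.interp(idx[bad], xp, fp)
    return out


def correct_aliasing(
    surface_px: np.ndarray,
    flags: np.ndarray,
    geom: ScanGeometry,
    bottom_margin_px: int = 6,
) -> np.ndarray:
    """Mirror fold-over runs beyond the maximum imaging depth.

    Within each flagged run the corrected radius is
    ``2 * depth_px - apparent``; unflagged columns pass through unchanged.
    Each flagged run must be bounded (circularly) by columns whose surface
    reaches the bottom of the frame, otherwise the fold hypothesis is
    inconsistent and an error is raised. Applying the mirror twice restores
    the input (involution).
    """
    surface_px = np.asarray(surface_px, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if surface_px.shape != flags.shape:
        raise ValueError("surface and flags must have the same shape")
    n = surface_px.size
    for run in _circular_runs(flags):
        if run.size == n:
            raise FoldRegionError("fold region spans all columns; no bounding columns")
        left = (run[0] - 1) % n
        right = (run[-1] + 1) % n
        for edge in (left, right):
            v = surface_px[edge]
            if np.isnan(v) or v < geom.depth_px - 1 - bottom_margin_px:
                raise FoldRegionError(
                    "inconsistent fold region: flagged run not bounded by "
                    "bottom-touching columns"
                )
    out = surface_px.copy()
    out[flags] = 2.0 * geom.depth_px - surface_px[flags]
    return out


def boundary_to_csa(
    radii_mm: np.ndarray,
    angles: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> float:
    """Lumen area (mm^2) of a star-shaped boundary given per-column radii.

    Uses the polygon area of the closed polar contour,
    ``A = 1/2 * sum_j r_j r_{j+1} sin(dtheta_j)``. Invalid/NaN columns are
    filled by circular linear interpolation first; fewer than 3 valid columns
    is an error.
    """
    radii = np.asarray(radii_mm, dtype=float).copy()
    if valid is not None:
        radii[~np.asarray(valid, dtype=bool)] = np.nan
    n = radii.size
    if angles is None:
        angles = np.arange(n) * (2.0 * np.pi / n)
    n_valid = int(np.count_nonzero(~np.isnan(radii)))
    if n_valid < 3:
        raise ScanRejectedError(f"only {n_valid} valid columns; need >= 3 for an area")
    radii = _circular_fill(radii)
    r_next = np.roll(radii, -1)
    dtheta = np.diff(np.concatenate([angles, [angles[0] + 2.0 * np.pi]]))
    return float(0.5 * np.sum(radii * r_next * np.sin(dtheta)))


def segment_stack(
    stack: np.ndarray,
    geom: ScanGeometry,
    frame_times: np.ndarray | None = None,
    seed_depths: dict[int, np.ndarray] | None = None,
    **seg_kwargs,
) -> tuple[LumenBoundary, CsaSeries]:
    """Segment every frame of a stack and integrate per-frame CSA.

    Sheath detection and scale calibration use the first frame; fold-over
    runs are mirror-corrected per frame. Returns the corrected boundary and
    the calibrated CSA series.
    """
    n_frames = stack.shape[0]
    if frame_times is None:
        frame_times = np.arange(n_frames) / geom.frame_rate
    sheath_px = detect_sheath(stack[0], geom)
    scale = calibrate_scale(sheath_px, geom)
    radius_px = np.full((n_frames, geom.n_angles), np.nan)
    aliased = np.zeros((n_frames, geom.n_angles), dtype=bool)
    csa = np.empty(n_frames)
    angles = geom.angles()
    for f in range(n_frames):
        seeds = None if seed_depths is None else seed_depths.get(f)
        seg = segment_lumen(
            stack[f], geom, sheath_px=sheath_px, seed_column_depths=seeds, **seg_kwargs
        )
        corrected = correct_aliasing(seg.surface_px, seg.fold_cols, geom)
        radius_px[f] = corrected
        aliased[f] = seg.fold_cols
        csa[f] = boundary_to_csa(corrected * scale, angles)
    boundary = LumenBoundary(radius_px=radius_px, aliased=aliased, scale_mm_per_px=scale)
    return boundary, CsaSeries(csa_mm2=csa, time_s=np.asarray(frame_times, dtype=float))
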