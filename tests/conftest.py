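"""Shared fixtures: reduced-size synthetic scans generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from aoctel import synth
from aoctel.geometry import ScanGeometry


@pytest.fixture(scope="session")
def small_geom() -> ScanGeometry:
    """Reduced acquisition: same 12.5 mm range, coarser sampling, 20 Hz
    frames over 12.5 s so the cycle structure matches the full-size scan."""
    return ScanGeometry(
        frame_rate=20.0,
        n_frames=250,
        depth_px=384,
        n_angles=416,
        pressure_rate=2000.0,
    )


@pytest.fixture(scope="session")
def tube() -> synth.TubeModel:
    return synth.TubeModel(
        inner_radius_mm=8.0, outer_radius_mm=10.0, youngs_modulus_cmH2O=4000.0
    )


@pytest.fixture(scope="session")
def quiet_vent() -> synth.VentilatorParams:
    return synth.VentilatorParams(noise_sd_cmH2O=0.0)


def make_scan(
    tube: synth.TubeModel,
    geom: ScanGeometry,
    noisy: bool,
    seed: int = 0,
    offset=(0.2, 0.1),
    **render_kwargs,
):
    """Generate (ground truth, stack, frame times, pressure) for one scan."""
    vent = synth.VentilatorParams(noise_sd_cmH2O=1.32 if noisy else 0.0)
    t, p = synth.make_pressure(vent, geom, seed=seed)
    gt = synth.simulate_boundary(tube, t, p, geom, catheter_offset_mm=offset, seed=seed)
    render_kwargs.setdefault("speckle", noisy)
    if not noisy:
        render_kwargs.setdefault("noise_db_spread", 0.0)
    stack, ft = synth.render_frames(gt, geom, seed=seed + 1, **render_kwargs)
    return gt, stack, ft, t, p


@pytest.fixture(scope="session")
def noiseless_scan(tube, small_geom):
    return make_scan(tube, small_geom, noisy=False, seed=11)


@pytest.fixture(scope="session")
def speckled_scan(tube, small_geom):
    return make_scan(tube, small_geom, noisy=True, seed=13)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
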