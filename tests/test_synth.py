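import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_bvp

from aoctel import synth
from aoctel.errors import ScanRejectedError
from aoctel.geometry import ScanGeometry
from conftest import make_scan

# ---------------------------------------------------------------- pressure


def test_pressure_trace_covers_full_scan_duration():
    geom = ScanGeometry()  # 500 frames at 40 Hz -> 12.5 s
    t, p = synth.make_pressure(synth.VentilatorParams(), geom, seed=0)
    assert len(t) == round(12.5 * geom.pressure_rate)
    assert t[-1] == pytest.approx(12.5 - 1.0 / geom.pressure_rate)


def test_noiseless_full_modulation_hits_mip_and_peep_exactly():
    geom = ScanGeometry()
    vent = synth.VentilatorParams(noise_sd_cmH2O=0.0, attenuation=1.0)
    _, p = synth.make_pressure(vent, geom, seed=0)
    assert p.max() == vent.mip_cmH2O
    assert p.min() == vent.peep_cmH2O


def test_attenuation_scales_plateau():
    geom = ScanGeometry()
    vent = synth.VentilatorParams(noise_sd_cmH2O=0.0, attenuation=0.5)
    _, p = synth.make_pressure(vent, geom, seed=0)
    assert p.max() == pytest.approx(vent.peep_cmH2O + 0.5 * (18.0 - vent.peep_cmH2O))


def test_scan_contains_at_least_three_full_breaths():
    # 12.5 s at 20 breaths/min -> 4 complete 3 s periods
    geom = ScanGeometry()
    vent = synth.VentilatorParams(noise_sd_cmH2O=0.0)
    t, p = synth.make_pressure(vent, geom, seed=0)
    n_periods = int(np.floor((t[-1] + 1 / geom.pressure_rate) / vent.period_s))
    assert n_periods >= 3


@given(bpm=st.floats(8.0, 40.0), peep=st.floats(0.0, 8.0))
@settings(max_examples=25, deadline=None)
def test_noiseless_waveform_is_periodic(bpm, peep):
    geom = ScanGeometry(n_frames=200, frame_rate=40.0, pressure_rate=2000.0)
    vent = synth.VentilatorParams(
        breaths_per_min=bpm, peep_cmH2O=peep, noise_sd_cmH2O=0.0
    )
    t, p = synth.make_pressure(vent, geom, seed=0)
    period = 60.0 / bpm
    n_shift = period * geom.pressure_rate
    if abs(n_shift - round(n_shift)) > 1e-9:
        return  # period not representable on the sample grid
    n_shift = int(round(n_shift))
    if n_shift >= len(p):
        return
    np.testing.assert_allclose(p[n_shift:], p[:-n_shift], atol=1e-9)


def test_pressure_noise_is_seeded():
    geom = ScanGeometry(n_frames=50)
    vent = synth.VentilatorParams()
    _, p1 = synth.make_pressure(vent, geom, seed=5)
    _, p2 = synth.make_pressure(vent, geom, seed=5)
    _, p3 = synth.make_pressure(vent, geom, seed=6)
    np.testing.assert_array_equal(p1, p2)
    assert not np.array_equal(p1, p3)


def test_invalid_ventilator_params_rejected():
    with pytest.raises(ValueError):
        synth.VentilatorParams(mip_cmH2O=5.0, peep_cmH2O=5.0)
    with pytest.raises(ValueError):
        synth.VentilatorParams(attenuation=0.0)
    with pytest.raises(ValueError):
        synth.VentilatorParams(breaths_per_min=0.0)


# ---------------------------------------------------------------- analytic nCsC


def _ncsc_numeric_oracle(a, b, e, nu, dp=0.01):
    """Independent oracle: solve the radial-equilibrium ODE
    u'' + u'/r - u/r**2 = 0 with traction boundary conditions numerically."""
    c = e / ((1.0 + nu) * (1.0 - 2.0 * nu))

    def sigma_rr(r, u, du):
        return c * ((1.0 - nu) * du + nu * u / r)

    def odefun(r, y):
        return np.vstack([y[1], y[0] / r**2 - y[1] / r])

    def bc(ya, yb):
        return np.array(
            [sigma_rr(a, ya[0], ya[1]) + dp, sigma_rr(b, yb[0], yb[1])]
        )

    r = np.linspace(a, b, 200)
    y0 = np.zeros((2, r.size))
    sol = solve_bvp(odefun, bc, r, y0, tol=1e-10)
    assert sol.success
    u_a = sol.sol(a)[0]
    return 100.0 * (2.0 * u_a / a) / dp


def test_analytic_ncsc_matches_numeric_elasticity_solution():
    tube = synth.TubeModel(8.0, 10.0, 500.0, poisson=0.45)
    oracle = _ncsc_numeric_oracle(8.0, 10.0, 500.0, 0.45)
    assert synth.analytic_ncsc(tube) == pytest.approx(oracle, rel=0.01)


@given(k=st.floats(0.1, 10.0))
@settings(max_examples=40, deadline=None)
def test_analytic_ncsc_scale_invariant(k):
    base = synth.TubeModel(8.0, 10.0, 500.0, poisson=0.45)
    scaled = synth.TubeModel(8.0 * k, 10.0 * k, 500.0, poisson=0.45)
    assert synth.analytic_ncsc(scaled) == pytest.approx(
        synth.analytic_ncsc(base), rel=1e-12
    )


def test_analytic_ncsc_halves_when_modulus_doubles():
    soft = synth.TubeModel(8.0, 10.0, 500.0)
    stiff = synth.TubeModel(8.0, 10.0, 1000.0)
    assert synth.analytic_ncsc(stiff) == pytest.approx(
        synth.analytic_ncsc(soft) / 2.0, rel=1e-12
    )


@given(e1=st.floats(100.0, 5000.0), e2=st.floats(100.0, 5000.0))
@settings(max_examples=25, deadline=None)
def test_analytic_ncsc_strictly_decreasing_in_modulus(e1, e2):
    if e1 == e2:
        return
    lo, hi = sorted([e1, e2])
    n_lo = synth.analytic_ncsc(synth.TubeModel(8.0, 10.0, lo))
    n_hi = synth.analytic_ncsc(synth.TubeModel(8.0, 10.0, hi))
    assert n_lo > n_hi


@given(b1=st.floats(8.2, 16.0), b2=st.floats(8.2, 16.0))
@settings(max_examples=25, deadline=None)
def test_analytic_ncsc_increases_as_wall_thins(b1, b2):
    if b1 == b2:
        return
    thin, thick = sorted([b1, b2])
    n_thin = synth.analytic_ncsc(synth.TubeModel(8.0, thin, 500.0))
    n_thick = synth.analytic_ncsc(synth.TubeModel(8.0, thick, 500.0))
    assert n_thin > n_thick


def test_degenerate_tube_rejected():
    with pytest.raises(ValueError):
        synth.TubeModel(10.0, 8.0, 500.0)
    with pytest.raises(ValueError):
        synth.TubeModel(8.0, 10.0, -1.0)
    with pytest.raises(ValueError):
        synth.TubeModel(8.0, 10.0, 500.0, poisson=0.5)


# ---------------------------------------------------------------- boundary simulation


def test_constant_pressure_gives_rest_circle(small_geom):
    tube = synth.TubeModel(8.0, 10.0, 4000.0, rest_pressure_cmH2O=5.0)
    t = np.arange(int(small_geom.duration_s * small_geom.pressure_rate))
    t = t / small_geom.pressure_rate
    p = np.full_like(t, 5.0)
    gt = synth.simulate_boundary(tube, t, p, small_geom)
    assert np.ptp(gt.boundary_mm) == pytest.approx(0.0, abs=1e-12)
    assert gt.csa_mm2[0] == pytest.approx(np.pi * 64.0, rel=1e-3)


def test_ground_truth_fields_reproduce_ncsc(small_geom, quiet_vent):
    # soft enough for the linearized radius response to stay within 1%
    tube = synth.TubeModel(8.0, 10.0, 5000.0)
    t, p = synth.make_pressure(quiet_vent, small_geom, seed=3)
    gt = synth.simulate_boundary(tube, t, p, small_geom)
    from aoctel.elasto import frame_pressure_stats

    fp = frame_pressure_stats(t, p, gt.frame_times_s, small_geom.frame_rate)
    d_csa = gt.csa_mm2.max() - gt.csa_mm2.min()
    csa_bar = (gt.csa_mm2.max() + gt.csa_mm2.min()) / 2.0
    d_p = fp.mean_cmH2O.max() - fp.mean_cmH2O.min()
    assert 100.0 * (d_csa / csa_bar) / d_p == pytest.approx(gt.ncsc_true, rel=0.01)


def test_offset_circle_radii_span(small_geom):
    tube = synth.TubeModel(8.0, 10.0, 4000.0, rest_pressure_cmH2O=5.0)
    t = np.arange(1000) / small_geom.pressure_rate
    geom = ScanGeometry(
        frame_rate=small_geom.frame_rate,
        n_frames=int(t[-1] * small_geom.frame_rate),
        depth_px=small_geom.depth_px,
        n_angles=small_geom.n_angles,
        pressure_rate=small_geom.pressure_rate,
    )
    p = np.full_like(t, 5.0)
    gt = synth.simulate_boundary(tube, t, p, geom, catheter_offset_mm=(1.0, 0.0))
    assert gt.boundary_mm.min() == pytest.approx(7.0, abs=1e-3)
    assert gt.boundary_mm.max() == pytest.approx(9.0, abs=1e-3)


def test_catheter_touching_wall_rejected(small_geom, quiet_vent):
    tube = synth.TubeModel(1.0, 2.0, 4000.0)
    t, p = synth.make_pressure(quiet_vent, small_geom, seed=0)
    with pytest.raises(ScanRejectedError):
        synth.simulate_boundary(tube, t, p, small_geom, catheter_offset_mm=(1.5, 0.0))


def test_csa_consistent_with_boundary_polygon(noiseless_scan, small_geom):
    gt = noiseless_scan[0]
    ang = small_geom.angles()
    from aoctel.segment import boundary_to_csa

    for f in (0, 60, 150):
        area = boundary_to_csa(gt.boundary_mm[f], ang)
        assert area == pytest.approx(gt.csa_mm2[f], rel=1e-3)


def test_cardiac_modulation_adds_csa_ripple(small_geom, tube, quiet_vent):
    t, p = synth.make_pressure(quiet_vent, small_geom, seed=0)
    gt0 = synth.simulate_boundary(tube, t, p, small_geom)
    gt1 = synth.simulate_boundary(
        tube, t, p, small_geom, cardiac_amp=0.02, cardiac_hz=1.5
    )
    ripple = gt1.csa_mm2 / gt0.csa_mm2 - 1.0
    assert np.ptp(ripple) == pytest.approx(0.02 * 2, rel=0.15)


# ---------------------------------------------------------------- rendering


def test_surface_rendered_at_true_depth_row(small_geom, quiet_vent):
    tube = synth.TubeModel(10.0, 12.0, 4000.0, rest_pressure_cmH2O=5.0)
    geom = ScanGeometry(
        frame_rate=20.0, n_frames=2, depth_px=1152, n_angles=416, pressure_rate=2000.0
    )
    t = np.arange(int(geom.duration_s * geom.pressure_rate)) / geom.pressure_rate
    p = np.full_like(t, 5.0)
    gt = synth.simulate_boundary(tube, t, p, geom)
    stack, _ = synth.render_frames(gt, geom, speckle=False, noise_db_spread=0.0, seed=0)
    expected_row = 10.0 / (12.5 / 1152)
    frame = stack[0]
    thr = frame.max() * 0.25
    for col in range(0, geom.n_angles, 37):
        sheath_clear = frame[60:, col]
        row = 60 + int(np.argmax(sheath_clear > thr))
        assert abs(row - expected_row) <= 1.0


def test_beyond_range_surface_folds_to_mirrored_depth():
    geom = ScanGeometry(
        frame_rate=20.0, n_frames=1, depth_px=1152, n_angles=64, pressure_rate=2000.0
    )
    gt = synth.GroundTruth(
        boundary_mm=np.full((1, 64), 14.0),
        csa_mm2=np.array([np.pi * 14.0**2]),
        pressure_cmH2O=np.zeros(10),
        pressure_time_s=np.arange(10) / 2000.0,
        ncsc_true=0.1,
        frame_times_s=np.array([0.0]),
    )
    stack, _ = synth.render_frames(gt, geom, speckle=False, noise_db_spread=0.0, seed=0)
    frame = stack[0]
    beyond_sheath = frame[60:, 0]
    thr = np.median(beyond_sheath) + 0.05 * 65535  # noise floor + margin
    # folded surface: tissue occupies apparent depths up to 2*12.5 - 14 = 11 mm
    deepest = 60 + np.max(np.nonzero(beyond_sheath > thr)[0])
    expected = 11.0 / (12.5 / 1152)
    assert abs((deepest + 1) - expected) <= 1.5


def test_unrenderable_fold_rejected():
    geom = ScanGeometry(
        frame_rate=20.0, n_frames=1, depth_px=256, n_angles=32, pressure_rate=2000.0
    )
    gt = synth.GroundTruth(
        boundary_mm=np.full((1, 32), 2 * 12.5),
        csa_mm2=np.array([1.0]),
        pressure_cmH2O=np.zeros(10),
        pressure_time_s=np.arange(10) / 2000.0,
        ncsc_true=0.1,
        frame_times_s=np.array([0.0]),
    )
    with pytest.raises(ValueError, match="rendered"):
        synth.render_frames(gt, geom, seed=0)


def test_render_is_seeded(tube, small_geom):
    geom = ScanGeometry(
        frame_rate=20.0, n_frames=2, depth_px=128, n_angles=64, pressure_rate=2000.0
    )
    gt, stack1, *_ = make_scan(tube, geom, noisy=True, seed=4, offset=(0.0, 0.0))
    _, stack2, *_ = make_scan(tube, geom, noisy=True, seed=4, offset=(0.0, 0.0))
    np.testing.assert_array_equal(stack1, stack2)


# ---------------------------------------------------------------- A-line averaging


def test_average_alines_collapses_identical_groups():
    geom = ScanGeometry()
    raw = np.ones((3, 4992))
    out = synth.average_alines(raw, geom)
    assert out.shape == (3, 1248)
    np.testing.assert_array_equal(out, 1.0)


def test_average_alines_is_group_mean():
    geom = ScanGeometry(n_angles=1)
    raw = np.array([[0.0, 0.0, 0.0, 4.0]])
    np.testing.assert_array_equal(synth.average_alines(raw, geom), [[1.0]])


def test_average_alines_matches_bruteforce(rng):
    geom = ScanGeometry(n_angles=16, aline_group=4)
    raw = rng.normal(size=(2, 9, 64))
    out = synth.average_alines(raw, geom)
    # independent oracle: explicit loop over groups
    expected = np.empty((2, 9, 16))
    for j in range(16):
        expected[..., j] = raw[..., 4 * j : 4 * j + 4].mean(axis=-1)
    np.testing.assert_allclose(out, expected, rtol=0, atol=0)


def test_average_alines_rejects_indivisible_counts():
    geom = ScanGeometry(n_angles=16, aline_group=4)
    with pytest.raises(ValueError, match="divisible"):
        synth.average_alines(np.ones((4, 63)), geom)
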