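"""Tests of force-displacement cycle reduction and friction metrics."""

import numpy as np
import pandas as pd
import pytest

import hairbundle as hb
from hairbundle.cycles import (
    ForceCycle,
    activation_time,
    average_cycles,
    cycle_metrics,
    friction_profile,
    inversion_point,
    mean_position,
)
from hairbundle.simulate import DynamicBundleParams, FiberParams, simulate_cycle


@pytest.fixture(scope="module")
def gated_cycle(request):
    """Paper-protocol simulation: 40 Hz, 600 nm peak-to-peak triangular
    stimulus, gated bundle with 1-ms activation time."""
    p = hb.with_force_zero_at_origin(
        hb.GatingSpringParams(K=0.85, F_G=17.0, X_0=-2.0, delta=20.0)
    )
    dp = DynamicBundleParams(p, xi=1e-4, tau_a=1e-3)
    raw = simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, 10)
    return p, raw


def _viscous_raw(noise_seed=None, n_cycles=6, noise_sd=0.0):
    p = hb.GatingSpringParams(K=0.85, F_G=0.0, X_0=0.0, delta=20.0)
    dp = DynamicBundleParams(p, xi=1e-4, tau_a=0.0)
    raw = simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, n_cycles)
    if noise_sd:
        rng = np.random.default_rng(noise_seed)
        raw = raw.assign(F_pN=raw.F_pN + rng.normal(0.0, noise_sd, len(raw)))
    return raw


def test_averaging_shrinks_force_noise_as_sqrt_n():
    """Residual SD of the binned half-cycle shrinks ~1/sqrt(n cycles)."""
    sds = []
    for n in (1, 4, 16):
        raw = _viscous_raw(noise_seed=1, n_cycles=n, noise_sd=2.0)
        c = average_cycles(raw, 40.0)
        ok = np.isfinite(c.F_plus)
        A = np.vstack([c.X[ok], np.ones(ok.sum())]).T
        coef, *_ = np.linalg.lstsq(A, c.F_plus[ok], rcond=None)
        sds.append(float(np.std(c.F_plus[ok] - A @ coef)))
    assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.35)
    assert sds[1] / sds[2] == pytest.approx(2.0, rel=0.35)


def test_single_noiseless_cycle_binning_is_faithful():
    raw = _viscous_raw(n_cycles=1)
    c = average_cycles(raw, 40.0)
    # away from the turning points, the binned up-branch lies on the viscous
    # closed form K*X + xi*v_bundle to well within a bin
    v = 2.0 * np.ptp(raw.X_nm.to_numpy()) * 40.0
    interior = slice(10, 90)
    ok = np.isfinite(c.F_plus[interior])
    resid = c.F_plus[interior][ok] - (0.85 * c.X[interior][ok] + 1e-4 * v)
    assert np.max(np.abs(resid)) < 0.5


def test_cycle_grid_covers_stimulus_with_stiff_fiber(control_params):
    """With a stiff fiber the bundle tracks the base: the averaged cycle
    spans >= 480 nm of the 600-nm stimulus (>= 80% coverage)."""
    dp = DynamicBundleParams(control_params, xi=1e-4, tau_a=1e-3)
    raw = simulate_cycle(dp, FiberParams(5.0), 40.0, 600.0, 10)
    c = average_cycles(raw, 40.0)
    assert np.ptp(c.X) >= 480.0
    assert c.coverage >= 0.8


def test_truncation_error_when_too_few_cycles():
    raw = _viscous_raw(n_cycles=2)
    with pytest.raises(ValueError, match="cycles"):
        average_cycles(raw, 40.0, n_cycles=5)


def test_viscous_friction_profile_is_flat_xi_v():
    """With no gating force the friction profile is flat and equals xi*v,
    v being the bundle's cycle speed, within 2%."""
    raw = _viscous_raw()
    c = average_cycles(raw, 40.0)
    phi, phi_max, x_at, flat = friction_profile(c)
    assert flat
    assert x_at is None
    X = raw.X_nm.to_numpy()
    v = 2.0 * (X.max() - X.min()) * 40.0  # bundle speed on the triangle
    assert phi_max == pytest.approx(1e-4 * v, rel=0.02)


def test_reversible_cycle_has_vanishing_friction(control_params):
    """Quasi-static stimulation (slow ramp, instantaneous gating) leaves
    only the residual viscous contribution, far below the gated phi_MAX."""
    dp = DynamicBundleParams(control_params, xi=1e-4, tau_a=0.0)
    raw = simulate_cycle(dp, FiberParams(0.5), 2.0, 600.0, 2, dt=1e-5)
    c = average_cycles(raw, 2.0)
    phi, phi_max, _, _ = friction_profile(c)
    assert phi_max < 0.2  # pN; gated cycles at 40 Hz reach ~5 pN


def test_phi_argmax_near_set_point(gated_cycle):
    p, raw = gated_cycle
    c = average_cycles(raw, 40.0)
    _, _, x_at, flat = friction_profile(c)
    assert not flat
    grid_step = np.ptp(c.X) / 100.0
    assert abs(x_at - p.X_0) <= 1.5 * grid_step


def test_friction_nonnegative_for_dissipative_cycles(gated_cycle):
    _, raw = gated_cycle
    c = average_cycles(raw, 40.0)
    phi, *_ = friction_profile(c)
    interior = phi[np.isfinite(phi)][3:-3]
    assert np.all(interior > -1e-9)


def test_phi_max_monotone_in_gating_force():
    """phi_MAX grows with the generating gating force (the property that
    makes it a reporter for F_G)."""
    phis = []
    for fg in (0.0, 5.0, 10.0, 17.0):
        p = hb.with_force_zero_at_origin(
            hb.GatingSpringParams(K=0.85, F_G=fg, X_0=-2.0, delta=20.0)
        )
        dp = DynamicBundleParams(p, xi=1e-4, tau_a=1e-3)
        raw = simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, 6)
        _, phi_max, _, _ = friction_profile(average_cycles(raw, 40.0))
        phis.append(phi_max)
    assert np.all(np.diff(phis) > 0)


def test_energy_consistency(gated_cycle):
    """Enclosed cycle area (dissipated work) equals the path integral of the
    friction profile within 2%."""
    _, raw = gated_cycle
    n_per = len(raw) // 10
    X = raw.X_nm.to_numpy()[: 10 * n_per]
    F = raw.F_pN.to_numpy()[: 10 * n_per]
    area = 0.0
    for k in range(10):
        sl = slice(k * n_per, (k + 1) * n_per)
        area += np.trapezoid(F[sl], X[sl])
    area /= 10.0
    c = average_cycles(raw, 40.0)
    phi, *_ = friction_profile(c)
    ok = np.isfinite(c.F_plus) & np.isfinite(c.F_minus)
    path = 2.0 * np.trapezoid(phi[ok], c.X[ok])
    assert area == pytest.approx(path, rel=0.02)


# ---------------------------------------------------------------------------
# inversion point


def _symmetric_cycle(a=10.0, b=4.0):
    """Constructed cycle symmetric about (a, b) with a friction bump at a."""
    X = np.linspace(a - 100.0, a + 100.0, 101)
    bump = 3.0 * np.exp(-((X - a) ** 2) / (2 * 25.0**2))
    F_mid = b + 0.5 * (X - a)
    return ForceCycle(X=X, F_plus=F_mid + bump, F_minus=F_mid - bump,
                      freq=40.0, peak_to_peak=200.0, n_averaged=1)


def test_inversion_point_of_symmetric_cycle():
    x0, f0, flat = inversion_point(_symmetric_cycle(10.0, 4.0))
    assert not flat
    assert x0 == pytest.approx(10.0, abs=2.1)  # one grid step
    assert f0 == pytest.approx(4.0 + 0.5 * (x0 - 10.0), abs=1e-9)


def test_inversion_point_force_offset_equivariance():
    c = _symmetric_cycle(10.0, 4.0)
    c_off = ForceCycle(X=c.X, F_plus=c.F_plus + 6.0, F_minus=c.F_minus + 6.0,
                       freq=40.0, peak_to_peak=200.0, n_averaged=1)
    _, f0, _ = inversion_point(c)
    _, f0_off, _ = inversion_point(c_off)
    assert f0_off - f0 == pytest.approx(6.0, abs=1e-12)


def test_inversion_trajectory_slope_tracks_stiffness():
    """As the set point migrates (a current ramp), the inversion-point
    trajectory is near-linear with slope close to the symmetric-part
    stiffness of the cycle."""
    pts = []
    for x0 in (-60.0, -30.0, 0.0, 30.0, 60.0):
        p = hb.GatingSpringParams(K=0.85, F_G=17.0, X_0=x0, delta=20.0, F_null=8.5)
        dp = DynamicBundleParams(p, xi=1e-4, tau_a=1e-3)
        raw = simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, 4)
        c = average_cycles(raw, 40.0)
        pts.append(inversion_point(c)[:2])
    pts = np.asarray(pts)
    reg = hb.regress(pts[:, 0], pts[:, 1])
    assert reg.r_squared > 0.98
    # dF0/dX0 = K - F_G * dP/dX ... ~ K at the half-open point minus gating dip
    assert 0.3 <= reg.slope <= 0.9


# ---------------------------------------------------------------------------
# activation time and mean position


def test_activation_time_formula_scale(gated_cycle):
    """tau = DeltaX/(2*V_MAX) recovers the generating activation time to
    within ~30% for the paper protocol."""
    _, raw = gated_cycle
    tau = activation_time(raw, 40.0)
    assert tau == pytest.approx(1e-3, rel=0.35)


def test_activation_time_zero_limit(control_params):
    dp = DynamicBundleParams(control_params, xi=1e-5, tau_a=0.0)
    raw = simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, 6, dt=2e-6)
    tau = activation_time(raw, 40.0)
    # below two grid steps' worth of travel time
    v = 2.0 * np.ptp(raw.X_nm.to_numpy()) * 40.0
    assert tau < 2.0 * (np.ptp(raw.X_nm.to_numpy()) / 100.0) / v


def test_activation_time_monotone_in_tau_a(control_params):
    taus = []
    for ta in (0.25e-3, 0.5e-3, 1e-3, 2e-3):
        dp = DynamicBundleParams(control_params, xi=1e-4, tau_a=ta)
        raw = simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, 6)
        taus.append(activation_time(raw, 40.0))
    assert np.all(np.diff(taus) > 0)


def test_mean_position_tracks_offset():
    t = np.arange(0, 1.0, 1e-4)
    X = 25.0 + 100.0 * np.sin(2 * np.pi * 10 * t)
    raw = pd.DataFrame({"t_s": t, "Delta_nm": X, "X_nm": X, "F_pN": np.zeros_like(t)})
    assert mean_position(raw, freq=10.0) == pytest.approx(25.0, abs=1e-9)


def test_cycle_metrics_bundle(gated_cycle):
    p, raw = gated_cycle
    m = cycle_metrics(raw, 40.0)
    assert m.phi_max_pN > 3.0
    assert not m.flat_phi
    assert not m.sign_flag
    assert abs(m.X0_nm - p.X_0) < 6.0
    assert m.tau_act_s > 0
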