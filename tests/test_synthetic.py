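"""Tests of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

import hairbundle as hb
from hairbundle.simulate import (
    DivergenceError,
    DynamicBundleParams,
    EnsembleGenConfig,
    FiberParams,
    ObservableModel,
    StateTransitionModel,
    double_lorentzian_psd,
    find_equilibria,
    gen_bimodal_positions,
    gen_ensemble,
    gen_fd_step_protocol,
    gen_oscillation_trace,
    gen_rc_step,
    gen_step_kinetics,
    simulate_cycle,
)

BISTABLE = hb.with_force_zero_at_origin(
    hb.GatingSpringParams(K=0.85, F_G=17.0, X_0=0.0, delta=4.0)
)


# ---------------------------------------------------------------------------
# quasi-static step protocol


def test_linear_closed_form_root():
    """With F_G = 0 the force balance has the closed form X = k_F*Delta/(k_F+K)."""
    p = hb.GatingSpringParams(K=1.0, F_G=0.0, X_0=0.0, delta=20.0)
    df = gen_fd_step_protocol(p, FiberParams(0.5), [300.0])
    assert df.X_nm.iloc[0] == pytest.approx(100.0, abs=1e-9)
    assert df.F_pN.iloc[0] == pytest.approx(100.0, abs=1e-9)


def test_zero_command_gives_resting_point(control_params):
    df = gen_fd_step_protocol(control_params, FiberParams(0.5), [0.0])
    assert df.X_nm.iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert df.F_pN.iloc[0] == pytest.approx(0.0, abs=1e-9)


def _dense_scan_root(Delta, p, k_F, x_prev):
    """Brute-force oracle: stable root nearest x_prev from a dense scan."""
    grid = np.arange(-500.0, 500.0, 0.01)
    g = k_F * (Delta - grid) - hb.fd_force(grid, p)
    idx = np.flatnonzero(np.sign(g[:-1]) != np.sign(g[1:]))
    roots = grid[idx] - g[idx] * 0.01 / (g[idx + 1] - g[idx])
    stable = roots[np.atleast_1d(hb.fd_slope(roots, p) + k_F > 0)]
    return stable[np.argmin(np.abs(stable - x_prev))]


def test_bistable_branch_matches_dense_scan_oracle():
    """Continuation branch selection agrees with the dense root-scan oracle
    on both sweep directions, and every reported point satisfies the force
    balance to < 1e-9 pN."""
    k_F = 0.1
    sched = np.linspace(-300.0, 300.0, 15)
    for schedule in (sched, sched[::-1]):
        df = gen_fd_step_protocol(BISTABLE, FiberParams(k_F), schedule)
        x_prev = _dense_scan_root(0.0, BISTABLE, k_F, 0.0)
        for Delta, x_sel in zip(schedule, df.X_nm.to_numpy()):
            resid = k_F * (Delta - x_sel) - hb.fd_force(x_sel, BISTABLE)
            assert abs(resid) < 1e-9
            want = _dense_scan_root(Delta, BISTABLE, k_F, x_prev)
            assert x_sel == pytest.approx(want, abs=0.02)
            x_prev = x_sel


def test_bistable_sweeps_are_hysteretic():
    """Up and down sweeps select different branches inside the bistable range."""
    k_F = 0.1
    sched = np.linspace(-300.0, 300.0, 25)
    up = gen_fd_step_protocol(BISTABLE, FiberParams(k_F), sched).X_nm.to_numpy()
    dn = gen_fd_step_protocol(BISTABLE, FiberParams(k_F), sched[::-1]).X_nm.to_numpy()[::-1]
    assert np.max(np.abs(up - dn)) > 5.0


def test_find_equilibria_counts_roots():
    roots, stable = find_equilibria(0.0, BISTABLE, 0.1)
    assert roots.size == 3
    assert stable.sum() == 2  # outer roots stable, middle unstable


# ---------------------------------------------------------------------------
# dynamic cycles


def test_cycle_quasi_static_limit(control_params):
    """Slow stimulation with instantaneous gating collapses onto the
    quasi-static gating-spring curve (within 0.5 nm of displacement)."""
    dp = DynamicBundleParams(control_params, xi=1e-4, tau_a=0.0)
    raw = simulate_cycle(dp, FiberParams(0.5), freq=2.0, peak_to_peak=600.0,
                         n_cycles=2, dt=1e-5)
    F_qs = hb.fd_force(raw.X_nm.to_numpy(), control_params)
    x_equiv = np.abs(raw.F_pN.to_numpy() - F_qs) / control_params.K
    assert x_equiv.max() < 0.5


def test_cycle_dt_halving_contract(control_params):
    """Halving dt changes the maximal friction force by < 1%."""
    from hairbundle.cycles import average_cycles, friction_profile

    dp = DynamicBundleParams(control_params, xi=1e-4, tau_a=1e-3)
    phis = []
    for dt in (2e-5, 1e-5):
        raw = simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, 6, dt=dt)
        _, phi_max, _, _ = friction_profile(average_cycles(raw, 40.0))
        phis.append(phi_max)
    assert abs(phis[1] - phis[0]) / phis[1] < 0.01


def test_cycle_divergence_error_names_dt(control_params):
    dp = DynamicBundleParams(control_params, xi=1e-6, tau_a=0.0)
    with pytest.raises(DivergenceError, match="dt"):
        simulate_cycle(dp, FiberParams(0.5), 40.0, 600.0, 2, dt=1e-4)


# ---------------------------------------------------------------------------
# oscillations


def test_oscillation_rms_closed_form():
    """sqrt(4*pi*A*Q/f0) = 1 for A=1, Q=1, f0=4*pi."""
    tr = gen_oscillation_trace(1.0, 4.0 * np.pi, 1.0, fs=200.0, duration=20.0, seed=3)
    assert tr.X_nm.std() == pytest.approx(1.0, rel=0.05)


def test_oscillation_zero_amplitude():
    tr = gen_oscillation_trace(0.0, 8.0, 2.0, fs=250.0, duration=20.0, seed=0)
    assert np.all(tr.X_nm.to_numpy() == 0.0)


def test_oscillation_rejects_low_sampling():
    with pytest.raises(ValueError, match="alias"):
        gen_oscillation_trace(1.0, 80.0, 2.0, fs=250.0, duration=20.0)


def test_averaged_periodogram_matches_target_density():
    """The mean periodogram over 50 seeds tracks the target two-sided
    density within 5% in the band [f0/4, 4*f0]."""
    from hairbundle.oscillation import power_spectrum

    A, f0, Q = 2.0, 8.0, 1.5
    acc = None
    for s in range(50):
        tr = gen_oscillation_trace(A, f0, Q, fs=250.0, duration=20.0, seed=s)
        spec = power_spectrum(tr, nperseg=len(tr))
        acc = spec.C_tilde if acc is None else acc + spec.C_tilde
        f = spec.f
    from hairbundle.oscillation import Spectrum, smooth_spectrum

    mean_psd = acc / 50.0
    # 1-Hz smoothing removes the residual per-bin scatter of the 50-seed mean
    sm = smooth_spectrum(Spectrum(f=f, C_tilde=mean_psd, df=float(f[1] - f[0])), 1.0)
    band = (f >= f0 / 4.0) & (f <= 4.0 * f0)
    target = double_lorentzian_psd(f[band], A, f0, Q)
    assert np.trapezoid(mean_psd[band], f[band]) == pytest.approx(
        np.trapezoid(target, f[band]), rel=0.05
    )
    assert np.median(np.abs(sm.C_tilde[band] / target - 1.0)) < 0.05


# ---------------------------------------------------------------------------
# bimodal positions


def test_bimodal_mixture_mean_and_labels():
    x = gen_bimodal_positions(0.5, -30.0, 30.0, 8.0, 8.0, 200_000, seed=0)
    assert np.mean(x) == pytest.approx(0.0, abs=0.3)
    with pytest.raises(ValueError, match="mu_o"):
        gen_bimodal_positions(0.5, 30.0, -30.0, 8.0, 8.0, 100)


# ---------------------------------------------------------------------------
# RC steps


def test_rc_step_closed_form():
    df = gen_rc_step(10.0, 23.0, 1.0)
    t = df.t_s.to_numpy()
    U = df.U_mV.to_numpy()
    assert U[-1] == pytest.approx(10.0, rel=1e-3)  # steady state I*R
    # value at t = tau = 230 us
    i = np.argmin(np.abs(t - 230e-6))
    assert U[i] == pytest.approx(10.0 * (1 - np.exp(-1)), rel=1e-3)


def test_rc_step_zero_current():
    df = gen_rc_step(10.0, 23.0, 0.0)
    assert np.all(df.U_mV.to_numpy() == 0.0)


# ---------------------------------------------------------------------------
# ensembles


def test_ensemble_noiseless_recovers_configured_line():
    m = ObservableModel(4.6, -9.6, 1.0)  # r2 = 1: zero residual variance
    cfg = EnsembleGenConfig(
        currents=tuple(np.linspace(-4.5, 10.0, 30)), n_cells=30,
        models={"dX0_nm": m},
    )
    tab = gen_ensemble(cfg, seed=0)
    d = hb.ensemble_deltas(tab)
    reg = hb.regress(d.I_uA, d.dX0_nm)
    assert reg.slope == pytest.approx(4.6, rel=1e-12)
    assert reg.intercept == pytest.approx(-9.6, rel=1e-12)
    assert reg.r_squared == pytest.approx(1.0, abs=1e-12)


def test_ensemble_slope_recovery_with_matched_residuals():
    """R^2-matched residuals leave the mean recovered slope within 5% of the
    configured value (200 seeds)."""
    m = ObservableModel(-2.3, 5.0, 0.74)
    cfg = EnsembleGenConfig(
        currents=tuple(np.linspace(-4.5, 10.0, 34)), n_cells=34,
        models={"dF_G_pN": m},
    )
    slopes = []
    for s in range(200):
        d = hb.ensemble_deltas(gen_ensemble(cfg, seed=s))
        slopes.append(hb.regress(d.I_uA, d.dF_G_pN).slope)
    assert np.mean(slopes) == pytest.approx(-2.3, rel=0.05)


def test_ensemble_weak_state_rows_are_zero():
    stm = StateTransitionModel(I_down=-5.0, hyst=2.3)
    cfg = EnsembleGenConfig(currents=(-8.0, -6.0, 3.0), n_cells=6)
    tab = gen_ensemble(cfg, stm, seed=1)
    weak = tab[tab.state == "weak"]
    assert len(weak) == 4  # currents -8 and -6 for two cells each
    assert np.all(weak.F_G_pN.to_numpy() == 0.0)
    assert np.all(weak.d_nm.to_numpy() == 0.0)


def test_ensemble_config_validation():
    with pytest.raises(ValueError):
        ObservableModel(1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        ObservableModel(1.0, 0.0, 1.2)


# ---------------------------------------------------------------------------
# kinetics generator


def test_step_kinetics_shapes_and_plateaus():
    df = gen_step_kinetics(noise_sd=0.0)
    t = df.t_s.to_numpy()
    x = df.Xbar_nm.to_numpy()
    assert x[t < 1.0].std() == 0.0  # flat baseline
    # ON plateau approached: at t=5 s (8 tau) the step is complete
    assert x[np.argmin(np.abs(t - 5.0)) - 1] == pytest.approx(-120.0, rel=1e-3)


def test_zero_step_kinetics_flagged():
    df = gen_step_kinetics(X_step=0.0, phi_step=0.0, noise_sd=0.0)
    with pytest.raises(ValueError, match="undefined"):
        hb.t10_90(df.t_s, df.Xbar_nm)


# ---------------------------------------------------------------------------
# determinism


@pytest.mark.parametrize("maker", [
    lambda seed: gen_fd_step_protocol(
        BISTABLE, FiberParams(0.5), np.linspace(-200, 200, 12), noise_sd=2.0, seed=seed),
    lambda seed: gen_oscillation_trace(2.5, 8.0, 2.0, 250.0, 20.0, seed=seed),
    lambda seed: gen_ensemble(EnsembleGenConfig(), StateTransitionModel(), seed=seed),
    lambda seed: gen_rc_step(10.0, 23.0, 1.0, noise_sd_mV=0.2, seed=seed),
    lambda seed: gen_step_kinetics(noise_sd=0.3, seed=seed),
], ids=["fd", "oscillation", "ensemble", "rc", "kinetics"])
def test_generators_are_seed_deterministic(maker):
    a, b = maker(42), maker(42)
    pd.testing.assert_frame_equal(a, b)
    c = maker(43)
    assert not a.equals(c)
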