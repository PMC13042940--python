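"""Synthetic hair-bundle data generators.

Every input the analysis pipeline consumes can be generated here:

* quasi-static force-displacement relations measured through an elastic
  stimulus fiber (step protocol, hysteretic branch continuation in the
  bistable negative-stiffness regime),
* dynamic force-displacement cycles under triangular stimulation, with
  gating friction arising from a finite channel-activation time,
* spontaneous-oscillation traces with a prescribed double-Lorentzian
  spectrum and bimodal position histograms,
* transepithelial RC step responses,
* per-cell ensembles following configured current-dependence regressions
  with a hysteretic strong/weak gating-state transition, and
* paired kinetics traces (mean position and maximal friction force) with
  exponential 10-90% relaxations.

All generators are seed-deterministic: the same seed produces bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    BundleGeometry,
    GatingSpringParams,
    fd_force,
    fd_slope,
    open_probability,
)

__all__ = [
    "FiberParams",
    "DynamicBundleParams",
    "StateTransitionModel",
    "ObservableModel",
    "EnsembleGenConfig",
    "DivergenceError",
    "gen_fd_step_protocol",
    "find_equilibria",
    "simulate_cycle",
    "gen_oscillation_trace",
    "gen_bimodal_positions",
    "gen_rc_step",
    "gen_ensemble",
    "gen_phi_ramp",
    "gen_step_kinetics",
]


class DivergenceError(RuntimeError):
    """Raised when the cycle integrator leaves the physical range."""


@dataclass(frozen=True)
class FiberParams:
    """Stimulus fiber: stiffness k_F (pN/nm); the applied force is
    F = k_F * (Delta - X) for base command Delta and bundle position X."""

    k_F: float = 0.5

    def __post_init__(self) -> None:
        if self.k_F <= 0:
            raise ValueError(f"k_F must be > 0, got {self.k_F}")


@dataclass(frozen=True)
class DynamicBundleParams:
    """Bundle parameters for dynamic simulations.

    params : quasi-static gating-spring parameters.
    xi : effective drag coefficient of bundle + fiber tip, pN*s/nm.
    tau_a : channel activation time constant, s (0 = instantaneous gating).
    noise_sd : Gaussian measurement noise added to recorded X (nm) and F (pN).
    """

    params: GatingSpringParams
    xi: float = 1e-4
    tau_a: float = 1e-3
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError(f"xi must be > 0, got {self.xi}")
        if self.tau_a < 0:
            raise ValueError(f"tau_a must be >= 0, got {self.tau_a}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


# ---------------------------------------------------------------------------
# quasi-static step protocol


def find_equilibria(
    Delta: float,
    p: GatingSpringParams,
    k_F: float,
    span: float | None = None,
    n_scan: int = 8001,
) -> tuple[np.ndarray, np.ndarray]:
    """All roots of the force balance k_F*(Delta - X) = F(X).

    Returns (roots, stable) where ``stable`` marks roots at which the total
    restoring stiffness k_F + dF/dX is positive (mechanically stable
    equilibria of the overdamped dynamics).
    """
    lin_x = (k_F * Delta - p.F_null) / (k_F + p.K)
    if span is None:
        span = p.F_G / (k_F + p.K) + 12.0 * p.delta + 50.0
    lo = min(lin_x - span, p.X_0 - span)
    hi = max(lin_x + span, p.X_0 + span)
    grid = np.linspace(lo, hi, n_scan)

    def g(x: float | np.ndarray):
        return k_F * (Delta - x) - fd_force(x, p)

    vals = g(grid)
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    roots = np.array(sorted(set(np.round(roots, 12))))
    if roots.size == 0:  # impossible for K, k_F > 0; guarded anyway
        raise RuntimeError(f"no force-balance root found for Delta={Delta}")
    stable = (k_F + fd_slope(roots, p)) > 0
    stable = np.atleast_1d(stable)
    return roots, stable


def gen_fd_step_protocol(
    p: GatingSpringParams,
    fiber: FiberParams,
    schedule: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    cell_id: str = "sim",
    I_uA: float = 0.0,
) -> pd.DataFrame:
    """Quasi-static force-displacement relation from a step protocol.

    For each base command Delta in ``schedule`` the steady bundle position
    solves k_F*(Delta - X) = F(X).  In the bistable (negative-stiffness)
    regime the branch is selected by continuation: among the stable roots,
    the one nearest the bundle position reached at the previous step (no
    displacement-clamp feedback, so jumps are hysteretic).  Records
    (X, F = k_F*(Delta - X)) with optional Gaussian measurement noise on
    both coordinates.

    Returns a DataFrame with columns X_nm, F_pN (attrs carry metadata).
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be nonempty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x_prev = _continuation_root(0.0, p, fiber.k_F, x_prev=0.0)
    X, F = [], []
    for Delta in schedule:
        x_prev = _continuation_root(float(Delta), p, fiber.k_F, x_prev=x_prev)
        X.append(x_prev)
        F.append(fiber.k_F * (Delta - x_prev))
    X = np.asarray(X)
    F = np.asarray(F)
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)
        F = F + rng.normal(0.0, noise_sd, F.shape)
    df = pd.DataFrame({"X_nm": X, "F_pN": F})
    df.attrs.update({"cell_id": cell_id, "I_uA": I_uA, "k_F_pN_per_nm": fiber.k_F})
    return df


def _continuation_root(
    Delta: float, p: GatingSpringParams, k_F: float, x_prev: float
) -> float:
    roots, stable = find_equilibria(Delta, p, k_F)
    stable_roots = roots[stable]
    if stable_roots.size == 0:  # only marginally stable roots; take nearest
        stable_roots = roots
    return float(stable_roots[np.argmin(np.abs(stable_roots - x_prev))])


# ---------------------------------------------------------------------------
# dynamic cycles


def _triangle(phase: np.ndarray) -> np.ndarray:
    """Symmetric triangle of unit amplitude, ascending through 0 at phase 0."""
    ph = np.mod(phase + 0.25, 1.0)
    return 4.0 * np.abs(ph - 0.5) - 1.0


def simulate_cycle(
    dp: DynamicBundleParams,
    fiber: FiberParams,
    freq: float = 40.0,
    peak_to_peak: float = 600.0,
    n_cycles: int = 10,
    dt: float = 1e-5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bundle response to a symmetric triangular waveform of the fiber base.

    Integrates the overdamped dynamics

        xi * dX/dt  = k_F*(Delta(t) - X) - (K*X - F_G*P_o + F_null)
        tau_a * dP_o/dt = P_inf(X) - P_o

    with a fixed-step explicit scheme (Euler for X; exact exponential
    relaxation for P_o).  In the quasi-static limit (xi -> 0, tau_a -> 0)
    the applied force k_F*(Delta - X) reproduces the gating-spring relation
    F(X).  The first stimulus cycle is discarded as a transient.

    Returns a DataFrame with columns t_s, Delta_nm, X_nm, F_pN.
    """
    p = dp.params
    if dt <= 0 or dt >= 1.0 / (4.0 * freq):
        raise ValueError("dt must be positive and well below the stimulus period")
    rng = np.random.default_rng(seed)
    n_per = int(round(1.0 / (freq * dt)))
    n_tot = n_per * (n_cycles + 1)
    amp = peak_to_peak / 2.0
    t = np.arange(n_tot) * dt
    Delta = amp * _triangle(freq * t)

    # start on the quasi-static branch at Delta(0)
    x = _continuation_root(float(Delta[0]), p, fiber.k_F, x_prev=0.0)
    po = float(open_probability(x, p.X_0, p.delta))
    X = np.empty(n_tot)
    decay = math.exp(-dt / dp.tau_a) if dp.tau_a > 0 else 0.0
    limit = 10.0 * max(peak_to_peak, 1.0)
    K, F_G, X_0, delta, F_null = p.K, p.F_G, p.X_0, p.delta, p.F_null
    k_F, xi = fiber.k_F, dp.xi
    for i in range(n_tot):
        X[i] = x
        z = (x - X_0) / delta
        if z < -40.0:
            p_inf = 0.0
        elif z > 40.0:
            p_inf = 1.0
        else:
            p_inf = 1.0 / (1.0 + math.exp(-z))
        po = p_inf + (po - p_inf) * decay
        force = k_F * (Delta[i] - x) - (K * x - F_G * po + F_null)
        x = x + dt * force / xi
        if abs(x) > limit:
            raise DivergenceError(
                f"integration diverged (|X| > {limit:.3g} nm) at t={t[i]:.6g} s; "
                f"dt={dt:g} s is too coarse for xi={xi:g}"
            )
    # discard the first (transient) cycle
    sl = slice(n_per, n_tot)
    t_out = t[sl] - t[n_per]
    X_out = X[sl].copy()
    D_out = Delta[sl].copy()
    if dp.noise_sd > 0:
        X_out = X_out + rng.normal(0.0, dp.noise_sd, X_out.shape)
    F_out = fiber.k_F * (D_out - X_out)
    df = pd.DataFrame({"t_s": t_out, "Delta_nm": D_out, "X_nm": X_out, "F_pN": F_out})
    df.attrs.update(
        {
            "freq_Hz": freq,
            "peak_to_peak_nm": peak_to_peak,
            "n_cycles": n_cycles,
            "dt_s": dt,
            "k_F_pN_per_nm": fiber.k_F,
        }
    )
    return df


# ---------------------------------------------------------------------------
# spontaneous oscillations


def double_lorentzian_psd(f, A: float, f0: float, Q: float):
    """Two-sided PSD model: A/[(f0/2Q)^2 + (f-f0)^2] + A/[(f0/2Q)^2 + (f+f0)^2].

    Its integral over the full frequency line equals 4*pi*A*Q/f0.
    """
    f = np.asarray(f, dtype=float)
    w2 = (f0 / (2.0 * Q)) ** 2
    out = A / (w2 + (f - f0) ** 2) + A / (w2 + (f + f0) ** 2)
    return float(out) if out.ndim == 0 else out


def gen_oscillation_trace(
    A: float,
    f0: float,
    Q: float,
    fs: float = 250.0,
    duration: float = 25.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Surrogate spontaneous-oscillation trace with a double-Lorentzian PSD.

    Spectral synthesis: independent complex Gaussian Fourier coefficients
    with variance proportional to the target two-sided density are inverse
    transformed to a real trace.  The expected sample variance is
    4*pi*A*Q/f0 (the squared RMS amplitude of the oscillation).

    Returns a DataFrame with columns t_s, X_nm.
    """
    if A < 0:
        raise ValueError("A must be >= 0")
    if fs <= 4.0 * f0:
        raise ValueError(f"fs={fs} Hz too low: need fs > 4*f0 = {4 * f0} Hz (aliasing)")
    if duration * f0 < 100:
        raise ValueError("duration*f0 must be >= 100 for a resolved spectrum")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if A == 0.0:
        return pd.DataFrame({"t_s": t, "X_nm": np.zeros(n)})
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = double_lorentzian_psd(freqs, A, f0, Q)
    # E|X_k|^2 = n*fs*C(f_k) reproduces the two-sided density after irfft
    scale = np.sqrt(n * fs * psd / 2.0)
    coef = scale * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coef[0] = math.sqrt(n * fs * psd[0]) * rng.standard_normal()
    if n % 2 == 0:
        coef[-1] = math.sqrt(n * fs * psd[-1]) * rng.standard_normal()
    x = np.fft.irfft(coef, n=n)
    df = pd.DataFrame({"t_s": t, "X_nm": x})
    df.attrs.update({"fs_Hz": fs, "A_nm2_Hz": A, "f0_Hz": f0, "Q": Q})
    return df


def gen_bimodal_positions(
    w: float,
    mu_c: float,
    mu_o: float,
    sd_c: float,
    sd_o: float,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Positions drawn from a two-Gaussian mixture.

    ``w`` is the weight of the open mode (larger mean ``mu_o``); ``mu_c`` is
    the closed-mode mean.  Emulates the bimodal position histogram of a
    relaxation-oscillating bundle whose open-mode weight is the steady-state
    open probability.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if mu_o <= mu_c:
        raise ValueError(
            f"open-mode mean mu_o={mu_o} must exceed closed-mode mean mu_c={mu_c}"
        )
    rng = np.random.default_rng(seed)
    is_open = rng.random(n) < w
    x = np.where(
        is_open,
        rng.normal(mu_o, sd_o, n),
        rng.normal(mu_c, sd_c, n),
    )
    return x


# ---------------------------------------------------------------------------
# transepithelial RC step


def gen_rc_step(
    R_kOhm: float,
    C_nF: float,
    I_step_uA: float,
    fs_Hz: float = 2e6,
    duration_s: float = 2e-3,
    noise_sd_mV: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Transepithelial potential response to a current step.

    U(t) = I*R*(1 - exp(-t/(R*C))) + noise; with R in kOhm and C in nF the
    time constant R*C is in microseconds.  Returns columns t_s, U_mV.
    """
    if R_kOhm <= 0 or C_nF <= 0:
        raise ValueError("R and C must be > 0")
    rng = np.random.default_rng(seed)
    tau_s = R_kOhm * C_nF * 1e-6
    t = np.arange(int(round(duration_s * fs_Hz))) / fs_Hz
    U = I_step_uA * R_kOhm * (1.0 - np.exp(-t / tau_s))
    if noise_sd_mV > 0:
        U = U + rng.normal(0.0, noise_sd_mV, U.shape)
    df = pd.DataFrame({"t_s": t, "U_mV": U})
    df.attrs.update({"R_kOhm": R_kOhm, "C_nF": C_nF, "I_step_uA": I_step_uA})
    return df


# ---------------------------------------------------------------------------
# ensembles and state transition


@dataclass(frozen=True)
class StateTransitionModel:
    """Hysteretic transition between strong- and weak-gating states.

    The gating force drops to zero (weak state) when the control current
    falls below ``I_down`` on a descending ramp; on an ascending ramp the
    strong state is only recovered above ``I_down + hyst``.
    """

    F_G0: float = 17.0  # control gating force, pN
    slope_FG: float = -2.3  # dF_G/dI, pN/uA
    I_down: float = -5.0  # descending-ramp transition current, uA
    hyst: float = 2.3  # hysteresis shift, uA
    weak_F_G: float = 0.0

    def __post_init__(self) -> None:
        if self.hyst < 0:
            raise ValueError("hyst must be >= 0")
        if self.weak_F_G != 0.0:
            raise ValueError("weak_F_G must be 0 (undetectable gating)")

    def threshold(self, branch: str) -> float:
        if branch == "descending":
            return self.I_down
        if branch == "ascending":
            return self.I_down + self.hyst
        raise ValueError(f"branch must be 'descending' or 'ascending', got {branch!r}")


@dataclass(frozen=True)
class ObservableModel:
    """Linear current-dependence of one observable: value = slope*I + intercept,
    with Gaussian residuals scaled so the expected OLS R^2 matches ``r2``."""

    slope: float
    intercept: float
    r2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2 <= 1.0):
            raise ValueError(f"r2 must be in (0, 1], got {self.r2}")

    def residual_sd(self, currents: np.ndarray) -> float:
        if self.r2 == 1.0:
            return 0.0
        var_i = float(np.var(np.asarray(currents, dtype=float)))
        return abs(self.slope) * math.sqrt(var_i * (1.0 - self.r2) / self.r2)


def default_observable_models() -> dict[str, ObservableModel]:
    """Ensemble regression models for the current dependence of the
    condition deltas (slope, intercept, R^2 per observable)."""
    return {
        "dX0_nm": ObservableModel(4.6, -9.6, 0.75),
        "dK_pN_per_nm": ObservableModel(-0.01, 0.04, 0.33),
        "dF_G_pN": ObservableModel(-2.3, 5.0, 0.74),
        "rel_dd_pct": ObservableModel(-11.0, 22.0, 0.78),
    }


@dataclass(frozen=True)
class EnsembleGenConfig:
    """Configuration of the per-cell ensemble generator."""

    currents: tuple[float, ...] = tuple(np.linspace(-5.0, 10.0, 34))
    n_cells: int = 34
    models: dict[str, ObservableModel] = field(default_factory=default_observable_models)
    K0: float = 0.85  # control stiffness, pN/nm
    F_G0: float = 17.0  # control gating force, pN
    X00: float = -2.0  # control set point, nm
    d0: float = 3.5  # control gating swing, nm (gamma*F_G0/(K0-K_SP))
    branch: str = "descending"

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")
        if len(self.currents) == 0:
            raise ValueError("currents must be nonempty")


def gen_ensemble(
    cfg: EnsembleGenConfig,
    stm: StateTransitionModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell ensemble with configured current-dependence regressions.

    Each cell contributes a control row (I = 0) with the control parameter
    values and one row at its assigned current.  For currents above the
    state-transition threshold, every observable delta is drawn from its
    regression line plus Gaussian residuals whose variance is matched to
    the configured R^2; below the threshold the cell is in the weak state
    and F_G = d = 0 identically.

    Columns: cell_id, I_uA, K_pN_per_nm, F_G_pN, X0_nm, d_nm, state.
    """
    stm = stm or StateTransitionModel(I_down=-math.inf)  # no transition by default
    rng = np.random.default_rng(seed)
    currents = np.asarray(cfg.currents, dtype=float)
    rows = []
    thr = stm.threshold(cfg.branch)
    sds = {k: m.residual_sd(currents) for k, m in cfg.models.items()}
    for c in range(cfg.n_cells):
        cid = f"cell{c:03d}"
        I = float(currents[c % len(currents)])
        rows.append(
            dict(cell_id=cid, I_uA=0.0, K_pN_per_nm=cfg.K0, F_G_pN=cfg.F_G0,
                 X0_nm=cfg.X00, d_nm=cfg.d0, state="strong")
        )
        draws = {
            k: m.slope * I + m.intercept + rng.normal(0.0, sds[k])
            for k, m in cfg.models.items()
        }
        if I < thr:
            rows.append(
                dict(cell_id=cid, I_uA=I,
                     K_pN_per_nm=cfg.K0 + draws.get("dK_pN_per_nm", 0.0),
                     F_G_pN=0.0, X0_nm=math.nan, d_nm=0.0, state="weak")
            )
        else:
            # each observable is drawn from its own regression line; the
            # draws are recorded as-is so OLS on the output is unbiased
            rows.append(
                dict(cell_id=cid, I_uA=I,
                     K_pN_per_nm=cfg.K0 + draws.get("dK_pN_per_nm", 0.0),
                     F_G_pN=cfg.F_G0 + draws.get("dF_G_pN", 0.0),
                     X0_nm=cfg.X00 + draws.get("dX0_nm", 0.0),
                     d_nm=cfg.d0 * (1.0 + draws.get("rel_dd_pct", 0.0) / 100.0),
                     state="strong")
            )
    return pd.DataFrame(rows)


def gen_phi_ramp(
    stm: StateTransitionModel,
    I_start: float = 0.0,
    I_min: float = -9.0,
    n_points: int = 120,
    phi_strong: float = 6.0,
    phi_rise: float = 0.35,
    phi_weak: float = 0.5,
    drop_width: float = 0.25,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Maximal-friction-force branches along a descending-then-ascending
    current ramp with a hysteretic drop.

    On each branch, phi_MAX rises gently and saturates as the current grows
    more negative (phi_strong - phi_rise*I at I<0) and collapses to the
    weak-state plateau ``phi_weak`` through a logistic drop of width
    ``drop_width`` centred on the branch's transition current.

    Returns a DataFrame with columns branch, I_uA, phi_max_pN ordered in
    ramp time (descending branch first).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for branch in ("descending", "ascending"):
        I = np.linspace(I_start, I_min, n_points)
        if branch == "ascending":
            I = I[::-1]
        thr = stm.threshold(branch)
        strong_level = phi_strong - phi_rise * np.minimum(I, 0.0)
        occ = 1.0 / (1.0 + np.exp(-(I - thr) / drop_width))  # strong-state occupancy
        phi = phi_weak + (strong_level - phi_weak) * occ
        if noise_sd > 0:
            phi = phi + rng.normal(0.0, noise_sd, phi.shape)
        for i, ph in zip(I, phi):
            rows.append(dict(branch=branch, I_uA=float(i), phi_max_pN=float(ph)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transition kinetics


def gen_step_kinetics(
    tau_on_X: float = 0.5,
    tau_off_X: float = 0.1,
    tau_on_phi: float = 0.18,
    tau_off_phi: float = 0.4,
    t_on: float = 1.0,
    t_off: float = 5.0,
    duration: float = 8.0,
    fs: float = 50.0,
    X_base: float = -20.0,
    X_step: float = -100.0,
    phi_base: float = 6.0,
    phi_step: float = -5.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired time courses of the cycle-averaged position and the maximal
    friction force across a current step.

    Both observables relax exponentially toward their ON plateau after
    ``t_on`` (time constants tau_on_*) and back to baseline after ``t_off``
    (tau_off_*).  Returns columns t_s, Xbar_nm, phi_max_pN.
    """
    for tau in (tau_on_X, tau_off_X, tau_on_phi, tau_off_phi):
        if tau <= 0:
            raise ValueError("time constants must be positive")
    if not (0 < t_on < t_off < duration):
        raise ValueError("need 0 < t_on < t_off < duration")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * fs))) / fs

    def relax(base: float, step: float, tau_on: float, tau_off: float) -> np.ndarray:
        y = np.full_like(t, base)
        on = (t >= t_on) & (t < t_off)
        y[on] = base + step * (1.0 - np.exp(-(t[on] - t_on) / tau_on))
        y_off0 = base + step * (1.0 - math.exp(-(t_off - t_on) / tau_on))
        off = t >= t_off
        y[off] = base + (y_off0 - base) * np.exp(-(t[off] - t_off) / tau_off)
        return y

    X = relax(X_base, X_step, tau_on_X, tau_off_X)
    phi = relax(phi_base, phi_step, tau_on_phi, tau_off_phi)
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)
        phi = phi + rng.normal(0.0, noise_sd, phi.shape)
    df = pd.DataFrame({"t_s": t, "Xbar_nm": X, "phi_max_pN": phi})
    df.attrs.update({"t_on_s": t_on, "t_off_s": t_off})
    return df
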