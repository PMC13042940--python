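"""Transepithelial RC circuit of the two-compartment preparation.

A current step I injected across the sensory epithelium charges it like a
single RC element: the endolymphatic potential follows
U(t) = U_inf * (1 - exp(-t/tau)) with U_inf = I*R and tau = R*C.  With R in
kOhm and C in nF the time constant is in microseconds.  Fitting the
decaying residual U_inf - U(t) is equivalent to fitting a pure exponential
decay of amplitude A = U_inf.  The steady potential converts applied
current to endolymphatic potential, U = I*R.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "EpitheliumParams",
    "ExponentialFit",
    "fit_exponential",
    "derive_rc",
    "current_to_potential",
]


@dataclass(frozen=True)
class EpitheliumParams:
    """Transepithelial resistance R (kOhm), capacitance C (nF) and time
    constant tau = R*C (µs; kOhm*nF = µs)."""

    R_kOhm: float
    C_nF: float

    def __post_init__(self) -> None:
        if self.R_kOhm <= 0 or self.C_nF <= 0:
            raise ValueError("R and C must be > 0")

    @property
    def tau_us(self) -> float:
        return self.R_kOhm * self.C_nF

    def to_json_dict(self) -> dict:
        return {"R_kOhm": self.R_kOhm, "C_nF": self.C_nF, "tau_us": self.tau_us}


@dataclass(frozen=True)
class ExponentialFit:
    """Exponential step-response fit: amplitude A (mV, the steady-state
    potential) and time constant tau (µs).  ``flat`` marks a featureless
    trace for which tau is undefined."""

    A_mV: float
    tau_us: float
    flat: bool = False

    def summary(self) -> str:
        if self.flat:
            return "Exponential step fit: flat trace, A = 0, tau undefined"
        return (
            "Exponential step-response fit\n"
            f"A   = {self.A_mV:.4g} mV\n"
            f"tau = {self.tau_us:.4g} us"
        )


def fit_exponential(ts: pd.DataFrame) -> ExponentialFit:
    """Fit U(t) = A*(1 - exp(-t/tau)) to a step response.

    ``ts`` holds columns t_s (seconds) and U_mV.  The approach to steady
    state is fitted by least squares; equivalently the residual
    U_inf - U(t) decays as a pure exponential of amplitude A.  Returns the
    amplitude in mV and the time constant in microseconds.  A constant
    trace yields A = 0 with tau flagged undefined; a non-monotone trace
    triggers a warning but is still fitted.
    """
    t = ts["t_s"].to_numpy().astype(float)
    U = ts["U_mV"].to_numpy().astype(float)
    if t.size < 5:
        raise ValueError("need >= 5 samples")
    t = t - t[0]
    span = float(U.max() - U.min())
    scale = max(abs(U).max(), 1e-12)
    if span < 1e-9 * scale or span == 0.0:
        return ExponentialFit(A_mV=0.0, tau_us=math.nan, flat=True)
    # initial guesses: steady level from the trace tail, tau from the 63% crossing
    A0 = float(np.mean(U[-max(t.size // 10, 1):]))
    if A0 == 0.0:
        A0 = float(U[np.argmax(np.abs(U))])
    target = 0.632 * A0
    crossed = np.flatnonzero(
        (U[:-1] - target) * (U[1:] - target) <= 0 if A0 > 0 else (target - U[:-1]) * (target - U[1:]) <= 0
    )
    tau0 = float(t[crossed[0] + 1]) if crossed.size else float(t[-1] / 3.0)
    tau0 = max(tau0, float(t[1]))
    smoothed = np.convolve(U, np.ones(5) / 5.0, mode="valid")
    monotone = np.all(np.diff(smoothed) >= -0.02 * abs(span)) or np.all(
        np.diff(smoothed) <= 0.02 * abs(span)
    )
    if not monotone:
        warnings.warn("step response is not monotone; exponential fit may be biased")

    def model(tt, A, tau):
        return A * (1.0 - np.exp(-tt / tau))

    popt, _ = curve_fit(model, t, U, p0=[A0, tau0], maxfev=10000)
    A, tau_s = float(popt[0]), abs(float(popt[1]))
    return ExponentialFit(A_mV=A, tau_us=tau_s * 1e6)


def derive_rc(A_mV: float, tau_us: float, I_step_uA: float) -> EpitheliumParams:
    """R = A/I (kOhm) and C = tau/R (nF) from the step-fit amplitude and
    time constant.  Polarity-invariant: reversing both I and A leaves R
    unchanged."""
    if I_step_uA == 0:
        raise ZeroDivisionError("I_step must be nonzero")
    R = A_mV / I_step_uA
    if R <= 0:
        raise ValueError(
            f"inconsistent polarity: A={A_mV} mV for I={I_step_uA} uA gives R <= 0"
        )
    return EpitheliumParams(R_kOhm=R, C_nF=tau_us / R)


def current_to_potential(I_uA, R_kOhm: float):
    """Steady endolymphatic potential U = I*R (mV for µA and kOhm)."""
    I_uA = np.asarray(I_uA, dtype=float)
    if not np.all(np.isfinite(I_uA)) or not np.isfinite(R_kOhm):
        raise ValueError("inputs must be finite")
    out = I_uA * R_kOhm
    return float(out) if out.ndim == 0 else out
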