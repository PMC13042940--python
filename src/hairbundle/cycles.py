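"""Force-displacement cycle analysis under triangular stimulation.

A periodic triangular movement of the stimulus-fiber base drives the
bundle back and forth; the applied force F = k_F*(Delta - X) traced
against the bundle position X over one period forms a dissipative cycle.
The half-height of the cycle at position X,

    phi(X) = [F_plus(X) - F_minus(X)] / 2,

is the average friction force impeding the motion there (F_plus/F_minus:
force on the positive-/negative-velocity half-cycles).  Delayed gating of
the transduction channels (finite activation time) adds a peaked component
to phi on top of the flat viscous background; the peak value phi_MAX is a
reporter for the magnitude of the gating force, and its abscissa
identifies the set-point deflection X_0.  The shift DeltaX between the
positions of maximal bundle speed on the two half-cycles estimates the
channel activation time tau = DeltaX / (2*V_MAX).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ForceCycle",
    "CycleMetrics",
    "average_cycles",
    "friction_profile",
    "inversion_point",
    "activation_time",
    "mean_position",
    "cycle_metrics",
]

# outermost fraction of the X-range excluded from friction statistics
# (fiber-reversal artifacts at the turning points)
_EDGE_FRACTION = 0.05


@dataclass(frozen=True)
class ForceCycle:
    """Averaged force-displacement cycle on a common displacement grid.

    X : common grid, nm.  F_plus / F_minus : average force on the positive-
    and negative-velocity half-cycles, pN (NaN where a half-cycle has no
    support).  freq / peak_to_peak describe the stimulus; n_averaged is the
    number of stimulus periods averaged.
    """

    X: np.ndarray
    F_plus: np.ndarray
    F_minus: np.ndarray
    freq: float
    peak_to_peak: float
    n_averaged: int

    def __post_init__(self) -> None:
        if not (self.X.shape == self.F_plus.shape == self.F_minus.shape):
            raise ValueError("X, F_plus, F_minus must share one grid")

    @property
    def coverage(self) -> float:
        """Fraction of the stimulus peak-to-peak amplitude spanned in X."""
        return float(np.ptp(self.X)) / self.peak_to_peak


@dataclass(frozen=True)
class CycleMetrics:
    """Scalar metrics of one averaged cycle."""

    phi_max_pN: float
    X0_nm: float
    F0_pN: float
    Xbar_nm: float
    tau_act_s: float
    flat_phi: bool
    sign_flag: bool  # True when phi < 0 over a substantial range (circulation
    # opposite to the dissipative convention)


def average_cycles(raw: pd.DataFrame, freq: float, n_cycles: int | None = None) -> ForceCycle:
    """Fold a raw triangular-stimulation record into one averaged cycle.

    The record must hold columns t_s, Delta_nm, X_nm, F_pN with uniform
    sampling and a whole number of samples per stimulus period.  Samples
    are split by the sign of dDelta/dt, phase-averaged over periods, and
    binned onto a common X grid (bin width = X span / 100) by averaging;
    bin centres are refined to the mean X within each bin.
    """
    t = raw["t_s"].to_numpy()
    Delta = raw["Delta_nm"].to_numpy()
    X = raw["X_nm"].to_numpy()
    F = raw["F_pN"].to_numpy()
    dt = float(np.median(np.diff(t)))
    n_per = int(round(1.0 / (freq * dt)))
    n_avail = len(t) // n_per
    if n_cycles is None:
        n_cycles = n_avail
    if n_avail < n_cycles or n_cycles < 1:
        raise ValueError(
            f"record holds {n_avail} whole cycles, {n_cycles} requested"
        )
    n_use = n_cycles * n_per
    X = X[:n_use]
    F = F[:n_use]
    Delta = Delta[:n_use]
    # half-cycle membership from the sign of the base velocity
    dDelta = np.gradient(Delta, dt)
    up = dDelta > 0

    lo, hi = float(X.min()), float(X.max())
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate record: X has no span")
    n_bins = 100
    edges = np.linspace(lo, hi, n_bins + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])

    def bin_mean(mask: np.ndarray) -> np.ndarray:
        idx = np.clip(np.digitize(X[mask], edges) - 1, 0, n_bins - 1)
        s = np.bincount(idx, weights=F[mask], minlength=n_bins)
        c = np.bincount(idx, minlength=n_bins)
        out = np.full(n_bins, np.nan)
        nz = c > 0
        out[nz] = s[nz] / c[nz]
        return out

    F_plus = bin_mean(up)
    F_minus = bin_mean(~up)
    pkpk = raw.attrs.get("peak_to_peak_nm", span)
    return ForceCycle(
        X=grid, F_plus=F_plus, F_minus=F_minus,
        freq=freq, peak_to_peak=pkpk, n_averaged=n_cycles,
    )


def _interior_mask(c: ForceCycle) -> np.ndarray:
    span = np.ptp(c.X)
    lo = c.X.min() + _EDGE_FRACTION * span
    hi = c.X.max() - _EDGE_FRACTION * span
    return (c.X >= lo) & (c.X <= hi)


def friction_profile(c: ForceCycle) -> tuple[np.ndarray, float, float | None, bool]:
    """Friction profile phi(X) = [F_plus - F_minus]/2 and its maximum.

    Returns (phi, phi_max, X_at_max, flat).  The outermost 5% of the X
    range is excluded from the max statistics (turning-point artifacts).
    ``X_at_max`` is None when the profile is flat (featureless), in which
    case phi_max is the interior median level.
    """
    phi = 0.5 * (c.F_plus - c.F_minus)
    mask = _interior_mask(c) & np.isfinite(phi)
    if not np.any(mask):
        raise ValueError("no overlapping X support between half-cycles")
    interior = phi[mask]
    spread = float(np.nanmax(interior) - np.nanmin(interior))
    level = float(np.nanmedian(interior))
    flat = spread < 0.05 * max(abs(level), 1e-12)
    if flat:
        return phi, level, None, True
    i = int(np.nanargmax(np.where(mask, phi, -np.inf)))
    return phi, float(phi[i]), float(c.X[i]), False


def inversion_point(c: ForceCycle) -> tuple[float, float, bool]:
    """Point of inversion symmetry (X_0, F_0) of the cycle.

    X_0 is the abscissa of the friction-profile maximum; F_0 the mid force
    [F_plus(X_0) + F_minus(X_0)]/2 there.  For a flat (featureless) profile
    the grid midpoint is returned with ``flat=True``.
    """
    phi, phi_max, x_at, flat = friction_profile(c)
    if flat or x_at is None:
        x0 = float(0.5 * (c.X.min() + c.X.max()))
        flat = True
    else:
        x0 = x_at
    i = int(np.argmin(np.abs(c.X - x0)))
    # nearest grid point with both half-cycles defined
    ok = np.isfinite(c.F_plus) & np.isfinite(c.F_minus)
    if not ok[i]:
        i = int(np.flatnonzero(ok)[np.argmin(np.abs(c.X[ok] - x0))])
    f0 = 0.5 * (c.F_plus[i] + c.F_minus[i])
    return x0, float(f0), flat


def _smooth(y: np.ndarray, w: int = 5) -> np.ndarray:
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="same")


def activation_time(raw: pd.DataFrame, freq: float) -> float:
    """Channel activation time from the speed-maximum shift, tau = DeltaX/(2*V_MAX).

    The bundle speed is estimated by finite differences after a 5-sample
    moving average; on each half-cycle of the phase-folded mean cycle the
    position of maximal |dX/dt| is located, and their shift DeltaX divided
    by twice the maximal speed gives the activation time in seconds.
    """
    t = raw["t_s"].to_numpy()
    Delta = raw["Delta_nm"].to_numpy()
    X = raw["X_nm"].to_numpy()
    dt = float(np.median(np.diff(t)))
    n_per = int(round(1.0 / (freq * dt)))
    n_cycles = len(t) // n_per
    if n_cycles < 1:
        raise ValueError("record shorter than one stimulus period")
    Xm = X[: n_cycles * n_per].reshape(n_cycles, n_per).mean(axis=0)
    Dm = Delta[: n_cycles * n_per].reshape(n_cycles, n_per).mean(axis=0)
    Xs = _smooth(Xm)
    v = np.gradient(Xs, dt)
    dD = np.gradient(Dm, dt)
    up = dD > 0
    # guard the seam samples where the smoothing kernel wraps
    guard = np.ones(n_per, dtype=bool)
    guard[:3] = guard[-3:] = False
    v_up = np.where(up & guard, np.abs(v), -np.inf)
    v_dn = np.where(~up & guard, np.abs(v), -np.inf)
    i_up = int(np.argmax(v_up))
    i_dn = int(np.argmax(v_dn))
    v_max = 0.5 * (abs(v[i_up]) + abs(v[i_dn]))
    if v_max <= 0:
        raise ValueError("degenerate stimulus: maximal bundle speed is zero")
    dX = abs(Xs[i_up] - Xs[i_dn])
    return float(dX / (2.0 * v_max))


def mean_position(raw: pd.DataFrame, freq: float | None = None) -> float:
    """Time-averaged bundle position over whole stimulus cycles."""
    X = raw["X_nm"].to_numpy()
    if X.size == 0:
        raise ValueError("empty record")
    if freq is not None:
        t = raw["t_s"].to_numpy()
        dt = float(np.median(np.diff(t)))
        n_per = int(round(1.0 / (freq * dt)))
        n_cycles = X.size // n_per
        if n_cycles >= 1:
            X = X[: n_cycles * n_per]
    return float(np.mean(X))


def cycle_metrics(raw: pd.DataFrame, freq: float, n_cycles: int | None = None) -> CycleMetrics:
    """All scalar cycle metrics for one raw triangular-stimulation record."""
    c = average_cycles(raw, freq, n_cycles)
    phi, phi_max, x_at, flat = friction_profile(c)
    x0, f0, _ = inversion_point(c)
    mask = _interior_mask(c) & np.isfinite(phi)
    sign_flag = bool(np.nanmedian(phi[mask]) < 0)
    tau = activation_time(raw, freq)
    xbar = mean_position(raw, freq)
    return CycleMetrics(
        phi_max_pN=phi_max, X0_nm=x0, F0_pN=f0, Xbar_nm=xbar,
        tau_act_s=tau, flat_phi=flat, sign_flag=sign_flag,
    )
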