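"""Ensemble statistics: correlations, regressions, paired tests, summary
values, hysteretic state-transition detection and 10-90% kinetics.

Conventions follow standard practice for this kind of dataset: Pearson's
correlation with two-sided p-values, ordinary least squares, two-tailed
paired Student's t-tests, and summaries quoted as mean +/- sample SD.  No
multiple-testing correction is applied (raw p-values are reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "TransitionResult",
    "KineticsResult",
    "correlate",
    "regress",
    "compare_paired",
    "summarize",
    "detect_drop",
    "detect_drop_from_ramp",
    "NoTransitionError",
    "t10_90",
    "step_kinetics",
    "ensemble_deltas",
    "analyze_ensemble",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass(frozen=True)
class TransitionResult:
    """Midpoint-crossing transition currents of the two ramp branches.

    The strong->weak drop current on the descending branch, the weak->strong
    recovery current on the ascending branch, their difference (the
    hysteresis shift, expected >= 0), and the pre-/post-drop friction
    levels used to define the midpoint.
    """

    I_drop_descending_uA: float
    I_drop_ascending_uA: float
    pre_level_pN: float
    post_level_pN: float

    @property
    def hysteresis_shift_uA(self) -> float:
        return self.I_drop_ascending_uA - self.I_drop_descending_uA


@dataclass(frozen=True)
class KineticsResult:
    """10-90% transition times (ms) of mean position and maximal friction
    force after step onset (ON) and offset (OFF), with their ratios."""

    t_X_on_ms: float
    t_X_off_ms: float
    t_phi_on_ms: float
    t_phi_off_ms: float

    @property
    def ratio_on(self) -> float:
        return self.t_phi_on_ms / self.t_X_on_ms

    @property
    def ratio_off(self) -> float:
        return self.t_phi_off_ms / self.t_X_off_ms


def _clean_xy(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    x, y = _clean_xy(x, y)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def regress(x, y) -> RegressionResult:
    """Ordinary least-squares line y = slope*x + intercept with R^2."""
    x, y = _clean_xy(x, y)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0:
        raise ValueError("degenerate regressor: zero variance in x")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), n=int(x.size),
    )


def compare_paired(a, b) -> tuple[float, float]:
    """Two-tailed paired Student's t-test; returns (t, p)."""
    a, b = _clean_xy(a, b)
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = b - a
    if np.allclose(np.var(d, ddof=1), 0.0):
        raise ValueError("degenerate pairing: zero difference variance")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def summarize(values) -> tuple[float, float, int]:
    """(mean, sample SD, n); SD is NaN for a single value."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 1:
        raise ValueError("need n >= 1")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else math.nan
    return float(np.mean(v)), sd, int(v.size)


# ---------------------------------------------------------------------------
# hysteretic drop detection


class NoTransitionError(RuntimeError):
    """The friction force never falls below the midpoint level."""


def _midpoint_crossing(I: np.ndarray, phi: np.ndarray, level: float) -> float:
    """First crossing of phi below ``level`` in ramp-time order, with linear
    interpolation of the crossing current between samples."""
    below = phi < level
    idx = np.flatnonzero(below)
    if idx.size == 0:
        raise NoTransitionError("phi_MAX never crosses the midpoint level")
    i = int(idx[0])
    if i == 0:
        return float(I[0])
    f0, f1 = phi[i - 1], phi[i]
    w = (level - f0) / (f1 - f0)
    return float(I[i - 1] + w * (I[i] - I[i - 1]))


def detect_drop(
    I_desc, phi_desc, I_asc, phi_asc
) -> TransitionResult:
    """Detect the strong->weak gating transition and its hysteresis.

    Inputs are the maximal friction force phi_MAX sampled along a
    descending current ramp (samples in ramp-time order, current
    decreasing) and the subsequent ascending ramp.  The strong (pre-drop)
    and weak (post-drop) levels are the medians of the samples above and
    below the mid-range of each branch's phi values (plateau medians); the
    transition current on each branch is where phi first crosses the level
    halfway between them, linearly interpolated.  The hysteresis shift is
    the ascending minus the descending crossing current.

    Invariant under uniform vertical scaling of phi and under horizontal
    translation of both branches.
    """
    I_d, phi_d = _clean_xy(I_desc, phi_desc)
    I_a, phi_a = _clean_xy(I_asc, phi_asc)
    results = {}
    levels = {}
    for name, I, phi in (("descending", I_d, phi_d), ("ascending", I_a, phi_a)):
        midrange = 0.5 * (phi.max() + phi.min())
        hi = phi[phi >= midrange]
        lo = phi[phi < midrange]
        if lo.size == 0 or hi.size == 0:
            raise NoTransitionError(f"no identifiable plateaus on {name} branch")
        pre = float(np.median(hi))
        post = float(np.median(lo))
        level = 0.5 * (pre + post)
        if name == "ascending":
            # weak->strong recovery: track the ramp in time order and find
            # where phi first rises above the level
            above = phi > level
            idx = np.flatnonzero(above)
            if idx.size == 0:
                raise NoTransitionError("ascending branch never recovers")
            i = int(idx[0])
            if i == 0:
                crossing = float(I[0])
            else:
                f0, f1 = phi[i - 1], phi[i]
                w = (level - f0) / (f1 - f0)
                crossing = float(I[i - 1] + w * (I[i] - I[i - 1]))
        else:
            crossing = _midpoint_crossing(I, phi, level)
        results[name] = crossing
        levels[name] = (pre, post)
    return TransitionResult(
        I_drop_descending_uA=results["descending"],
        I_drop_ascending_uA=results["ascending"],
        pre_level_pN=levels["descending"][0],
        post_level_pN=levels["descending"][1],
    )


def detect_drop_from_ramp(df: pd.DataFrame) -> TransitionResult:
    """Convenience wrapper for a ramp table with columns branch, I_uA,
    phi_max_pN (as produced by the ramp generator)."""
    d = df[df["branch"] == "descending"]
    a = df[df["branch"] == "ascending"]
    return detect_drop(
        d["I_uA"].to_numpy(), d["phi_max_pN"].to_numpy(),
        a["I_uA"].to_numpy(), a["phi_max_pN"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# 10-90% kinetics


def t10_90(t, y, noise_sd: float | None = None) -> float:
    """Time (same units as t) to transition from 10% to 90% of the total
    change between the baseline and plateau levels.

    Baseline and plateau are the medians of the first and last 10% of the
    window; crossing times are linearly interpolated between samples.
    Raises ValueError when the total change is below 3x the noise SD
    (estimated from the detrended baseline when not supplied).
    """
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if t.shape != y.shape or t.size < 10:
        raise ValueError("need matching t, y with >= 10 samples")
    n10 = max(t.size // 10, 2)
    base = float(np.median(y[:n10]))
    plateau = float(np.median(y[-n10:]))
    change = plateau - base
    if noise_sd is None:
        noise_sd = float(np.std(np.diff(y[:n10]))) / math.sqrt(2.0)
    if abs(change) < 3.0 * noise_sd or change == 0.0:
        raise ValueError(
            f"total change {change:.3g} below 3x noise SD {noise_sd:.3g}: t10-90 undefined"
        )
    lvl10 = base + 0.10 * change
    lvl90 = base + 0.90 * change
    s = np.sign(change)
    yy = s * y
    times = []
    for lvl in (s * lvl10, s * lvl90):
        idx = np.flatnonzero(yy >= lvl)
        if idx.size == 0:
            raise ValueError("level never crossed")
        i = int(idx[0])
        if i == 0:
            times.append(float(t[0]))
        else:
            w = (lvl - yy[i - 1]) / (yy[i] - yy[i - 1])
            times.append(float(t[i - 1] + w * (t[i] - t[i - 1])))
    return times[1] - times[0]


def step_kinetics(df: pd.DataFrame, t_on: float, t_off: float) -> KineticsResult:
    """10-90% ON/OFF times (ms) for the paired Xbar / phi_MAX kinetics trace
    (columns t_s, Xbar_nm, phi_max_pN)."""
    t = df["t_s"].to_numpy()
    t_end = float(t[-1])
    # windows hold a short pre-transition baseline (~10% of window length)
    on_win = (t >= t_on - (t_off - t_on) / 9.0) & (t < t_off)
    off_win = t >= t_off - (t_end - t_off) / 9.0
    out = {}
    for col, key in (("Xbar_nm", "X"), ("phi_max_pN", "phi")):
        y = df[col].to_numpy()
        out[f"{key}_on"] = 1e3 * t10_90(t[on_win], y[on_win])
        out[f"{key}_off"] = 1e3 * t10_90(t[off_win], y[off_win])
    return KineticsResult(
        t_X_on_ms=out["X_on"], t_X_off_ms=out["X_off"],
        t_phi_on_ms=out["phi_on"], t_phi_off_ms=out["phi_off"],
    )


# ---------------------------------------------------------------------------
# ensemble tables


def ensemble_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell condition deltas from an ensemble table.

    The table holds per-cell rows (cell_id, I_uA, K_pN_per_nm, F_G_pN,
    X0_nm, d_nm, state) with a control row (I = 0) per cell.  Returns one
    row per treated condition with the deltas against that cell's control:
    dX0_nm, dK_pN_per_nm, dF_G_pN, dd_nm, rel_dd_pct and the state flag.
    """
    rows = []
    for cid, grp in table.groupby("cell_id"):
        ctrl = grp[grp["I_uA"] == 0.0]
        if ctrl.empty:
            raise ValueError(f"cell {cid!r} has no control (I=0) row")
        c = ctrl.iloc[0]
        for _, r in grp[grp["I_uA"] != 0.0].iterrows():
            weak = r["state"] == "weak"
            rows.append(
                dict(
                    cell_id=cid,
                    I_uA=r["I_uA"],
                    dX0_nm=(math.nan if weak else r["X0_nm"] - c["X0_nm"]),
                    dK_pN_per_nm=r["K_pN_per_nm"] - c["K_pN_per_nm"],
                    dF_G_pN=r["F_G_pN"] - c["F_G_pN"],
                    dd_nm=r["d_nm"] - c["d_nm"],
                    rel_dd_pct=100.0 * (r["d_nm"] - c["d_nm"]) / c["d_nm"]
                    if c["d_nm"] > 0 else math.nan,
                    state=r["state"],
                )
            )
    return pd.DataFrame(rows)


def analyze_ensemble(table: pd.DataFrame) -> dict:
    """Current-dependence regressions and correlations of the ensemble deltas.

    For each observable (set-point shift, stiffness change, gating-force
    change, relative gating-swing change) restricted to strong-state rows,
    returns the OLS line, R^2 and the Pearson (r, p) against the current.
    """
    deltas = ensemble_deltas(table)
    strong = deltas[deltas["state"] == "strong"]
    out = {}
    for col in ("dX0_nm", "dK_pN_per_nm", "dF_G_pN", "rel_dd_pct"):
        sub = strong.dropna(subset=[col])
        if len(sub) < 3:
            continue
        reg = regress(sub["I_uA"], sub[col])
        r, p = correlate(sub["I_uA"], sub[col])
        out[col] = {
            "slope": reg.slope, "intercept": reg.intercept,
            "r_squared": reg.r_squared, "pearson_r": r, "p_value": p,
            "n": reg.n,
        }
    weak = deltas[deltas["state"] == "weak"]
    if len(weak):
        mean, sd, n = summarize(weak["dF_G_pN"])
        out["weak_state_dF_G_pN"] = {"mean": mean, "sd": sd, "n": n}
    return out
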