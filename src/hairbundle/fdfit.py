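"""Fitting the gating-spring relation to force-displacement data.

``GatingSpringModel`` holds one cell's (X, F) record and fits the
four-parameter gated relation

    F(X) = K*X - F_G / (1 + exp(-(X - X_0)/delta)) + F_null

by bounded nonlinear least squares with a deterministic multistart over the
poorly identified width ``delta``, alongside a two-parameter straight line.
Model selection uses a small-sample corrected information criterion plus
the requirement that the fitted gating force exceed twice its standard
error; otherwise the relation is declared linear and the gating force is
reported as undetectable (F_G = 0), matching the treatment of cells whose
force-displacement relations lose all signature of gating compliance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .core import (
    BundleGeometry,
    DegenerateStiffnessError,
    DerivedGating,
    GatingSpringParams,
    classify_regime,
    derive_gating,
    fd_force,
    min_fd_slope,
)

__all__ = [
    "FDRelation",
    "FitFailureError",
    "GatingSpringModel",
    "GatingSpringResults",
    "DeltaMetrics",
    "fit_gating_spring",
    "select_model",
    "delta_metrics",
]

_DELTA_BOUNDS = (1.0, 100.0)


class FitFailureError(RuntimeError):
    """Raised when no multistart converges; carries the best SSE reached."""

    def __init__(self, message: str, best_sse: float = math.inf):
        super().__init__(message)
        self.best_sse = best_sse


@dataclass(frozen=True)
class FDRelation:
    """One cell's force-displacement record under one condition.

    X : displacements, nm.  F : forces, pN.  I_uA : transepithelial current
    (or generic control-parameter value) of the condition; cell_id pairs
    control and treated records.
    """

    X: np.ndarray
    F: np.ndarray
    cell_id: str = ""
    I_uA: float = 0.0

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "F", F)
        if X.shape != F.shape or X.ndim != 1:
            raise ValueError("X and F must be 1-D arrays of equal length")
        if X.size < 6:
            raise ValueError(f"need >= 6 points, got {X.size}")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(F))):
            raise ValueError("X and F must be finite")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cell_id: str = "", I_uA: float = 0.0):
        missing = {"X_nm", "F_pN"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return cls(
            X=df["X_nm"].to_numpy(),
            F=df["F_pN"].to_numpy(),
            cell_id=df.attrs.get("cell_id", cell_id),
            I_uA=df.attrs.get("I_uA", I_uA),
        )


def _aicc(sse: float, n: int, k: int, scale: float) -> float:
    # SSE floored at numerical noise so a perfect fit does not yield -inf
    floor = n * (1e-9 * max(scale, 1e-12)) ** 2
    sse = max(sse, floor)
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class GatingSpringModel:
    """Gating-spring force-displacement model for one (X, F) record.

    Parameters
    ----------
    X, F : array-like
        Displacements (nm) and forces (pN).
    geometry : BundleGeometry, optional
        Projection factor and pivot stiffness used for the derived gating
        swing; defaults to gamma = 0.14, K_SP = 0.17 pN/nm.

    Examples
    --------
    >>> model = GatingSpringModel(X, F)
    >>> res = model.fit()
    >>> res.params.F_G, res.model_type
    """

    def __init__(self, X, F, geometry: BundleGeometry | None = None):
        self.rel = X if isinstance(X, FDRelation) else FDRelation(np.asarray(X), np.asarray(F))
        self.geometry = geometry or BundleGeometry()

    @classmethod
    def from_relation(cls, rel: FDRelation, geometry: BundleGeometry | None = None):
        obj = cls.__new__(cls)
        obj.rel = rel
        obj.geometry = geometry or BundleGeometry()
        return obj

    # -- initialization ----------------------------------------------------
    def _initial_guesses(self) -> tuple[float, float, float]:
        """(K0, FG0, X00) from the outer-third limbs and the global line."""
        X, F = self.rel.X, self.rel.F
        order = np.argsort(X)
        Xs, Fs = X[order], F[order]
        n = Xs.size
        third = max(n // 3, 2)
        lo, hi = slice(0, third), slice(n - third, n)

        def linfit(x, y):
            A = np.vstack([x, np.ones_like(x)]).T
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return coef  # slope, intercept

        s_lo, b_lo = linfit(Xs[lo], Fs[lo])
        s_hi, b_hi = linfit(Xs[hi], Fs[hi])
        # pooled within-limb slope
        K0 = float(
            (
                np.sum((Xs[lo] - Xs[lo].mean()) * (Fs[lo] - Fs[lo].mean()))
                + np.sum((Xs[hi] - Xs[hi].mean()) * (Fs[hi] - Fs[hi].mean()))
            )
            / (np.sum((Xs[lo] - Xs[lo].mean()) ** 2) + np.sum((Xs[hi] - Xs[hi].mean()) ** 2))
        )
        K0 = max(K0, 1e-3)
        FG0 = max(float(b_lo - b_hi), 0.0)
        # X of maximal deviation below the single global line
        s_all, b_all = linfit(Xs, Fs)
        X00 = float(Xs[np.argmax(np.abs(Fs - (s_all * Xs + b_all)))])
        return K0, FG0, X00

    # -- fitting -----------------------------------------------------------
    def _fit_gated(self, n_delta_starts: int = 5):
        X, F = self.rel.X, self.rel.F
        K0, FG0, X00 = self._initial_guesses()
        if FG0 == 0.0:
            FG0 = 0.2 * (F.max() - F.min())  # allow the gated branch a chance

        def residuals(theta):
            K, F_G, X_0, delta = theta
            po = expit((X - X_0) / delta)
            base = K * X - F_G * po
            fnull = float(np.mean(F - base))  # closed form given the others
            return base + fnull - F

        best = None
        lb = [1e-6, 0.0, X.min() - 0.5 * np.ptp(X), _DELTA_BOUNDS[0]]
        ub = [np.inf, np.inf, X.max() + 0.5 * np.ptp(X), _DELTA_BOUNDS[1]]
        for d0 in np.geomspace(_DELTA_BOUNDS[0], _DELTA_BOUNDS[1], n_delta_starts):
            theta0 = [K0, max(FG0, 1e-3), X00, d0]
            theta0 = np.clip(theta0, lb, ub)
            try:
                sol = least_squares(
                    residuals, theta0, bounds=(lb, ub), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except Exception:
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0]:
                best = (sse, sol)
        if best is None:
            raise FitFailureError("gated fit failed to converge from any start")
        sse, sol = best
        K, F_G, X_0, delta = sol.x
        po = expit((X - X_0) / delta)
        fnull = float(np.mean(F - (K * X - F_G * po)))
        params = GatingSpringParams(K=K, F_G=F_G, X_0=X_0, delta=delta, F_null=fnull)
        bse = self._standard_errors(sol, sse, n_params=5)
        return params, sse, bse

    def _standard_errors(self, sol, sse: float, n_params: int) -> dict[str, float]:
        n = self.rel.X.size
        dof = max(n - n_params, 1)
        s2 = sse / dof
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * s2
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(J.shape[1], np.inf)
        return {"K": se[0], "F_G": se[1], "X_0": se[2], "delta": se[3]}

    def _fit_linear(self):
        X, F = self.rel.X, self.rel.F
        A = np.vstack([X, np.ones_like(X)]).T
        coef, *_ = np.linalg.lstsq(A, F, rcond=None)
        K, fnull = float(coef[0]), float(coef[1])
        resid = F - (K * X + fnull)
        sse = float(np.sum(resid**2))
        n = X.size
        s2 = sse / max(n - 2, 1)
        sxx = float(np.sum((X - X.mean()) ** 2))
        se_K = math.sqrt(s2 / sxx) if sxx > 0 else math.inf
        return K, fnull, sse, se_K

    def fit(self, n_delta_starts: int = 5) -> "GatingSpringResults":
        """Fit both branches, select the model, return results."""
        X, F = self.rel.X, self.rel.F
        n = X.size
        scale = float(np.std(F)) or 1.0
        K_lin, fnull_lin, sse_lin, se_K_lin = self._fit_linear()
        gated_error: FitFailureError | None = None
        try:
            params_g, sse_g, bse_g = self._fit_gated(n_delta_starts)
        except FitFailureError as err:
            gated_error = err
            params_g, sse_g, bse_g = None, math.inf, {}

        aicc_lin = _aicc(sse_lin, n, k=3, scale=scale)  # slope, intercept, variance
        aicc_g = _aicc(sse_g, n, k=6, scale=scale) if params_g else math.inf
        gated_detectable = (
            params_g is not None
            and aicc_g < aicc_lin
            and params_g.F_G > 2.0 * bse_g.get("F_G", math.inf)
        )
        if gated_detectable:
            params = params_g
            sse = sse_g
            bse = bse_g
            model_type = "gated"
        else:
            # undetectable gating: report the linear branch with F_G = 0
            K_eff = max(K_lin, 1e-9)
            params = GatingSpringParams(
                K=K_eff, F_G=0.0, X_0=0.0, delta=20.0, F_null=fnull_lin
            )
            sse = sse_lin
            bse = {"K": se_K_lin, "F_G": math.nan, "X_0": math.nan, "delta": math.nan}
            model_type = "linear"
        rmse = math.sqrt(sse / n)
        try:
            derived = derive_gating(params, self.geometry)
            degenerate = False
        except DegenerateStiffnessError:
            derived = DerivedGating(
                K_GS=params.K - self.geometry.K_SP, D=math.nan, d=math.nan,
                min_slope=min_fd_slope(params), regime=classify_regime(params),
            )
            degenerate = True
        return GatingSpringResults(
            model=self, params=params, model_type=model_type, rmse=rmse,
            bse=bse, derived=derived, degenerate_stiffness=degenerate,
            sse_gated=sse_g, sse_linear=sse_lin,
            aicc_gated=aicc_g, aicc_linear=aicc_lin,
            gated_params=params_g, gated_error=gated_error,
        )


@dataclass(frozen=True)
class GatingSpringResults:
    """Results of a gating-spring force-displacement fit."""

    model: GatingSpringModel
    params: GatingSpringParams
    model_type: str  # 'gated' | 'linear'
    rmse: float
    bse: dict[str, float]
    derived: DerivedGating
    degenerate_stiffness: bool
    sse_gated: float
    sse_linear: float
    aicc_gated: float
    aicc_linear: float
    gated_params: GatingSpringParams | None = None
    gated_error: FitFailureError | None = None

    @property
    def undetectable_gating(self) -> bool:
        return self.model_type == "linear"

    def predict(self, X) -> np.ndarray:
        if self.model_type == "linear":
            return self.params.K * np.asarray(X, float) + self.params.F_null
        return fd_force(X, self.params)

    def summary(self) -> str:
        p, b = self.params, self.bse
        lines = [
            "Gating-spring force-displacement fit",
            "=" * 44,
            f"model:            {self.model_type}",
            f"n points:         {self.model.rel.X.size}",
            f"rmse:             {self.rmse:.4g} pN",
            f"K     = {p.K:8.4g} +/- {b.get('K', math.nan):.2g}  pN/nm",
            f"F_G   = {p.F_G:8.4g} +/- {b.get('F_G', math.nan):.2g}  pN"
            + ("  (undetectable)" if self.undetectable_gating else ""),
            f"X_0   = {p.X_0:8.4g} +/- {b.get('X_0', math.nan):.2g}  nm",
            f"delta = {p.delta:8.4g} +/- {b.get('delta', math.nan):.2g}  nm",
            f"F_null= {p.F_null:8.4g}  pN",
            f"regime:           {self.derived.regime or classify_regime(p)}",
        ]
        if not self.degenerate_stiffness:
            lines += [
                f"K_GS  = {self.derived.K_GS:8.4g}  pN/nm",
                f"d     = {self.derived.d:8.4g}  nm (gating swing, tip-link axis)",
            ]
        else:
            lines.append("gating swing undefined (K <= K_SP)")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        d = self.params.to_json_dict()
        d.update(
            {
                "model": self.model_type,
                "rmse_pN": self.rmse,
                "se_K_pN_per_nm": self.bse.get("K", math.nan),
                "se_F_G_pN": self.bse.get("F_G", math.nan),
                "se_X0_nm": self.bse.get("X_0", math.nan),
                "se_delta_nm": self.bse.get("delta", math.nan),
                "K_GS_pN_per_nm": self.derived.K_GS,
                "d_nm": self.derived.d,
                "D_nm": self.derived.D,
                "undetectable_gating": self.undetectable_gating,
                "degenerate_stiffness": self.degenerate_stiffness,
            }
        )
        return d


def fit_gating_spring(
    rel: FDRelation,
    geo: BundleGeometry | None = None,
    n_delta_starts: int = 5,
) -> GatingSpringResults:
    """Fit the gating-spring relation to one force-displacement record."""
    return GatingSpringModel.from_relation(rel, geo).fit(n_delta_starts=n_delta_starts)


def select_model(rel: FDRelation, geo: BundleGeometry | None = None) -> str:
    """'gated' or 'linear' for this record (AICc + 2-standard-error rule)."""
    return fit_gating_spring(rel, geo).model_type


@dataclass(frozen=True)
class DeltaMetrics:
    """Per-cell condition deltas relative to the I = 0 control fit."""

    cell_id: str
    I_uA: float
    dX0_nm: float
    dK_pN_per_nm: float
    dF_G_pN: float
    dd_nm: float
    rel_dF_G_pct: float
    rel_dK_pct: float
    rel_dd_pct: float
    treated_linear: bool

    def to_json_dict(self) -> dict:
        return dict(self.__dict__)


def delta_metrics(fit_I: GatingSpringResults, fit_0: GatingSpringResults) -> DeltaMetrics:
    """Condition deltas between a treated fit and its control fit.

    When the treated relation is linear (undetectable gating), the deltas
    follow the convention dF_G = -F_G(0) and dd/d_0 = -100%; the set-point
    shift is undefined (NaN) since a linear relation has no set point.
    """
    rel_I, rel_0 = fit_I.model.rel, fit_0.model.rel
    if rel_I.cell_id != rel_0.cell_id:
        raise ValueError(
            f"cannot pair fits from different cells: {rel_I.cell_id!r} vs {rel_0.cell_id!r}"
        )
    p_I, p_0 = fit_I.params, fit_0.params
    dK = p_I.K - p_0.K
    rel_dK = 100.0 * dK / p_0.K
    if fit_I.undetectable_gating:
        dX0 = math.nan
        dFG = -p_0.F_G
        dd = -fit_0.derived.d
        rel_dFG = -100.0 if p_0.F_G > 0 else 0.0
        rel_dd = -100.0 if p_0.F_G > 0 else 0.0
    else:
        dX0 = p_I.X_0 - p_0.X_0
        dFG = p_I.F_G - p_0.F_G
        dd = fit_I.derived.d - fit_0.derived.d
        rel_dFG = 100.0 * dFG / p_0.F_G if p_0.F_G > 0 else math.nan
        rel_dd = 100.0 * dd / fit_0.derived.d if fit_0.derived.d > 0 else math.nan
    return DeltaMetrics(
        cell_id=rel_I.cell_id,
        I_uA=rel_I.I_uA,
        dX0_nm=dX0,
        dK_pN_per_nm=dK,
        dF_G_pN=dFG,
        dd_nm=dd,
        rel_dF_G_pct=rel_dFG,
        rel_dK_pct=rel_dK,
        rel_dd_pct=rel_dd,
        treated_linear=fit_I.undetectable_gating,
    )
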