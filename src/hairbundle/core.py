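"""Gating-spring model of hair-bundle mechanics.

The mechanotransduction channels of a hair bundle are gated directly by
force, delivered through elastic "gating springs" in series with the tip
links.  Channel opening relaxes gating-spring tension by the gating force
``F_G``, so the quasi-static force-displacement relation of the bundle is

    F(X) = K*X - F_G * P_o(X) + F_null,
    P_o(X) = 1 / (1 + exp(-(X - X_0)/delta)),

where ``K`` is the linear stiffness (pN/nm), ``X_0`` the set-point
deflection at which the open probability is 1/2, ``delta`` the width of
the Boltzmann activation curve (nm) and ``F_null`` an offset enforcing
F(0) = 0.  The slope dip at intermediate deflections is the gating
compliance; when ``F_G > 4*K*delta`` the slope becomes negative and the
bundle is bistable.

The gating swing is the conformational displacement accompanying channel
opening.  Along the bundle axis it is ``D = F_G / K_GS`` with gating-spring
stiffness ``K_GS = K - K_SP`` (``K_SP`` is the residual stereociliary-pivot
stiffness after tip-link disruption); projected on the tip-link axis it is
``d = gamma * D`` with geometric projection factor ``gamma``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy.special import expit

__all__ = [
    "GatingSpringParams",
    "BundleGeometry",
    "DerivedGating",
    "DegenerateStiffnessError",
    "fd_force",
    "open_probability",
    "fd_slope",
    "min_fd_slope",
    "classify_regime",
    "gating_swing",
    "gating_force",
    "derive_gating",
    "with_force_zero_at_origin",
]

ArrayLike = Union[float, np.ndarray]


class DegenerateStiffnessError(ValueError):
    """Raised when K <= K_SP, i.e. the gating-spring stiffness is nonpositive."""


def _check_finite(name: str, value: float) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class GatingSpringParams:
    """Parameters of the gating-spring force-displacement relation.

    Attributes
    ----------
    K : float
        Linear stiffness, pN/nm.  Must be > 0.
    F_G : float
        Whole-bundle gating force, pN.  Must be >= 0.
    X_0 : float
        Set-point deflection (open probability 1/2), nm.
    delta : float
        Characteristic displacement of the activation curve, nm.  Must be > 0.
    F_null : float
        Force offset, pN; chosen so that F(0) = 0 in experimental records.
    """

    K: float
    F_G: float
    X_0: float
    delta: float
    F_null: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K", "F_G", "X_0", "delta", "F_null"):
            _check_finite(name, getattr(self, name))
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.F_G < 0:
            raise ValueError(f"F_G must be >= 0, got {self.F_G}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")

    # flat JSON with unit-suffixed keys
    def to_json_dict(self) -> dict:
        return {
            "K_pN_per_nm": self.K,
            "F_G_pN": self.F_G,
            "X0_nm": self.X_0,
            "delta_nm": self.delta,
            "Fnull_pN": self.F_null,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GatingSpringParams":
        return cls(
            K=d["K_pN_per_nm"],
            F_G=d["F_G_pN"],
            X_0=d["X0_nm"],
            delta=d["delta_nm"],
            F_null=d.get("Fnull_pN", 0.0),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())


@dataclass(frozen=True)
class BundleGeometry:
    """Geometry linking bundle-axis and tip-link-axis quantities.

    gamma : projection factor onto the tip-link axis (0 < gamma <= 1).
    K_SP : stereociliary-pivot stiffness after tip-link disruption, pN/nm.
    """

    gamma: float = 0.14
    K_SP: float = 0.17

    def __post_init__(self) -> None:
        if not (0 < self.gamma <= 1):
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.K_SP < 0:
            raise ValueError(f"K_SP must be >= 0, got {self.K_SP}")

    def to_json_dict(self) -> dict:
        return {"gamma": self.gamma, "K_SP_pN_per_nm": self.K_SP}

    @classmethod
    def from_json_dict(cls, d: dict) -> "BundleGeometry":
        return cls(gamma=d["gamma"], K_SP=d["K_SP_pN_per_nm"])


@dataclass(frozen=True)
class DerivedGating:
    """Quantities derived from a gating-spring fit.

    K_GS : gating-spring stiffness K - K_SP, pN/nm.
    D : gating swing along the bundle axis, nm.
    d : gating swing along the tip-link axis, nm (d = gamma * D).
    min_slope : minimal local stiffness K - F_G/(4 delta), pN/nm (optional).
    regime : 'linear', 'gated-monotonic' or 'negative-stiffness' (optional).
    """

    K_GS: float
    D: float
    d: float
    min_slope: float = field(default=math.nan)
    regime: str = field(default="")


def open_probability(X: ArrayLike, X_0: float, delta: float) -> ArrayLike:
    """Two-state Boltzmann open probability, 1/(1 + exp(-(X - X_0)/delta)).

    Strictly increasing in X; equals 1/2 at the set point X = X_0.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    _check_finite("X_0", X_0)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    out = expit((X - X_0) / delta)
    return float(out) if out.ndim == 0 else out


def fd_force(X: ArrayLike, p: GatingSpringParams) -> ArrayLike:
    """Quasi-static force (pN) exerted on the bundle at deflection X (nm).

    F(X) = K*X - F_G * P_o(X) + F_null.  For X -> -inf / +inf the relation
    approaches the closed-channel limb K*X + F_null and the open-channel
    limb K*X + F_null - F_G; the vertical gap between limbs equals F_G.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    out = p.K * X - p.F_G * expit((X - p.X_0) / p.delta) + p.F_null
    return float(out) if out.ndim == 0 else out


def fd_slope(X: ArrayLike, p: GatingSpringParams) -> ArrayLike:
    """Local stiffness dF/dX (pN/nm) of the gating-spring relation.

    dF/dX = K - (F_G/delta) * P_o * (1 - P_o); minimal value K - F_G/(4 delta)
    attained at X = X_0.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    po = expit((X - p.X_0) / p.delta)
    out = p.K - (p.F_G / p.delta) * po * (1.0 - po)
    return float(out) if out.ndim == 0 else out


def min_fd_slope(p: GatingSpringParams) -> float:
    """Minimum of the local stiffness, K - F_G/(4 delta), at X = X_0."""
    return p.K - p.F_G / (4.0 * p.delta)


def classify_regime(p: GatingSpringParams) -> str:
    """Classify the force-displacement relation.

    'linear' when F_G = 0; 'negative-stiffness' when the gating force is
    strong enough that the minimal slope is negative (F_G > 4*K*delta);
    'gated-monotonic' otherwise.
    """
    if p.F_G == 0:
        return "linear"
    if p.F_G > 4.0 * p.K * p.delta:
        return "negative-stiffness"
    return "gated-monotonic"


def gating_swing(F_G: float, K: float, geo: BundleGeometry) -> DerivedGating:
    """Gating swing from the fitted gating force and stiffness.

    K_GS = K - K_SP; D = F_G / K_GS (bundle axis); d = gamma * D (tip-link
    axis).  Raises DegenerateStiffnessError when K <= K_SP.
    """
    _check_finite("F_G", F_G)
    _check_finite("K", K)
    if F_G < 0:
        raise ValueError(f"F_G must be >= 0, got {F_G}")
    K_GS = K - geo.K_SP
    if K_GS <= 0:
        raise DegenerateStiffnessError(
            f"gating-spring stiffness K - K_SP = {K_GS:.4g} pN/nm is nonpositive"
        )
    D = F_G / K_GS
    return DerivedGating(K_GS=K_GS, D=D, d=geo.gamma * D)


def gating_force(d: float, K: float, geo: BundleGeometry) -> float:
    """Inverse of :func:`gating_swing`: F_G = d * (K - K_SP) / gamma."""
    K_GS = K - geo.K_SP
    if K_GS <= 0:
        raise DegenerateStiffnessError(
            f"gating-spring stiffness K - K_SP = {K_GS:.4g} pN/nm is nonpositive"
        )
    return d * K_GS / geo.gamma


def derive_gating(p: GatingSpringParams, geo: BundleGeometry) -> DerivedGating:
    """Full derived record (swing, minimal slope, regime) for fitted params."""
    dg = gating_swing(p.F_G, p.K, geo)
    return replace(dg, min_slope=min_fd_slope(p), regime=classify_regime(p))


def with_force_zero_at_origin(p: GatingSpringParams) -> GatingSpringParams:
    """Return a copy of ``p`` with F_null set so that F(0) = 0.

    Mirrors the experimental convention that the measured force vanishes at
    the resting position.
    """
    fnull = p.F_G * expit((0.0 - p.X_0) / p.delta)
    return replace(p, F_null=float(fnull))
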