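"""Model equations for graviproprioceptive shoot bending.

Everything here is a pure function of state: the differential-growth
response law, the curvature-rate kinematics, growth-rate profiles and the
parameter bookkeeping. Time stepping lives in :mod:`gravikin.simulator`.

Geometry convention: vertical is the +y axis, ``A`` is the signed angle of
the local tangent measured from vertical (positive counterclockwise) and
``C = dA/ds`` with ``s`` the arclength from the clamped base to the apex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ModelParams",
    "GrowthProfile",
    "OrganState",
    "bending_number",
    "delta_response",
    "curvature_rate",
    "flank_rates",
    "mean_and_delta",
    "elongation_field",
    "drift_rate",
    "angles_from_curvature",
]

GraviceptionLaw = Literal["linear", "sine"]
PrefactorMode = Literal["small_curvature", "full_quadratic"]
GrowthMode = Literal["exponential", "subapical_step"]

_REL_TOL = 1e-12


class CurvatureRangeWarning(UserWarning):
    """Emitted when |C*R| >= 1 is fed to the small-curvature kinematics."""


@dataclass(frozen=True)
class ModelParams:
    """Sensitivities and geometry of a simulated organ.

    ``beta_tilde`` and ``gamma_tilde`` are the dimensionless graviceptive
    and proprioceptive sensitivities.  The dimensional pair
    ``beta = beta_tilde * E0 / R`` (1/(length*time)) and
    ``gamma = gamma_tilde * E0`` (1/time) is derived whenever ``E0 > 0``;
    passing explicit values that contradict the dimensionless ones raises.
    """

    beta_tilde: float
    gamma_tilde: float
    R: float = 1.0
    E0: float = 1.0
    Lgz: float = 100.0
    L0: float = 100.0
    A0: float = np.pi / 2
    graviception_law: GraviceptionLaw = "linear"
    prefactor: PrefactorMode = "small_curvature"
    saturate_delta: bool = False
    beta: float | None = field(default=None)
    gamma: float | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("R", "Lgz", "L0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("E0", "beta_tilde", "gamma_tilde"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.graviception_law not in ("linear", "sine"):
            raise ValueError(f"unknown graviception law {self.graviception_law!r}")
        if self.prefactor not in ("small_curvature", "full_quadratic"):
            raise ValueError(f"unknown prefactor mode {self.prefactor!r}")
        if self.E0 > 0:
            beta = self.beta_tilde * self.E0 / self.R
            gamma = self.gamma_tilde * self.E0
            for name, given, derived in (
                ("beta", self.beta, beta),
                ("gamma", self.gamma, gamma),
            ):
                if given is not None and not np.isclose(
                    given, derived, rtol=_REL_TOL, atol=0.0
                ):
                    raise ValueError(
                        f"explicit {name}={given} inconsistent with the "
                        f"dimensionless sensitivities (expected {derived})"
                    )
            object.__setattr__(self, "beta", beta)
            object.__setattr__(self, "gamma", gamma)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with fields replaced (re-validated)."""
        if self.E0 > 0 and ("beta" not in kwargs and "gamma" not in kwargs):
            kwargs.setdefault("beta", None)
            kwargs.setdefault("gamma", None)
        return replace(self, **kwargs)

    def gravi_response(self, A):
        """g(A): the angular sensing nonlinearity."""
        A = np.asarray(A, dtype=float)
        return np.sin(A) if self.graviception_law == "sine" else A


def bending_number(params: ModelParams, growth_mode: GrowthMode = "exponential") -> float:
    """B = beta_tilde * L_eff / (gamma_tilde * R).

    The effective length is the initial organ length under whole-organ
    (exponential) growth and the growth-zone length under subapical growth.
    """
    L_eff = params.L0 if growth_mode == "exponential" else params.Lgz
    if params.gamma_tilde == 0:
        raise ValueError("bending number undefined for gamma_tilde = 0")
    return params.beta_tilde * L_eff / (params.gamma_tilde * params.R)


@dataclass(frozen=True)
class GrowthProfile:
    """Spatial relative-elongation-rate field.

    ``exponential``: Edot(s) = E0 everywhere (whole organ elongates, so the
    total length grows exponentially).  ``subapical_step``: Edot = 0 for
    material basal to the growth zone and E0 in the apical zone of length
    ``Lgz`` (the boundary point itself belongs to the growing side).
    """

    mode: GrowthMode = "exponential"
    E0: float = 1.0
    Lgz: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("exponential", "subapical_step"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.E0 < 0:
            raise ValueError("E0 must be >= 0")
        if self.Lgz <= 0:
            raise ValueError("Lgz must be > 0")

    def velocity(self, s, L: float):
        """Growth-induced displacement speed v(s) = integral of Edot from 0 to s."""
        s = np.asarray(s, dtype=float)
        if self.mode == "exponential":
            return self.E0 * s
        return self.E0 * np.maximum(0.0, s - max(0.0, L - self.Lgz))


@dataclass
class OrganState:
    """Lagrangian midline snapshot: material elements base -> apex.

    ``ds``: element lengths; ``C``: element curvatures; ``frozen``: latched
    flags for elements that have left the growth zone.
    """

    t: float
    ds: np.ndarray
    C: np.ndarray
    frozen: np.ndarray

    def __post_init__(self) -> None:
        self.ds = np.asarray(self.ds, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        if not (self.ds.shape == self.C.shape == self.frozen.shape):
            raise ValueError("ds, C and frozen must share one shape")
        if self.ds.ndim != 1 or self.ds.size < 2:
            raise ValueError("state needs at least 2 elements")
        if not np.all(self.ds > 0):
            raise ValueError("all element lengths must be > 0")

    @property
    def n(self) -> int:
        return self.ds.size

    @property
    def L(self) -> float:
        return float(self.ds.sum())

    @property
    def s_nodes(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.ds)))

    @property
    def s_mid(self) -> np.ndarray:
        return np.cumsum(self.ds) - 0.5 * self.ds

    def node_angles(self, A0: float) -> np.ndarray:
        return A0 + np.concatenate(([0.0], np.cumsum(self.C * self.ds)))

    def mid_angles(self, A0: float) -> np.ndarray:
        return A0 + np.cumsum(self.C * self.ds) - 0.5 * self.C * self.ds

    def angle_steps(self) -> np.ndarray:
        """A' per element: the angle difference C*ds across each element."""
        return self.C * self.ds


def delta_response(A, C, params: ModelParams):
    """Differential-growth fraction commanded by gravi- and proprioception.

    Delta = -beta_tilde * g(A) - gamma_tilde * C * R, with g the linear or
    sine law.  Optionally saturated to [-1, 1] (non-shrinking flanks).
    """
    A = np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(C))):
        raise ValueError("non-finite angle or curvature input")
    delta = -params.beta_tilde * params.gravi_response(A) - params.gamma_tilde * C * params.R
    if params.saturate_delta:
        delta = np.clip(delta, -1.0, 1.0)
    return delta if delta.ndim else float(delta)


def curvature_rate(C, Edot, Delta, R: float, prefactor_mode: PrefactorMode = "small_curvature"):
    """Material rate of curvature change DC/Dt driven by differential growth.

    small_curvature: DC/Dt = Edot * Delta / R.
    full_quadratic:  DC/Dt = (1 - C^2 R^2) * Edot * Delta / R.
    """
    C = np.asarray(C, dtype=float)
    Edot = np.asarray(Edot, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    for arr, name in ((C, "C"), (Edot, "Edot"), (Delta, "Delta")):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name}")
    if prefactor_mode == "small_curvature":
        if np.any(np.abs(C * R) >= 1.0):
            warnings.warn(
                "|C*R| >= 1: the small-curvature kinematics is outside its "
                "validity range",
                CurvatureRangeWarning,
                stacklevel=2,
            )
        rate = Edot * Delta / R
    elif prefactor_mode == "full_quadratic":
        rate = (1.0 - (C * R) ** 2) * Edot * Delta / R
    else:
        raise ValueError(f"unknown prefactor mode {prefactor_mode!r}")
    return rate if rate.ndim else float(rate)


def flank_rates(Edot, Delta):
    """Per-flank elongation rates (eps1, eps2) = (Edot(1-Delta), Edot(1+Delta))."""
    Edot = np.asarray(Edot, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    e1 = Edot * (1.0 - Delta)
    e2 = Edot * (1.0 + Delta)
    return (e1 if e1.ndim else float(e1), e2 if e2.ndim else float(e2))


def mean_and_delta(eps1, eps2):
    """Inverse of :func:`flank_rates`: (Edot, Delta) from the flank rates."""
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    Edot = 0.5 * (eps1 + eps2)
    Delta = (eps2 - eps1) / (eps1 + eps2)
    return (Edot if Edot.ndim else float(Edot), Delta if Delta.ndim else float(Delta))


def elongation_field(s, L: float, profile: GrowthProfile):
    """Relative elongation rate Edot(s) for an organ of current length L.

    The subapical step is closed on the apical side: exactly at
    ``s = L - Lgz`` the element is growing.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < -1e-12 * max(L, 1.0)) or np.any(s > L * (1 + 1e-12)):
        raise ValueError(f"position outside [0, L={L}]")
    if profile.mode == "exponential":
        out = np.full_like(s, profile.E0)
    else:
        out = np.where(s >= L - profile.Lgz, profile.E0, 0.0)
    return out if out.ndim else float(out)


def drift_rate(C, Delta, E0: float, ds, R: float):
    """Rate of change of the angle difference A' = C*ds across an element.

    dA'/dt = E0 * (Delta + C*R) * ds / R.  With Delta = 0 this is the pure
    passive orientation drift E0 * C * ds of a curved elongating element.
    """
    C = np.asarray(C, dtype=float)
    ds = np.asarray(ds, dtype=float)
    if np.any(ds <= 0):
        raise ValueError("ds must be > 0")
    out = E0 * (np.asarray(Delta, dtype=float) + C * R) * ds / R
    return out if out.ndim else float(out)


def angles_from_curvature(state: OrganState, A0: float) -> np.ndarray:
    """Node angles by cumulative summation of C*ds from the clamped base.

    Returns ``state.n + 1`` values; the base node is exactly ``A0``.
    """
    return state.node_angles(A0)
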