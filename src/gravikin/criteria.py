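"""Regime diagnostics: drift controllability, convergence vs fixation times.

The fixation time and the fixation-negligibility bound are implemented
with their square roots (T_f = (1/E0) * sqrt(2R/(bt*Lgz)), B < sqrt(2*Lgz/R)):
these follow from integrating the maximal-bending curvature ramp over the
fixed zone, and are the only dimensionally consistent forms.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

from .model_core import GrowthMode, ModelParams, bending_number
from .steady_state import exp_growth_negligible

__all__ = [
    "RegimeReport",
    "active_control_ok",
    "convergence_time",
    "fixation_time",
    "fixation_negligible",
    "fixed_zone",
    "fixed_profile_bound",
    "regime_report",
]


@dataclass(frozen=True)
class RegimeReport:
    gamma_tilde: float
    B: float
    Lgz_over_R: float
    active_control_ok: bool
    exp_growth_negligible: bool
    fixation_negligible: bool
    Tc: float
    Tf: float
    Tc_over_Tf: float

    def to_dict(self) -> dict:
        return asdict(self)


def active_control_ok(gamma_tilde: float) -> bool:
    """Proprioception beats passive orientation drift iff gamma_tilde > 1."""
    if gamma_tilde < 0:
        raise ValueError("gamma_tilde must be >= 0")
    return bool(gamma_tilde > 1.0)


def convergence_time(E0: float, gamma_tilde: float) -> float:
    """Proprioception-dominated convergence timescale Tc = 1/(E0*gamma_tilde)."""
    if E0 <= 0:
        raise ValueError("convergence time undefined without elongation (E0 > 0)")
    if gamma_tilde <= 0:
        raise ValueError("gamma_tilde must be > 0")
    return 1.0 / (E0 * gamma_tilde)


def fixation_time(E0: float, beta_tilde: float, Lgz: float, R: float) -> float:
    """Lower bound on the time for a vertical element to leave the growth zone.

    Tf = (1/E0) * sqrt(2R / (beta_tilde * Lgz)): the maximal graviceptive
    bending ramp C(t)R = -bt*A0*E0*t integrated over the growing fixed zone
    first reaches angle zero at this time.
    """
    if not (E0 > 0 and beta_tilde > 0 and Lgz > 0 and R > 0):
        raise ValueError("all arguments must be > 0")
    return math.sqrt(2.0 * R / (beta_tilde * Lgz)) / E0


def fixation_negligible(B: float, Lgz: float, R: float, factor: float = 2.0) -> bool:
    """True iff curvature fixation cannot trap undulations: B < sqrt(factor*Lgz/R)."""
    if not (Lgz > 0 and R > 0):
        raise ValueError("lengths must be > 0")
    return bool(B < math.sqrt(factor * Lgz / R))


def fixed_zone(t: float, E0: float, Lgz: float, L0: float | None = None) -> tuple[float, float]:
    """(L(t), Lf(t)) in the linear-growth phase starting exactly filled.

    L(t) = Lgz*(1 + E0*t), Lf(t) = Lgz*E0*t.  Applies to L0 = Lgz; other
    initial lengths are handled by the simulator, not this closed form.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if L0 is not None and not math.isclose(L0, Lgz, rel_tol=1e-9):
        raise ValueError("closed form requires the organ to start exactly filled (L0 = Lgz)")
    return Lgz * (1.0 + E0 * t), Lgz * E0 * t


def fixed_profile_bound(
    t: float, A0: float, beta_tilde: float, E0: float, Lgz: float, R: float
) -> tuple[float, float]:
    """Maximal-bending bound on elements leaving the growth zone at time t.

    C_exit*R = -beta_tilde*A0*E0*t and, integrating that ramp over the
    fixed zone, A_exit = A0*(1 - beta_tilde*Lgz*(E0*t)^2 / (2R)); the 1/2
    makes A_exit vanish exactly at the fixation time.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    C_exit = -beta_tilde * A0 * E0 * t / R
    A_exit = A0 - beta_tilde * A0 * Lgz * (E0 * t) ** 2 / (2.0 * R)
    return C_exit, A_exit


def regime_report(params: ModelParams, growth_mode: GrowthMode = "subapical_step") -> RegimeReport:
    """Bundle the regime diagnostics for one parameter set."""
    B = bending_number(params, growth_mode)
    Tc = convergence_time(params.E0, params.gamma_tilde)
    Tf = fixation_time(params.E0, params.beta_tilde, params.Lgz, params.R)
    return RegimeReport(
        gamma_tilde=params.gamma_tilde,
        B=B,
        Lgz_over_R=params.Lgz / params.R,
        active_control_ok=active_control_ok(params.gamma_tilde),
        exp_growth_negligible=exp_growth_negligible(params.Lgz, params.R, B),
        fixation_negligible=fixation_negligible(B, params.Lgz, params.R),
        Tc=Tc,
        Tf=Tf,
        Tc_over_Tf=Tc / Tf,
    )
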