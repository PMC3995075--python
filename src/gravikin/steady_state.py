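"""Closed-form steady shapes and the model-discrimination statistic.

The exponential-growth steady profile is a real-order Bessel function of
the first kind; it is evaluated through the confluent limit function
0F1(g; -x) = Gamma(g) * x^((1-g)/2) * J_{g-1}(2*sqrt(x)), which is the
same expression but free of the 0^negative / Gamma overflow problems of
the literal product at large order or tiny argument (the s -> 0 limit is
exactly 1, i.e. the profile starts at the clamp angle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize
from scipy.special import hyp0f1

__all__ = [
    "SteadyShape",
    "ac_profile",
    "ace_profile",
    "mu_statistic",
    "critical_gamma",
    "exp_growth_negligible",
]


@dataclass(frozen=True)
class SteadyShape:
    """Sampled steady angle profile A(s) for one of the two models."""

    s: np.ndarray
    A: np.ndarray
    model: Literal["ac", "ace_exponential"]
    params: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        if self.s.shape != self.A.shape:
            raise ValueError("s and A must share a shape")


def ac_profile(s, A0: float, B: float, L_eff: float):
    """Non-elongating steady state: exponential decay A0 * exp(-B*s/L_eff)."""
    if not L_eff > 0:
        raise ValueError("L_eff must be > 0")
    s = np.asarray(s, dtype=float)
    out = A0 * np.exp(-B * s / L_eff)
    return out if out.ndim else float(out)


def ace_profile(s, A0: float, beta_tilde: float, gamma_tilde: float, R: float):
    """Exponential-growth steady state.

    A(s) = A0 * Gamma(g) * (bt*s/R)^((1-g)/2) * J_{g-1}(2*sqrt(bt*s/R))
         = A0 * 0F1(g; -bt*s/R)

    Defined for gamma_tilde > 0; the s -> 0 limit is A0 exactly.  For
    gamma_tilde < 1 the formula is still returned but the profile is a
    non-attracting (wavy, drift-unstable) stationary solution.
    """
    if not gamma_tilde > 0:
        raise ValueError("ace_profile undefined for gamma_tilde <= 0")
    if beta_tilde < 0 or not R > 0:
        raise ValueError("need beta_tilde >= 0 and R > 0")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be >= 0")
    out = A0 * hyp0f1(gamma_tilde, -beta_tilde * s / R)
    return out if out.ndim else float(out)


def mu_statistic(u, A0: float, gamma_tilde: float):
    """Absolute steady-profile difference between the two models.

    In the dimensionless position u = B*s/L_gz both steady states collapse
    to functions of (A0, gamma_tilde) alone:

        mu(u) = | A0*0F1(gamma_tilde; -gamma_tilde*u) - A0*exp(-u) |
    """
    if not gamma_tilde > 0:
        raise ValueError("mu_statistic undefined for gamma_tilde <= 0")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("u must be >= 0")
    out = np.abs(A0 * hyp0f1(gamma_tilde, -gamma_tilde * u) - A0 * np.exp(-u))
    return out if out.ndim else float(out)


def _mu_sup(gamma_tilde: float, A0: float, u_max: float, n_grid: int = 8001) -> float:
    """Supremum of mu over [0, u_max]: dense grid plus local refinement."""
    u = np.linspace(0.0, u_max, n_grid)
    mu = mu_statistic(u, A0, gamma_tilde)
    i = int(np.argmax(mu))
    lo = u[max(i - 1, 0)]
    hi = u[min(i + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda x: -mu_statistic(float(x), A0, gamma_tilde),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return max(float(mu[i]), float(-res.fun))
    return float(mu[i])


def critical_gamma(
    A0: float = np.pi / 2,
    mu_max: float = 0.05,
    u_max: float = 50.0,
    tol: float = 1e-3,
) -> float:
    """Smallest proprioceptive gain making the two steady states agree.

    Bisects for the smallest gamma_tilde whose supremum of mu over
    [0, u_max] does not exceed mu_max.  With the tolerance expressed
    relative to the initial amplitude (A0 = 1) the threshold is ~6.05; the
    absolute convention with A0 = pi/2 gives ~9.16.
    """
    if not mu_max > 0:
        raise ValueError("mu_max must be > 0")
    if not u_max > 0:
        raise ValueError("u_max must be > 0")
    ok = lambda g: _mu_sup(g, A0, u_max) <= mu_max
    lo, hi = 0.5, 8.0
    # grow hi until the criterion holds; shrink lo until it fails
    while not ok(hi):
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket the critical gain from above")
    if ok(lo):
        return lo  # criterion satisfiable everywhere probed
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def exp_growth_negligible(Lgz: float, R: float, B: float, threshold: float = 6.2) -> bool:
    """Whether whole-organ elongation is invisible at measurement accuracy.

    True iff Lgz/R > threshold * B (equivalently gamma_tilde > threshold
    when the graviceptive gain is of order one).
    """
    if not (Lgz > 0 and R > 0):
        raise ValueError("lengths must be > 0")
    return bool(Lgz / R > threshold * B)
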