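"""Synthetic midline generators: every downstream module is testable offline.

Named scenarios pin the four qualitative simulation regimes
(B, gamma_tilde, L_eff/R) = (10, 0.1, 100) and (10, 10, 100) under
whole-organ and subapical growth, plus a non-elongating reference run.
Digitization noise is applied to tangent angles and re-integrated, which
mimics orientation measurement error rather than i.i.d. point jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .model_core import GrowthProfile, ModelParams, OrganState, bending_number
from .phenotyping import MidlineSeries, write_midline_csv
from .simulator import Trajectory, simulate

__all__ = [
    "FixtureSpec",
    "scenario_setup",
    "render_midline",
    "series_from_trajectory",
    "generate",
    "write_fixture",
]

Scenario = Literal["fig5a", "fig5b", "fig5c", "fig5d", "ac_reference", "custom"]

#: default measurement noise on tangent angles [rad]
DEFAULT_NOISE_SD = 0.05


@dataclass(frozen=True)
class FixtureSpec:
    scenario: Scenario = "fig5b"
    noise_sd: float = 0.0
    n_frames: int = 8
    seed: int = 0
    B: float = 4.0  # ac_reference / custom only
    params: ModelParams | None = None
    profile: GrowthProfile | None = None
    mode: str = "ace"
    t_max: float | None = None
    N: int = 200

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scenario == "custom" and self.params is None:
            raise ValueError("custom scenario requires explicit params")


def scenario_setup(spec: FixtureSpec) -> tuple[ModelParams, GrowthProfile | None, str, float]:
    """(params, profile, mode, t_max) for a named scenario.

    All scenarios use R = 1, E0 = 1, a horizontal clamp and L_eff/R = 100;
    the dimensionless graviceptive gain follows from the pinned (B,
    gamma_tilde) pair.
    """
    L = 100.0

    def _exp(gt: float, B: float, t_max: float):
        bt = B * gt * 1.0 / L
        p = ModelParams(beta_tilde=bt, gamma_tilde=gt, R=1.0, E0=1.0, Lgz=L, L0=L)
        return p, GrowthProfile("exponential", 1.0, L), "ace", t_max

    def _sub(gt: float, B: float, t_max: float):
        bt = B * gt * 1.0 / L
        p = ModelParams(beta_tilde=bt, gamma_tilde=gt, R=1.0, E0=1.0, Lgz=L, L0=L)
        return p, GrowthProfile("subapical_step", 1.0, L), "ace", t_max

    table = {
        "fig5a": lambda: _exp(0.1, 10.0, 3.5),
        "fig5b": lambda: _exp(10.0, 10.0, 2.0),
        "fig5c": lambda: _sub(0.1, 10.0, 4.0),
        "fig5d": lambda: _sub(10.0, 10.0, 3.0),
    }
    if spec.scenario in table:
        params, profile, mode, t_max = table[spec.scenario]()
    elif spec.scenario == "ac_reference":
        bt = spec.B / L  # gamma_tilde = 1, E0 = 1 => beta = B/L, gamma = 1
        params = ModelParams(beta_tilde=bt, gamma_tilde=1.0, R=1.0, E0=1.0, Lgz=L, L0=L)
        profile, mode, t_max = None, "ac", 10.0
    else:
        params, profile, mode = spec.params, spec.profile, spec.mode
        t_max = spec.t_max if spec.t_max is not None else 3.0
    if spec.t_max is not None:
        t_max = spec.t_max
    return params, profile, mode, t_max


def render_midline(
    state: OrganState, base_xy=(0.0, 0.0), A0: float = np.pi / 2
) -> np.ndarray:
    """(n+1, 2) midline points by integrating the unit tangent (sin A, cos A).

    Each chord uses the element's mean node angle, which is chord-accurate
    to second order in the element length.
    """
    A_nodes = state.node_angles(A0)
    A_mean = 0.5 * (A_nodes[:-1] + A_nodes[1:])
    steps = state.ds[:, None] * np.column_stack([np.sin(A_mean), np.cos(A_mean)])
    pts = np.empty((state.n + 1, 2))
    pts[0] = base_xy
    pts[1:] = np.asarray(base_xy) + np.cumsum(steps, axis=0)
    return pts


def _render_noisy(state: OrganState, A0: float, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    A_nodes = state.node_angles(A0)
    A_mean = 0.5 * (A_nodes[:-1] + A_nodes[1:])
    if noise_sd > 0:
        A_mean = A_mean + rng.normal(0.0, noise_sd, size=A_mean.size)
    steps = state.ds[:, None] * np.column_stack([np.sin(A_mean), np.cos(A_mean)])
    pts = np.empty((state.n + 1, 2))
    pts[0] = (0.0, 0.0)
    pts[1:] = np.cumsum(steps, axis=0)
    return pts


def series_from_trajectory(
    traj: Trajectory,
    n_frames: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MidlineSeries:
    """Render n_frames snapshots, equally spaced in time, as noisy midlines."""
    if rng is None:
        rng = np.random.default_rng(0)
    wanted = np.linspace(traj.times[0], traj.times[-1], n_frames)
    idx = sorted(set(int(np.argmin(np.abs(traj.times - tw))) for tw in wanted))
    frames = [
        (float(traj.times[i]), _render_noisy(traj.snapshots[i], traj.params.A0, noise_sd, rng))
        for i in idx
    ]
    return MidlineSeries(frames)


def generate(spec: FixtureSpec) -> tuple[MidlineSeries, dict]:
    """Simulate a scenario and return (midline series, ground-truth record)."""
    params, profile, mode, t_max = scenario_setup(spec)
    traj = simulate(params, profile, mode=mode, t_max=t_max, N=spec.N)
    rng = np.random.default_rng(spec.seed)
    series = series_from_trajectory(traj, spec.n_frames, spec.noise_sd, rng)
    growth_mode = profile.mode if profile is not None else "subapical_step"
    truth = {
        "scenario": spec.scenario,
        "B": bending_number(params, growth_mode),
        "beta_tilde": params.beta_tilde,
        "gamma_tilde": params.gamma_tilde,
        "R": params.R,
        "E0": params.E0,
        "Lgz": params.Lgz,
        "L0": params.L0,
        "A0": params.A0,
        "mode": mode,
        "growth_mode": None if profile is None else profile.mode,
        "t_max": t_max,
        "converged_at": traj.converged_at,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "n_frames": spec.n_frames,
    }
    return series, truth


def write_fixture(spec: FixtureSpec, prefix: str | Path) -> tuple[Path, Path]:
    """Write <prefix>.csv (midlines) and <prefix>.json (ground truth)."""
    series, truth = generate(spec)
    prefix = Path(prefix)
    csv_path = write_midline_csv(series, prefix.with_suffix(".csv"))
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(truth, indent=2, default=float))
    return csv_path, json_path
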