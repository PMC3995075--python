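"""Kinematic phenotyping of digitized organ midlines.

Reproduces the measurement pipeline used on time-lapse images: the
effective length comes from superimposing the first and last frames, the
convergence length from an exponential fit to the steady angle profile,
and the bending number is their ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .criteria import RegimeReport, regime_report
from .model_core import ModelParams

__all__ = [
    "MidlineSeries",
    "PhenotypeResult",
    "NoConvergenceZoneError",
    "geometry",
    "effective_length",
    "fit_convergence_length",
    "phenotype",
    "read_midline_csv",
    "write_midline_csv",
]

#: angular measurement error of the digitization procedure [rad]; used both
#: for curved-zone onset detection and frame-superposition divergence.
ANGLE_TOL = 0.05


class NoConvergenceZoneError(ValueError):
    """The angle profile never curves or does not decay toward the apex."""


@dataclass
class MidlineSeries:
    """Time-stamped midline polylines, base -> apex, shared clamped base."""

    frames: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("need at least 2 frames")
        cleaned = []
        for t, pts in self.frames:
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise ValueError("each frame needs >= 3 (x, y) points")
            cleaned.append((float(t), pts))
        cleaned.sort(key=lambda fr: fr[0])
        self.frames = cleaned
        base = self.frames[0][1][0]
        scale = max(np.ptp(self.frames[0][1]), 1.0)
        for t, pts in self.frames[1:]:
            if np.max(np.abs(pts[0] - base)) > 1e-6 * scale:
                raise ValueError("frames do not share a clamped base point")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.frames])


@dataclass
class PhenotypeResult:
    L_eff: float
    L_c: float
    A0_fit: float
    B: float
    fit_rmse: float
    fit_range: tuple[float, float]
    report: RegimeReport | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "L_eff": self.L_eff,
            "L_c": self.L_c,
            "A0_fit": self.A0_fit,
            "B": self.B,
            "fit_rmse": self.fit_rmse,
            "fit_range": list(self.fit_range),
            "warnings": self.warnings,
        }
        if self.report is not None:
            d["report"] = self.report.to_dict()
        return d


def geometry(points: np.ndarray, n_resample: int = 200) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(s, A, C) arrays from a midline polyline.

    Arclength by cumulative chords, tangent angle from vertical by finite
    differences, curvature by centered differences, all on a uniform
    resampled grid of spacing L/n_resample.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicate consecutive points")
    s_raw = np.concatenate(([0.0], np.cumsum(seg)))
    s = np.linspace(0.0, s_raw[-1], n_resample + 1)
    x = np.interp(s, s_raw, points[:, 0])
    y = np.interp(s, s_raw, points[:, 1])
    dx = np.gradient(x, s)
    dy = np.gradient(y, s)
    A = np.unwrap(np.arctan2(dx, dy))
    C = np.gradient(A, s)
    return s, A, C


def effective_length(
    first: tuple[float, np.ndarray],
    last: tuple[float, np.ndarray],
    tol_angle: float = ANGLE_TOL,
    n_resample: int = 200,
) -> float:
    """Length of the responding apical zone by frame superposition.

    Base-aligned comparison of the first and last angle profiles on the
    first frame's arclength grid; the effective length runs from the first
    position where they differ by more than ``tol_angle`` to the apex of
    the first frame.  Identical frames give the full first-frame length.
    """
    _, pts_first = first
    _, pts_last = last
    scale = max(np.ptp(pts_first), 1.0)
    if np.max(np.abs(pts_first[0] - pts_last[0])) > 1e-6 * scale:
        raise ValueError("frames do not share a base point")
    s1, A1, _ = geometry(pts_first, n_resample)
    s2, A2, _ = geometry(pts_last, n_resample)
    A2_on_1 = np.interp(s1, s2, A2)
    diff = np.abs(A2_on_1 - A1)
    idx = np.nonzero(diff > tol_angle)[0]
    if idx.size == 0:
        return float(s1[-1])
    return float(s1[-1] - s1[idx[0]])


def fit_convergence_length(
    s: np.ndarray,
    A: np.ndarray,
    A0_known: float | None = None,
    tol_angle: float = ANGLE_TOL,
) -> tuple[float, float, float, tuple[float, float]]:
    """Exponential decay fit of a steady angle profile.

    Finds the curved-zone onset (first position deviating from the basal
    angle by more than ``tol_angle``), re-origins the arclength there and
    least-squares fits A = A0 * exp(-s/L_c) to the apex.  Returns
    (A0_fit, L_c, rmse, (s_start, s_end)).
    """
    s = np.asarray(s, dtype=float)
    A = np.asarray(A, dtype=float)
    dev = np.abs(A - A[0])
    onset = np.nonzero(dev > tol_angle)[0]
    if onset.size == 0:
        raise NoConvergenceZoneError("no convergence zone: profile never curves")
    i0 = int(onset[0])
    s_fit = s[i0:] - s[i0]
    A_fit = A[i0:]
    if s_fit.size < 5:
        raise NoConvergenceZoneError("no convergence zone: fewer than 5 points past onset")
    q = max(s_fit.size // 4, 1)
    if np.mean(np.abs(A_fit[-q:])) >= np.mean(np.abs(A_fit[:q])):
        raise NoConvergenceZoneError("no convergence zone: |A| does not decay")
    span = s_fit[-1]
    if A0_known is None:
        model = lambda x, a0, lc: a0 * np.exp(-x / lc)
        p0 = (A_fit[0], span / 3.0)
        popt, _ = curve_fit(
            model, s_fit, A_fit, p0=p0, bounds=([-np.inf, 1e-12 * span], np.inf), maxfev=10000
        )
        a0_fit, lc = float(popt[0]), float(popt[1])
    else:
        model = lambda x, lc: A0_known * np.exp(-x / lc)
        popt, _ = curve_fit(
            model, s_fit, A_fit, p0=(span / 3.0,), bounds=(1e-12 * span, np.inf), maxfev=10000
        )
        a0_fit, lc = float(A0_known), float(popt[0])
    rmse = float(np.sqrt(np.mean((model(s_fit, *popt) - A_fit) ** 2)))
    return a0_fit, lc, rmse, (float(s[i0]), float(s[-1]))


def phenotype(
    series: MidlineSeries,
    tol_angle: float = ANGLE_TOL,
    n_resample: int = 200,
    R: float | None = None,
    A0_known: float | None = None,
) -> PhenotypeResult:
    """Bending number and convergence length from a midline time series.

    B = L_eff / L_c.  When ``R`` is supplied, a regime report is attached
    using the order-one graviceptive-gain convention (beta_tilde = 1,
    gamma_tilde = L_eff/(B*R)).
    """
    notes: list[str] = []
    t_pen, pts_pen = series.frames[-2]
    t_last, pts_last = series.frames[-1]
    s_l, A_l, _ = geometry(pts_last, n_resample)
    s_p, A_p, _ = geometry(pts_pen, n_resample)
    if np.max(np.abs(np.interp(s_p, s_l, A_l) - A_p)) > tol_angle:
        msg = "last two frames still differ: profile may not be at steady state"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    L_eff = effective_length(series.frames[0], series.frames[-1], tol_angle, n_resample)
    a0_fit, L_c, rmse, fit_range = fit_convergence_length(s_l, A_l, A0_known, tol_angle)
    B = L_eff / L_c
    report = None
    if R is not None:
        gamma_tilde = L_eff / (B * R)
        params = ModelParams(
            beta_tilde=1.0, gamma_tilde=gamma_tilde, R=R, E0=1.0, Lgz=L_eff, L0=L_eff
        )
        report = regime_report(params, "subapical_step")
    return PhenotypeResult(
        L_eff=L_eff,
        L_c=L_c,
        A0_fit=a0_fit,
        B=B,
        fit_rmse=rmse,
        fit_range=fit_range,
        report=report,
        warnings=notes,
    )


def read_midline_csv(path: str | Path) -> MidlineSeries:
    """Read the long-format midline table (columns t, x, y; rows base -> apex)."""
    df = pd.read_csv(path)
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"midline CSV missing columns: {sorted(missing)}")
    frames = [
        (float(t), grp[["x", "y"]].to_numpy())
        for t, grp in df.groupby("t", sort=True)
    ]
    return MidlineSeries(frames)


def write_midline_csv(series: MidlineSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parts = [
        pd.DataFrame({"t": t, "x": pts[:, 0], "y": pts[:, 1]})
        for t, pts in series.frames
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
    return path
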