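"""Reduced (spatially lumped) active-gel pore dynamics.

During the early phase of pore opening in the adherent membrane–cortex
layer, the pore radius obeys

    dR/dt = [(σ0 + 2 f_adh R_L / 3) R − 2γ] / η_eff(R),

with a pore-size-dependent effective viscosity

    η_eff(R) = η + (η − 2 ρ0 τ_a ζ) R² / R_L².

Contractile stress (σ0) and adhesion (f_adh) drive opening; membrane
tension (γ) resists it. The coupling ζ between density and net gel
stress makes myosin (ζ > 0) lower η_eff — fluidising the layer and
speeding up rupture — while a passive actin layer (ζ < 0) stiffens it.

The pore opens only from an initial radius above the unstable fixed
point R_c = 6γ / (3σ0 + 2 f_adh R_L); smaller pores reseal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import GelParams

__all__ = [
    "PoreTrajectory",
    "FixedPointAnalysis",
    "effective_viscosity",
    "pore_opening_rate",
    "critical_radius",
    "critical_adhesion",
    "classify_regime",
    "simulate_pore",
    "simulate_rupture_trace",
    "phase_diagram",
    "EffectiveViscosityFloorError",
]

#: η_eff below this fraction of η is treated as unphysical (the reduced
#: equation is an early-phase approximation; a strongly negative η_eff
#: would integrate a backward-diffusive regime).
ETA_EFF_FLOOR_FRACTION = 0.01


class EffectiveViscosityFloorError(ValueError):
    """Raised when η_eff falls at or below the floor 0.01·η."""


@dataclass(frozen=True)
class PoreTrajectory:
    """Time-stamped pore radius R(t).

    ``terminated`` is set when the integration stopped because R reached
    the contact radius R_L (full rupture) or closed to 0.
    """

    times: np.ndarray
    radii: np.ndarray
    terminated: bool = False

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("times and radii must be 1-D and equal length")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(r)):
            raise ValueError("times and radii must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "radii", r)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "t_s": self.times,
            "R_m": self.radii,
            "terminated": np.full(self.times.shape, self.terminated),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PoreTrajectory":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["R_m"].to_numpy(),
                   bool(df["terminated"].iloc[-1]) if len(df) else False)


@dataclass(frozen=True)
class FixedPointAnalysis:
    """Critical radius and regime classification for a parameter set."""

    R_c: float
    stable_radius: Optional[float]
    regime: str  # 'seals' | 'opens_to_rupture' | 'stalls'


def effective_viscosity(params: GelParams, R: float | np.ndarray):
    """Effective viscosity η_eff(R) = η + (η − 2ρ0 τ_a ζ) R²/R_L², Pa·s.

    Raises
    ------
    EffectiveViscosityFloorError
        If the result is at or below ``ETA_EFF_FLOOR_FRACTION * eta``,
        signalling an unphysical parameter combination.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("R must be finite")
    if np.any(R < 0) or np.any(R > params.R_L * (1 + 1e-12)):
        raise ValueError("R must lie in [0, R_L]")
    eta_eff = params.eta + (
        params.eta - 2.0 * params.rho0 * params.tau_a * params.zeta
    ) * (R / params.R_L) ** 2
    floor = ETA_EFF_FLOOR_FRACTION * params.eta
    if np.any(eta_eff <= floor):
        raise EffectiveViscosityFloorError(
            f"eta_eff <= {floor:g} Pa·s (floor {ETA_EFF_FLOOR_FRACTION}·eta); "
            "zeta too large for the early-phase approximation"
        )
    return eta_eff if eta_eff.ndim else float(eta_eff)


def pore_opening_rate(params: GelParams, R: float | np.ndarray):
    """Signed pore edge speed dR/dt, m/s; positive = opening."""
    eta_eff = effective_viscosity(params, R)
    R = np.asarray(R, dtype=float)
    drive = (params.sigma0 + 2.0 * params.f_adh * params.R_L / 3.0) * R
    rate = (drive - 2.0 * params.gamma) / eta_eff
    return rate if rate.ndim else float(rate)


def critical_radius(params: GelParams) -> float:
    """Unstable fixed point R_c = 6γ / (3σ0 + 2 f_adh R_L), m.

    May exceed R_L, in which case no pore can open for these parameters.
    """
    denom = 3.0 * params.sigma0 + 2.0 * params.f_adh * params.R_L
    if denom <= 0:
        raise ValueError(
            "3·sigma0 + 2·f_adh·R_L must be > 0 for a finite critical radius"
        )
    return 6.0 * params.gamma / denom


def critical_adhesion(params: GelParams, R_init: float) -> float:
    """Adhesive force density at which R_c equals ``R_init``, N/m³.

    Returns (6γ/R_init − 3σ0) / (2 R_L), clamped at 0 when the
    contractile stress alone suffices to open a pore of that size.
    """
    if R_init <= 0:
        raise ValueError("R_init must be > 0")
    f = (6.0 * params.gamma / R_init - 3.0 * params.sigma0) / (2.0 * params.R_L)
    return max(f, 0.0)


def classify_regime(params: GelParams, R_probe: float) -> FixedPointAnalysis:
    """Classify the fate of a pore of initial radius ``R_probe``."""
    R_c = critical_radius(params)
    rate = pore_opening_rate(params, R_probe)
    if abs(R_probe - R_c) <= 1e-12 * max(R_c, params.R_L) or rate == 0.0:
        regime = "stalls"
        stable = None
    elif rate > 0:
        regime = "opens_to_rupture"
        stable = params.R_L
    else:
        regime = "seals"
        stable = 0.0
    return FixedPointAnalysis(R_c=R_c, stable_radius=stable, regime=regime)


def simulate_pore(params: GelParams, R_init: float,
                  t_grid: np.ndarray) -> PoreTrajectory:
    """Integrate dR/dt over ``t_grid`` from ``R_init``.

    Adaptive embedded Runge–Kutta (rtol 1e-8, atol 1e-12 m) with event
    detection at R = R_L and R = 0; past a terminal event the radius is
    held at the terminal value so the output grid is always honoured.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be 1-D, strictly increasing, length >= 2")
    if not (0.0 < R_init < params.R_L):
        raise ValueError("R_init must satisfy 0 < R_init < R_L")
    effective_viscosity(params, R_init)  # validate floor at start

    R_c = critical_radius(params)
    if math.isclose(R_init, R_c, rel_tol=1e-12, abs_tol=0.0):
        # degenerate fixed-point input: constant trajectory
        return PoreTrajectory(t_grid, np.full_like(t_grid, R_init),
                              terminated=False)

    def rhs(t, y):
        R = min(max(y[0], 0.0), params.R_L)
        try:
            return [pore_opening_rate(params, R)]
        except EffectiveViscosityFloorError as err:
            raise EffectiveViscosityFloorError(
                f"{err} (at t = {t:g} s)") from None

    def hit_RL(t, y):
        return y[0] - params.R_L
    hit_RL.terminal = True
    hit_RL.direction = 1

    def hit_zero(t, y):
        return y[0]
    hit_zero.terminal = True
    hit_zero.direction = -1

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [R_init],
                    t_eval=t_grid, rtol=1e-8, atol=1e-12,
                    events=(hit_RL, hit_zero), dense_output=False,
                    method="RK45")
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"pore integration failed: {sol.message}")

    radii = np.interp(t_grid, sol.t, sol.y[0]) if sol.t.size else np.array([])
    terminated = sol.status == 1
    if terminated:
        # hold at the terminal radius past the event time
        t_event = (sol.t_events[0][0] if sol.t_events[0].size
                   else sol.t_events[1][0])
        terminal_R = params.R_L if sol.t_events[0].size else 0.0
        radii = np.where(t_grid >= t_event, terminal_R, radii)
    radii = np.clip(radii, 0.0, params.R_L)
    return PoreTrajectory(t_grid, radii, terminated=terminated)


def simulate_rupture_trace(params: GelParams, R_init: float = 1e-6,
                           n_pts: int = 200, margin: float = 1.2,
                           t_max: float = 4000.0) -> PoreTrajectory:
    """Standard rupture-window trace: simulate until the pore reaches the
    contact radius, then resample 0..margin×T_rupture on ``n_pts``.

    This mimics how an experimental pore-radius trace is recorded —
    through the opening and a short saturated tail — and is the frozen
    protocol behind the reported opening timescales.
    """
    probe = simulate_pore(params, R_init, np.linspace(0.0, t_max, int(t_max)))
    reached = probe.radii >= 0.995 * params.R_L
    if not np.any(reached):
        raise RuntimeError(
            "pore did not reach the contact radius within t_max; "
            "parameters are in the sealing or stalled regime"
        )
    T = max(float(probe.times[np.argmax(reached)]), 10.0)
    grid = np.linspace(0.0, margin * T, n_pts)
    return simulate_pore(params, R_init, grid)


def phase_diagram(params: GelParams, f_adh_grid: np.ndarray,
                  R_grid: np.ndarray) -> dict:
    """Regime map over (f_adh, R): sign of dR/dt on each grid point.

    Returns a dict with ``labels`` (2-D array of {'seals','opens',
    'stalls'}, shape (len(f_adh_grid), len(R_grid))), the unstable
    fixed-point curve ``R_c`` per f_adh, and the stable radius R_L.
    """
    f_adh_grid = np.asarray(f_adh_grid, dtype=float)
    R_grid = np.asarray(R_grid, dtype=float)
    if f_adh_grid.size == 0 or R_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(R_grid < 0) or np.any(R_grid > params.R_L):
        raise ValueError("R_grid must lie within [0, R_L]")
    labels = np.empty((f_adh_grid.size, R_grid.size), dtype=object)
    R_c_curve = np.empty(f_adh_grid.size)
    for i, f in enumerate(f_adh_grid):
        p = params.replace(f_adh=float(f))
        R_c_curve[i] = critical_radius(p)
        rates = pore_opening_rate(p, R_grid)
        labels[i] = np.where(rates > 0, "opens",
                             np.where(rates < 0, "seals", "stalls"))
    return {
        "f_adh": f_adh_grid,
        "R": R_grid,
        "labels": labels,
        "R_c": R_c_curve,
        "stable_radius": params.R_L,
    }
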