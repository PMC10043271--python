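"""Length-scale hypothesis calculators.

Two candidate mechanisms can localise actin polymerization near the
contact line of an adherent liposome:

1. Mechanosensing — membrane tension propagates stress to the actin
   nucleators over the bendo-capillary length L_b = √(k_b/γ), the
   distance over which membrane bending matters near a contact line.
2. Reaction–diffusion — ATP permeating at the contact line penetrates a
   Thiele length L_Th = √(D/k) before being consumed by first-order
   actin–ATP reactions.

Comparing L_b and L_Th against the observed localisation distance
L_obs (~2 µm) discriminates between the mechanisms: L_b in the tens of
nanometres rules out tension propagation, while L_Th of 1–10 µm is
compatible with diffusion-limited polymerization.

Also provides the myosin thick-filament force/tension estimates used to
benchmark the active-stress contribution to membrane tension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

__all__ = [
    "MembraneMechanics",
    "ReactionDiffusion",
    "MotorEstimate",
    "bendocapillary_length",
    "thiele_length",
    "thick_filament_force",
    "filament_tension_contribution",
    "round_to_order",
    "hypothesis_report",
    "DEFAULT_MECHANICS",
    "DEFAULT_REACTION_DIFFUSION",
]

Bracket = tuple[float, float]
Scalar = float


def _as_bracket(x: Union[Scalar, Bracket]) -> Bracket:
    if isinstance(x, (tuple, list)):
        lo, hi = float(x[0]), float(x[1])
    else:
        lo = hi = float(x)
    if not (lo > 0 and hi > 0):
        raise ValueError(f"values must be positive, got {x!r}")
    if lo > hi:
        raise ValueError(f"bracket min must not exceed max, got {x!r}")
    return lo, hi


@dataclass(frozen=True)
class MembraneMechanics:
    """Bending stiffness k_b (J) and surface tension γ (N/m or bracket)."""

    k_b: float
    gamma: Union[Scalar, Bracket]

    def __post_init__(self):
        if self.k_b <= 0:
            raise ValueError("k_b must be > 0")
        _as_bracket(self.gamma)


@dataclass(frozen=True)
class ReactionDiffusion:
    """ATP diffusivity D (m²/s) and reaction rate k (1/s); brackets allowed."""

    D: Union[Scalar, Bracket]
    k: Union[Scalar, Bracket]

    def __post_init__(self):
        _as_bracket(self.D)
        _as_bracket(self.k)


@dataclass(frozen=True)
class MotorEstimate:
    """Per-filament force and its tension contribution on a liposome."""

    n_bound: int
    f_single: float
    F_filament: float
    R_L: float
    tension_contribution: float


# Defaults. k_b is the bending stiffness of an actin-coated membrane
# (~100x a bare bilayer); the tension bracket is the lysis-tension range
# measured by micropipette-type methods. D and k are literature-scale
# values for ATP diffusing in a dense actin network and pseudo-first-
# order actin–ATP consumption (the source study's exact supplementary
# values are not public).
DEFAULT_MECHANICS = MembraneMechanics(k_b=4e-18, gamma=(0.3e-3, 5.0e-3))
DEFAULT_REACTION_DIFFUSION = ReactionDiffusion(D=1e-10, k=(1.0, 100.0))


def bendocapillary_length(mech: MembraneMechanics):
    """L_b = √(k_b/γ), m.

    For a tension bracket returns (√(k_b/γ_max), √(k_b/γ_min)) — high
    tension gives the short end of the bracket.
    """
    lo, hi = _as_bracket(mech.gamma)
    if lo == hi:
        return math.sqrt(mech.k_b / lo)
    return math.sqrt(mech.k_b / hi), math.sqrt(mech.k_b / lo)


def thiele_length(rd: ReactionDiffusion):
    """L_Th = √(D/k), m; brackets propagated to (min, max)."""
    D_lo, D_hi = _as_bracket(rd.D)
    k_lo, k_hi = _as_bracket(rd.k)
    lo = math.sqrt(D_lo / k_hi)
    hi = math.sqrt(D_hi / k_lo)
    if lo == hi:
        return lo
    return lo, hi


def thick_filament_force(n_bound: int, f_single: float) -> float:
    """Force from one myosin thick filament: n_bound × f_single, N.

    With the commonly quoted ~12 simultaneously bound dimers at ~3.4 pN
    per motor this gives ~40.8 pN (often rounded to ~44 pN in the
    literature).
    """
    if n_bound < 1:
        raise ValueError("n_bound must be >= 1")
    if f_single <= 0:
        raise ValueError("f_single must be > 0")
    return n_bound * f_single


def filament_tension_contribution(F: float, R_L: float) -> float:
    """Tension contribution F/(2π R_L) of a filament force spread over
    the contact perimeter, N/m."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if R_L <= 0:
        raise ValueError("R_L must be > 0")
    return F / (2.0 * math.pi * R_L)


def round_to_order(x: float) -> float:
    """Order-of-magnitude rounding helper: returns 10^round(log10 x)."""
    if x <= 0:
        raise ValueError("x must be > 0")
    return 10.0 ** round(math.log10(x))


def motor_estimate(n_bound: int = 12, f_single: float = 3.4e-12,
                   R_L: float = 1e-5) -> MotorEstimate:
    """Bundle the thick-filament force and tension estimates."""
    F = thick_filament_force(n_bound, f_single)
    return MotorEstimate(
        n_bound=n_bound, f_single=f_single, F_filament=F, R_L=R_L,
        tension_contribution=filament_tension_contribution(F, R_L),
    )


def hypothesis_report(L_b, L_Th, L_obs: float) -> dict:
    """Structured verdict comparing candidate length scales with L_obs.

    ``mechanosensing_supported`` requires the bendo-capillary length to
    reach the observation scale (L_b ≥ L_obs, boundary inclusive; for a
    bracket, the upper endpoint is used — the most favourable case).
    ``reaction_diffusion_supported`` requires L_obs to fall within the
    L_Th bracket (inclusive), or within one order of magnitude of a
    scalar L_Th.
    """
    if L_obs <= 0:
        raise ValueError("L_obs must be > 0")
    Lb_lo, Lb_hi = _as_bracket(L_b)
    mechano = Lb_hi >= L_obs

    LTh_lo, LTh_hi = _as_bracket(L_Th)
    if LTh_lo == LTh_hi:
        rd_ok = LTh_lo / 10.0 <= L_obs <= LTh_lo * 10.0
    else:
        rd_ok = LTh_lo <= L_obs <= LTh_hi
    return {
        "L_b_m": (Lb_lo, Lb_hi),
        "L_Th_m": (LTh_lo, LTh_hi),
        "L_obs_m": L_obs,
        "ratio_Lb_over_Lobs": Lb_hi / L_obs,
        "ratio_LTh_over_Lobs": (LTh_lo / L_obs, LTh_hi / L_obs),
        "mechanosensing_supported": bool(mechano),
        "reaction_diffusion_supported": bool(rd_ok),
    }
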