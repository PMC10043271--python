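"""Parameter container for the membrane–actomyosin active-gel model.

All quantities are SI. The gel is described as a thin composite layer
(membrane + cortical actin) characterised by a bulk viscosity ``eta``,
a contractile active stress ``sigma0`` at the reference density, a
density-stress coupling ``zeta`` (derivative of net gel stress, active
minus pressure, with respect to density at the reference density), an
actin turnover time ``tau_a``, substrate friction ``Gamma``, adhesive
force density ``f_adh``, and membrane tension ``gamma`` acting at the
pore boundary. Density is stored normalised to its reference value, so
``rho0 == 1`` by convention and ``zeta`` carries units of stress (Pa).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["GelParams", "preset", "PRESETS", "DEFAULT_R_INIT"]

_FIELDS_SI = ("eta", "Gamma", "sigma0", "zeta", "rho0", "tau_a",
              "gamma", "f_adh", "R_L", "d")


@dataclass(frozen=True)
class GelParams:
    """Full parameter vector of the active-gel membrane–cortex model.

    Parameters
    ----------
    eta : float
        Composite cortex/membrane viscosity, Pa·s.
    Gamma : float
        Friction coefficient with the substrate, Pa·s/m².
    sigma0 : float
        Contractile active stress at the reference density, Pa.
    zeta : float
        d(σ_a − P)/dρ at ρ = ρ0 (ρ normalised to ρ0), Pa. Negative for
        a pure actin layer (density stiffens the gel), positive when
        myosin is present (density amplifies contractility, which
        fluidises the layer).
    rho0 : float
        Reference actin density, dimensionless (normalised to 1).
    tau_a : float
        Actin turnover time, s.
    gamma : float
        Membrane tension at the pore boundary, N/m.
    f_adh : float
        Adhesive force density, N/m³.
    R_L : float
        Liposome contact radius, m.
    d : float
        Actin layer thickness, m (reporting only; enters σ_a·d).
    """

    eta: float
    Gamma: float = 0.0
    sigma0: float = 0.0
    zeta: float = 0.0
    rho0: float = 1.0
    tau_a: float = 100.0
    gamma: float = 1e-4
    f_adh: float = 0.0
    R_L: float = 1e-5
    d: float = 1e-7

    def __post_init__(self) -> None:
        vals = asdict(self)
        for k, v in vals.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"GelParams.{k} must be finite, got {v!r}")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.Gamma < 0:
            raise ValueError("Gamma must be >= 0")
        if self.tau_a <= 0:
            raise ValueError("tau_a must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.f_adh < 0:
            raise ValueError("f_adh must be >= 0")
        if self.R_L <= 0:
            raise ValueError("R_L must be > 0")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be > 0")
        if self.d <= 0:
            raise ValueError("d must be > 0")

    def replace(self, **kw) -> "GelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GelParams":
        unknown = set(data) - set(_FIELDS_SI)
        if unknown:
            raise ValueError(f"unknown GelParams keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def save(self, path: str | Path) -> None:
        """Write to YAML (.yml/.yaml) or JSON, keys exactly the SI fields."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


# Preset parameter sets for the three liposome compositions.
#
# The study's supplementary fitted values are not public, so these are
# package defaults with literature-scale magnitudes (cortex viscosity
# 1e3–1e4 Pa·s, membrane tension 0.1 mN/m, turnover 100 s, layer
# thickness 100 nm, adhesion in the strong-adhesion regime where the
# critical pore radius is sub-micron), calibrated once so that the
# simulated pore-opening traces fit to the experimentally reported
# timescales: ~20 s (bare), ~80 s (actin), ~20 s (actomyosin).
# See docs/methods.md. Do not tune these.
_COMMON = dict(Gamma=1.3e15, rho0=1.0, tau_a=100.0, gamma=1e-4,
               f_adh=1e8, R_L=1e-5, d=1e-7)

#: Initial pore radius used by the standard rupture-trace protocol, m.
DEFAULT_R_INIT = 1e-6

PRESETS: dict[str, GelParams] = {
    "bare_liposome": GelParams(eta=5600.0, sigma0=0.0, zeta=0.0, **_COMMON),
    "actin_liposome": GelParams(eta=6140.0, sigma0=0.0, zeta=-898.0,
                                **_COMMON),
    "actomyosin_liposome": GelParams(eta=6140.0, sigma0=1.0, zeta=58.0,
                                     **_COMMON),
}


def preset(name: str) -> GelParams:
    """Return a named preset parameter set.

    Available: ``bare_liposome``, ``actin_liposome``,
    ``actomyosin_liposome``.
    """
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
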