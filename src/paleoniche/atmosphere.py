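"""Humid-air density, Sutherland viscosity, and CFD field-condition sets.

Density follows Dalton's law of partial pressures: the moist-air density is
the sum of the dry-air and water-vapour partial densities,

    rho = (P - Pv) / (R_d * T) + Pv / (R_v * T)

with R_d = 287.1 J/(kg K) and R_v = 461.5 J/(kg K).  Because R_v > R_d,
adding vapour at fixed total pressure lowers the density.  Dynamic viscosity
follows Sutherland's law with S = 110.4 K:

    mu = mu_ref * (T / T_ref)^(3/2) * (T_ref + S) / (T + S)

The reference point mu_ref = 1.716e-5 Pa s at T_ref = 273.15 K is the
standard air reference.  These quantities parameterise the flow domain of
flapping-flight simulations; the solver itself is outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AtmosphericConstants", "DEFAULT_CONSTANTS",
    "air_density", "air_viscosity", "field_condition_sets",
    "hpa_to_pa", "pa_to_hpa", "celsius_to_kelvin", "kelvin_to_celsius",
]


@dataclass(frozen=True)
class AtmosphericConstants:
    Rg_d: float = 287.1        # dry-air gas constant, J/(kg K)
    Rg_v: float = 461.5        # water-vapour gas constant, J/(kg K)
    S: float = 110.4           # Sutherland temperature, K
    mu_ref: float = 1.716e-5   # reference viscosity, Pa s
    T_ref: float = 273.15      # reference temperature, K

    def __post_init__(self):
        for f in ("Rg_d", "Rg_v", "S", "mu_ref", "T_ref"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


DEFAULT_CONSTANTS = AtmosphericConstants()


def air_density(P, Pv, T, constants: AtmosphericConstants = DEFAULT_CONSTANTS):
    """Moist-air density (kg/m^3) from total pressure, vapour pressure (Pa), T (K)."""
    P = np.asarray(P, dtype=float)
    Pv = np.asarray(Pv, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    if np.any(Pv < 0) or np.any(Pv >= P):
        raise ValueError("vapour pressure must satisfy 0 <= Pv < P")
    rho = (P - Pv) / (constants.Rg_d * T) + Pv / (constants.Rg_v * T)
    return float(rho) if rho.ndim == 0 else rho


def air_viscosity(T, constants: AtmosphericConstants = DEFAULT_CONSTANTS):
    """Dynamic viscosity of air (Pa s) by Sutherland's law."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    c = constants
    mu = c.mu_ref * (T / c.T_ref) ** 1.5 * (c.T_ref + c.S) / (T + c.S)
    return float(mu) if mu.ndim == 0 else mu


def hpa_to_pa(x):
    return np.asarray(x, dtype=float) * 100.0


def pa_to_hpa(x):
    return np.asarray(x, dtype=float) / 100.0


def celsius_to_kelvin(x):
    return np.asarray(x, dtype=float) + 273.15


def kelvin_to_celsius(x):
    return np.asarray(x, dtype=float) - 273.15


def derive_records(records: pd.DataFrame,
                   constants: AtmosphericConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Add rho and mu columns to a table with columns P, Pv, T, v (SI units)."""
    out = records.copy()
    out["rho"] = air_density(out["P"].to_numpy(), out["Pv"].to_numpy(),
                             out["T"].to_numpy(), constants)
    out["mu"] = air_viscosity(out["T"].to_numpy(), constants)
    return out


def field_condition_sets(records: pd.DataFrame,
                         constants: AtmosphericConstants = DEFAULT_CONSTANTS) -> dict:
    """Build the flow-domain condition sets from habitat atmospheric records.

    Six transient sets pair the extreme (max or min) of one of wind speed v,
    density rho, or viscosity mu with the means of the other two; the steady
    set uses mean v and mu with the minimum rho (the adverse low-density
    case).  A min/mean/max summary table per variable is included.
    """
    if len(records) == 0:
        raise ValueError("no atmospheric records supplied")
    rec = derive_records(records, constants) if "rho" not in records else records
    vars3 = ["v", "rho", "mu"]
    stats = {k: {"min": float(rec[k].min()), "mean": float(rec[k].mean()),
                 "max": float(rec[k].max())} for k in vars3}
    transient = []
    for var in vars3:
        for extreme in ("max", "min"):
            cond = {k: stats[k]["mean"] for k in vars3}
            cond[var] = stats[var][extreme]
            transient.append({"extreme_variable": var, "extreme": extreme, **cond})
    steady = {"v": stats["v"]["mean"], "mu": stats["mu"]["mean"],
              "rho": stats["rho"]["min"]}
    return {"transient": transient, "steady": steady, "summary": stats}
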