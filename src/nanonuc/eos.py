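"""Redlich-Kwong equation of state for the droplet liquid.

Provides isotherms, the liquid-branch spinodal, and the empirical
liquid-density and macroscopic-surface-tension correlations used by the
nucleation model.  All quantities are SI; molar volumes in m^3/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import R_GAS
from .errors import CovolumeError, SupercriticalError

OMEGA_A = 0.42748
OMEGA_B = 0.08664

# Corresponding-states constants of perfluoropentane (C5F12).
_PFP = dict(
    name="PFP",
    Tc=420.0,                  # K
    Pc_crit=2.045e6,           # Pa
    molar_mass=0.28803,        # kg/mol (C5F12; not printed in source data)
    rho_ref=759.53,            # kg/m^3
    density_coeffs=(-0.425, 8.191, -17.91, 19.63, -10.92, 2.655),
    sigma_coeff_A=0.0425,      # N/m
    critical_exponent_v=0.6,
    Psat=135e3,                # Pa at 310 K
)


@dataclass(frozen=True)
class FluidProperties:
    """Thermophysical constants of the volatile droplet liquid.

    ``Psat`` is the saturation vapor pressure at the working temperature;
    it is treated as a user input, not derived from the equation of state
    (see :func:`saturation_pressure_maxwell` for the optional construction).
    """

    name: str = "fluid"
    Tc: float = 0.0
    Pc_crit: float = 0.0
    molar_mass: float = 0.0
    rho_ref: float = 0.0
    density_coeffs: tuple[float, ...] = ()
    sigma_coeff_A: float = 0.0
    critical_exponent_v: float = 0.0
    Psat: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("Tc", "Pc_crit", "molar_mass", "rho_ref"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)!r}")

    @classmethod
    def pfp(cls, **overrides) -> "FluidProperties":
        """Perfluoropentane preset (working temperature 310 K)."""
        params = dict(_PFP)
        params.update(overrides)
        return cls(**params)

    def with_psat(self, psat: float) -> "FluidProperties":
        """Copy of this fluid with a different saturation pressure."""
        return replace(self, Psat=float(psat))


@dataclass(frozen=True)
class EOSIsotherm:
    """Sampled pressure-volume isotherm with its liquid spinodal point."""

    T: float
    V: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    spinodal_V: float = float("nan")
    spinodal_P: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T_K": self.T, "V_m3_per_mol": self.V, "P_Pa": self.P})


def rk_parameters(fluid: FluidProperties) -> tuple[float, float]:
    """Attraction and covolume parameters (a, b) from the critical point."""
    a = OMEGA_A * R_GAS**2 * fluid.Tc**2 / fluid.Pc_crit
    b = OMEGA_B * R_GAS * fluid.Tc / fluid.Pc_crit
    return a, b


def rk_pressure(V, T: float, fluid: FluidProperties):
    """Pressure (Pa) at molar volume ``V`` and temperature ``T``.

    Accepts scalar or array ``V``; raises :class:`CovolumeError` if any
    volume lies at or inside the covolume.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    a, b = rk_parameters(fluid)
    V = np.asarray(V, dtype=float)
    if np.any(V <= b):
        raise CovolumeError("molar volume inside covolume (V <= b)")
    alpha = (T / fluid.Tc) ** -0.5
    P = R_GAS * T / (V - b) - a * alpha / (V * (V + b))
    return float(P) if P.ndim == 0 else P


def _dPdV(V, T: float, fluid: FluidProperties):
    a, b = rk_parameters(fluid)
    alpha = (T / fluid.Tc) ** -0.5
    V = np.asarray(V, dtype=float)
    d = -R_GAS * T / (V - b) ** 2 + a * alpha * (2 * V + b) / (V * (V + b)) ** 2
    return float(d) if d.ndim == 0 else d


def liquid_spinodal(T: float, fluid: FluidProperties) -> tuple[float, float]:
    """Liquid-branch spinodal: the smallest-V local minimum of P(V).

    Returns ``(Vsp, Psp)``.  Brackets the first sign change of dP/dV on a
    log-spaced volume grid and refines it by Brent's method.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if T >= fluid.Tc:
        raise SupercriticalError(f"T = {T} K >= Tc = {fluid.Tc} K: no spinodal")
    _, b = rk_parameters(fluid)
    grid = np.geomspace(1.01 * b, 50 * b, 4096)
    slope = _dPdV(grid, T, fluid)
    sign_change = np.nonzero((slope[:-1] < 0) & (slope[1:] >= 0))[0]
    if sign_change.size == 0:
        raise SupercriticalError(f"no liquid-branch minimum found at T = {T} K")
    i = sign_change[0]
    Vsp = brentq(_dPdV, grid[i], grid[i + 1], args=(T, fluid), rtol=1e-14)
    return Vsp, rk_pressure(Vsp, T, fluid)


def spinodal_line(T_values, fluid: FluidProperties) -> pd.DataFrame:
    """Per-temperature spinodal table with columns T_K, V_m3_per_mol, P_Pa."""
    rows = []
    for T in T_values:
        Vsp, Psp = liquid_spinodal(float(T), fluid)
        rows.append({"T_K": float(T), "V_m3_per_mol": Vsp, "P_Pa": Psp})
    return pd.DataFrame(rows, columns=["T_K", "V_m3_per_mol", "P_Pa"])


def isotherm(T: float, fluid: FluidProperties, n: int = 2000,
             v_span: tuple[float, float] = (1.01, 50.0)) -> EOSIsotherm:
    """Sampled isotherm over ``v_span`` (in units of the covolume b)."""
    _, b = rk_parameters(fluid)
    V = np.geomspace(v_span[0] * b, v_span[1] * b, n)
    P = rk_pressure(V, T, fluid)
    if T < fluid.Tc:
        Vsp, Psp = liquid_spinodal(T, fluid)
    else:
        Vsp = Psp = float("nan")
    return EOSIsotherm(T=T, V=V, P=P, spinodal_V=Vsp, spinodal_P=Psp)


def liquid_density(T: float, fluid: FluidProperties) -> float:
    """Liquid density (kg/m^3) from the cube-root power-series correlation."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if T > fluid.Tc:
        raise ValueError(f"T = {T} K above Tc = {fluid.Tc} K")
    x = 1.0 - T / fluid.Tc
    series = sum(Bi * x ** ((i + 1) / 3) for i, Bi in enumerate(fluid.density_coeffs))
    return fluid.rho_ref * (1.0 + series)


def macroscopic_surface_tension(T: float, fluid: FluidProperties) -> float:
    """Flat-interface surface tension sigma_inf = A (1 - T/Tc)^(2v)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if T > fluid.Tc:
        raise ValueError(f"T = {T} K above Tc = {fluid.Tc} K")
    return fluid.sigma_coeff_A * (1.0 - T / fluid.Tc) ** (2 * fluid.critical_exponent_v)


def saturation_pressure_maxwell(T: float, fluid: FluidProperties) -> float:
    """Equal-area (Maxwell) saturation pressure from the equation of state.

    Optional utility; the model otherwise uses the user-supplied ``Psat``.
    """
    if T >= fluid.Tc:
        raise SupercriticalError("no coexistence above Tc")
    a, b = rk_parameters(fluid)
    alpha = (T / fluid.Tc) ** -0.5

    def antideriv(V):
        # indefinite integral of the pressure along the isotherm
        return R_GAS * T * np.log(V - b) - (a * alpha / b) * np.log(V / (V + b))

    def cubic_roots(P):
        # P V^3 - RT V^2 + (a*alpha - b RT - P b^2) V - a*alpha*b = 0
        coeffs = [P, -R_GAS * T, a * alpha - b * R_GAS * T - P * b**2, -a * alpha * b]
        roots = np.roots(coeffs)
        real = np.sort(roots[np.abs(roots.imag) < 1e-9 * np.abs(roots).max()].real)
        return real[real > b]

    def area_mismatch(P):
        roots = cubic_roots(P)
        Vl, Vv = roots[0], roots[-1]
        return antideriv(Vv) - antideriv(Vl) - P * (Vv - Vl)

    # Bracket between just above zero pressure and just below the
    # vapor-branch local maximum of the isotherm.
    grid = np.geomspace(1.01 * b, 500 * b, 8192)
    P_iso = rk_pressure(grid, T, fluid)
    dP = np.diff(P_iso)
    peaks = np.nonzero((dP[:-1] > 0) & (dP[1:] <= 0))[0] + 1
    if peaks.size == 0:
        raise SupercriticalError("isotherm has no van der Waals loop")
    _, Psp_liq = liquid_spinodal(T, fluid)
    lo = max(Psp_liq, 0.0) + 1e-9 * fluid.Pc_crit
    hi = 0.999 * float(P_iso[peaks[-1]])
    return brentq(area_mismatch, lo, hi, rtol=1e-12)
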