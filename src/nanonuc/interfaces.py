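"""Pressure bookkeeping at the bubble/droplet/tissue interfaces.

Covers the Laplace pressure of the confined droplet, Henry's-law partial
pressure of dissolved gases, the series (harmonic) modulus of the
droplet-tissue spring pair, the elastic back-pressure of a growing bubble,
the metastability degree of the stretched liquid, and the resulting
effective surface tension of the vapor embryo.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from . import eos
from .constants import P_ATM
from .errors import BeyondSpinodalError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GasSpecies:
    """A dissolved non-condensable gas with Henry's-law volatility constant."""

    name: str
    Ki: float   # volatility constant, Pa per unit concentration
    Cgi: float  # dissolved concentration, dimensionless

    def __post_init__(self) -> None:
        if self.Ki < 0 or self.Cgi < 0:
            raise ValueError("Ki and Cgi must be non-negative")


def oxygen() -> GasSpecies:
    return GasSpecies("O2", Ki=4.9e6, Cgi=0.07)


def carbon_dioxide() -> GasSpecies:
    return GasSpecies("CO2", Ki=7.2e5, Cgi=0.3)


def default_gases() -> tuple[GasSpecies, ...]:
    """Dissolved-gas content of the baseline droplet: O2 + CO2."""
    return (oxygen(), carbon_dioxide())


@dataclass(frozen=True)
class DropletConfig:
    """Geometry, interface and bulk properties of the liquid droplet."""

    R20: float = 140e-9        # initial radius, m
    sigma2: float = 56e-3      # droplet-tissue interfacial tension, N/m
    T0: float = 310.0          # K
    K2: float = 2.2e9          # droplet bulk modulus, Pa
    gases: tuple[GasSpecies, ...] = field(default_factory=default_gases)
    laplace_factor: float = 1.0  # 1 -> sigma2/R20; 2 -> conventional 2*sigma2/R20

    def __post_init__(self) -> None:
        if self.R20 <= 0:
            raise ValueError("R20 must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.K2 <= 0:
            raise ValueError("K2 must be positive")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")

    @property
    def V20(self) -> float:
        """Initial droplet volume, m^3."""
        return 4.0 * math.pi * self.R20**3 / 3.0


@dataclass(frozen=True)
class TissueConfig:
    """Elastic confinement of the surrounding tissue."""

    K3: float = 0.0      # tissue bulk modulus, Pa
    Pc_conf: float = 0.0  # optional static confinement pressure, Pa

    def __post_init__(self) -> None:
        if self.K3 < 0:
            raise ValueError("K3 must be non-negative")

    @classmethod
    def from_shear_modulus(cls, G: float, Pc_conf: float = 0.0) -> "TissueConfig":
        """Linear-elastic conversion K3 = 4G/3."""
        return cls(K3=4.0 * G / 3.0, Pc_conf=Pc_conf)


@dataclass(frozen=True)
class PressureState:
    """Snapshot of the pressure decomposition at one drive amplitude."""

    P0: float
    Plap: float
    Pat: float
    Pc_conf: float
    P2wo: float
    Pv1: float
    Pg1: float
    P1: float
    K: float


def laplace_pressure(R20: float, sigma2: float, factor: float = 1.0) -> float:
    """Laplace pressure of the resting droplet, ``factor * sigma2 / R20``.

    The model's convention is ``factor = 1``.
    """
    if R20 <= 0:
        raise ValueError("R20 must be positive")
    return factor * sigma2 / R20


def gas_partial_pressure(gases) -> float:
    """Total Henry's-law partial pressure of the dissolved gases, Pa."""
    total = 0.0
    for gas in gases:
        if gas.Ki < 0 or gas.Cgi < 0:
            raise ValueError("gas constants must be non-negative")
        total += gas.Ki * gas.Cgi
    return total


def series_modulus(K2: float, K3: float) -> float:
    """Harmonic (springs-in-series) modulus K2*K3/(K2+K3)."""
    if K2 <= 0:
        raise ValueError("K2 must be positive")
    if K3 < 0:
        raise ValueError("K3 must be non-negative")
    if K3 == 0:
        return 0.0
    return K2 * K3 / (K2 + K3)


def elastic_back_pressure(R1: float, R20: float, K: float) -> float:
    """Liquid-pressure rise K*(R1/R20)^3 caused by a bubble of radius R1."""
    if R1 < 0:
        raise ValueError("R1 must be non-negative")
    if R20 <= 0:
        raise ValueError("R20 must be positive")
    return K * (R1 / R20) ** 3


def resting_liquid_pressure(droplet: DropletConfig, tissue: TissueConfig,
                            Pat: float = 0.0, P0: float = P_ATM) -> float:
    """Bubble-free liquid pressure P2wo = P0 + Plap + Pat + Pc_conf."""
    Plap = laplace_pressure(droplet.R20, droplet.sigma2, droplet.laplace_factor)
    return P0 + Plap + Pat + tissue.Pc_conf


def pressure_state(droplet: DropletConfig, tissue: TissueConfig, Pat: float = 0.0,
                   P0: float = P_ATM, Pv1: float | None = None,
                   include_gas: bool = True,
                   fluid: eos.FluidProperties | None = None) -> PressureState:
    """Assemble the full pressure decomposition for one drive amplitude."""
    if fluid is None:
        fluid = eos.FluidProperties.pfp()
    if Pv1 is None:
        Pv1 = fluid.Psat
    Plap = laplace_pressure(droplet.R20, droplet.sigma2, droplet.laplace_factor)
    Pg1 = gas_partial_pressure(droplet.gases) if include_gas else 0.0
    return PressureState(
        P0=P0, Plap=Plap, Pat=Pat, Pc_conf=tissue.Pc_conf,
        P2wo=P0 + Plap + Pat + tissue.Pc_conf,
        Pv1=Pv1, Pg1=Pg1, P1=Pv1 + Pg1,
        K=series_modulus(droplet.K2, tissue.K3),
    )


def metastability_delta(P2: float, T: float, fluid: eos.FluidProperties,
                        psat: float | None = None,
                        pspin: float | None = None) -> float:
    """Degree of liquid metastability delta = (Psat - P2)/(Psat - Pspin).

    0 at saturation, 1 at the spinodal.  Values >= 1 raise
    :class:`BeyondSpinodalError`; negative values (compressed liquid) are
    allowed but logged.
    """
    if psat is None:
        psat = fluid.Psat
    if pspin is None:
        _, pspin = eos.liquid_spinodal(T, fluid)
    delta = (psat - P2) / (psat - pspin)
    if delta > 1.0:
        raise BeyondSpinodalError(
            f"P2 = {P2:.6g} Pa below the spinodal ({pspin:.6g} Pa): "
            "spontaneous spinodal decomposition regime")
    if delta < 0.0:
        logger.warning("compressed liquid: delta = %.4g < 0 at P2 = %.6g Pa", delta, P2)
    return delta


def effective_surface_tension(P2: float, T: float, fluid: eos.FluidProperties,
                              psat: float | None = None,
                              pspin: float | None = None) -> float:
    """Metastability-scaled bubble surface tension.

    sigma1 = sigma_inf(T) * phi^(1/3) with phi = (1 - delta)(1 + delta/2)^2.
    """
    delta = metastability_delta(P2, T, fluid, psat=psat, pspin=pspin)
    if delta >= 1.0:
        raise BeyondSpinodalError("delta >= 1: surface tension undefined at/beyond "
                                  "the spinodal")
    phi = (1.0 - delta) * (1.0 + 0.5 * delta) ** 2
    return eos.macroscopic_surface_tension(T, fluid) * phi ** (1.0 / 3.0)
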