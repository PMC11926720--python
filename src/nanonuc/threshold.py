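"""Initial-nucleation-threshold (INT) solver and parameter sweeps.

The INT is the magnitude of the rarefactional acoustic pressure at which
the probability of nucleating the first vapor bubble in the droplet
reaches 50% within the time window tau = 1/(tau_divisor * f).  The solver
bisects on the (negative) acoustic pressure; the bracket is bounded below
by the spinodal of the stretched liquid, which guarantees a sign change
whenever a threshold exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from . import energetics, eos, interfaces
from .constants import P_ATM
from .errors import (BeyondSpinodalError, ConvergenceError,
                     NoNucleationDriveError, SuperStabilizedError)

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ThresholdResult:
    """Converged INT solution with the full state at threshold."""

    P_INT: float                 # threshold magnitude, Pa (>= 0)
    Pat_star: float              # signed acoustic pressure at threshold, Pa (<= 0)
    P2_at_threshold: float       # liquid pressure at nucleation, Pa
    sigma1_at_threshold: float   # N/m
    R1wo_star: float             # m
    gamma_at_threshold: float
    Sigma: float                 # nucleation probability at Pat_star
    J_at_threshold: float        # m^-3 s^-1
    tau: float                   # s
    converged: bool
    iterations: int
    config_echo: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SweepTable:
    """Result of sweeping one scenario parameter."""

    parameter: str
    values: tuple
    results: tuple
    table: pd.DataFrame = field(repr=False)


def _probability_at(Pat: float, droplet: interfaces.DropletConfig,
                    tissue: interfaces.TissueConfig, fluid: eos.FluidProperties,
                    tau: float, pspin: float, include_gas: bool,
                    include_elastic_barrier: bool, P0: float):
    """Nucleation probability and state at one drive amplitude."""
    P2wo = interfaces.resting_liquid_pressure(droplet, tissue, Pat, P0=P0)
    gases = droplet.gases if include_gas else ()
    try:
        J, state = energetics.nucleation_rate(
            P2wo, droplet.T0, gases, fluid, pspin=pspin,
            K=interfaces.series_modulus(droplet.K2, tissue.K3), R20=droplet.R20,
            include_elastic_barrier=include_elastic_barrier)
    except NoNucleationDriveError:
        # No tension across the interface at this drive: nothing nucleates.
        return 0.0, None
    Sigma = energetics.nucleation_probability(J, droplet.V20, tau)
    return Sigma, state


def solve_threshold(droplet: interfaces.DropletConfig | None = None,
                    tissue: interfaces.TissueConfig | None = None,
                    f: float = 5e6, tau_divisor: float = 10.0,
                    include_gas: bool = True,
                    include_elastic_barrier: bool = True,
                    fluid: eos.FluidProperties | None = None,
                    P0: float = P_ATM,
                    xtol: float = 1e-4, max_iter: int = 200) -> ThresholdResult:
    """Bisect on the acoustic pressure until the 50% probability condition.

    Raises :class:`BeyondSpinodalError` if even a drive taking the liquid
    to its spinodal cannot reach 50% probability, and
    :class:`SuperStabilizedError` if the elastic confinement suppresses the
    barrier maximum throughout the bracket.
    """
    droplet = droplet or interfaces.DropletConfig()
    tissue = tissue or interfaces.TissueConfig()
    fluid = fluid or eos.FluidProperties.pfp()
    if f <= 0:
        raise ValueError("frequency must be positive")
    tau = 1.0 / (tau_divisor * f)
    _, pspin = eos.liquid_spinodal(droplet.T0, fluid)
    Plap = interfaces.laplace_pressure(droplet.R20, droplet.sigma2,
                                       droplet.laplace_factor)

    def sigma_of(Pat):
        return _probability_at(Pat, droplet, tissue, fluid, tau, pspin,
                               include_gas, include_elastic_barrier, P0)

    # Bracket: Pat = 0 (no drive) down to the drive that pins the liquid
    # just above its spinodal.
    eps = 1e-6 * (fluid.Psat - pspin)
    lo = pspin - P0 - Plap - tissue.Pc_conf + eps  # most negative admissible Pat
    hi = 0.0
    Sigma_lo, state_lo = sigma_of(lo)
    if Sigma_lo < 0.5:
        if state_lo is not None and \
                state_lo.regime == energetics.REGIME_SUPER_STABILIZED:
            raise SuperStabilizedError(
                "confinement suppresses the nucleation barrier over the whole bracket")
        raise BeyondSpinodalError(
            "50% nucleation probability unreachable above the spinodal")
    Sigma_hi, _ = sigma_of(hi)
    if Sigma_hi >= 0.5:
        raise ValueError("scenario nucleates with no applied drive (Sigma >= 0.5 at rest)")

    iterations = 0
    while hi - lo > xtol and iterations < max_iter:
        mid = 0.5 * (lo + hi)
        Sigma_mid, _ = sigma_of(mid)
        if Sigma_mid >= 0.5:
            lo = mid
        else:
            hi = mid
        iterations += 1
    converged = hi - lo <= xtol
    if not converged:
        raise ConvergenceError(f"bisection did not converge in {max_iter} iterations")

    Pat_star = 0.5 * (lo + hi)
    Sigma_star, state = sigma_of(Pat_star)
    config_echo = dict(
        R20=droplet.R20, sigma2=droplet.sigma2, T0=droplet.T0, K2=droplet.K2,
        K3=tissue.K3, Pc_conf=tissue.Pc_conf, f=f, tau_divisor=tau_divisor,
        include_gas=include_gas, include_elastic_barrier=include_elastic_barrier,
        P0=P0, Psat=fluid.Psat, laplace_factor=droplet.laplace_factor,
        gases=[(g.name, g.Ki, g.Cgi) for g in droplet.gases],
    )
    return ThresholdResult(
        P_INT=abs(Pat_star), Pat_star=Pat_star, P2_at_threshold=state.P2,
        sigma1_at_threshold=state.sigma1, R1wo_star=state.R1wo_star,
        gamma_at_threshold=state.gamma, Sigma=Sigma_star, J_at_threshold=state.J,
        tau=tau, converged=converged, iterations=iterations,
        config_echo=config_echo)


def liquid_pressure_at_threshold(result: ThresholdResult,
                                 fluid: eos.FluidProperties | None = None) -> float:
    """Liquid pressure at nucleation; asserted to lie above the spinodal."""
    fluid = fluid or eos.FluidProperties.pfp()
    _, pspin = eos.liquid_spinodal(result.config_echo["T0"], fluid)
    if result.P2_at_threshold <= pspin:
        raise BeyondSpinodalError("threshold liquid pressure at or below the spinodal")
    return result.P2_at_threshold


def underpressure_at_threshold(T_values, psat_table: dict,
                               droplet: interfaces.DropletConfig | None = None,
                               tissue: interfaces.TissueConfig | None = None,
                               f: float = 5e6, tau_divisor: float = 10.0,
                               **kwargs) -> pd.DataFrame:
    """Tension dP = P1 - P2 at the 50% condition, per temperature.

    ``psat_table`` maps temperature (K) to the saturation pressure (Pa);
    the model refuses to extrapolate a single-temperature preset.
    """
    droplet = droplet or interfaces.DropletConfig()
    tissue = tissue or interfaces.TissueConfig()
    rows = []
    for T in T_values:
        if T not in psat_table:
            raise ValueError(f"no saturation pressure supplied for T = {T} K")
        fluid_T = eos.FluidProperties.pfp().with_psat(psat_table[T])
        droplet_T = replace(droplet, T0=float(T))
        res = solve_threshold(droplet_T, tissue, f=f, tau_divisor=tau_divisor,
                              fluid=fluid_T, **kwargs)
        Pg1 = interfaces.gas_partial_pressure(droplet.gases) \
            if res.config_echo["include_gas"] else 0.0
        P1 = psat_table[T] + Pg1
        rows.append({"T_K": float(T), "P_INT_Pa": res.P_INT,
                     "P2_thr_Pa": res.P2_at_threshold,
                     "dP_Pa": P1 - res.P2_at_threshold})
    return pd.DataFrame(rows, columns=["T_K", "P_INT_Pa", "P2_thr_Pa", "dP_Pa"])


def probability_curve(Pat_grid,
                      droplet: interfaces.DropletConfig | None = None,
                      tissue: interfaces.TissueConfig | None = None,
                      f: float = 5e6, tau_divisor: float = 10.0,
                      include_gas: bool = True,
                      include_elastic_barrier: bool = True,
                      fluid: eos.FluidProperties | None = None,
                      P0: float = P_ATM) -> pd.DataFrame:
    """Nucleation probability per drive amplitude; out-of-domain rows flagged."""
    droplet = droplet or interfaces.DropletConfig()
    tissue = tissue or interfaces.TissueConfig()
    fluid = fluid or eos.FluidProperties.pfp()
    tau = 1.0 / (tau_divisor * f)
    _, pspin = eos.liquid_spinodal(droplet.T0, fluid)
    rows = []
    for Pat in Pat_grid:
        try:
            Sigma, _ = _probability_at(float(Pat), droplet, tissue, fluid, tau,
                                       pspin, include_gas,
                                       include_elastic_barrier, P0)
            rows.append({"Pat_Pa": float(Pat), "Sigma": Sigma, "status": "ok"})
        except BeyondSpinodalError:
            rows.append({"Pat_Pa": float(Pat), "Sigma": float("nan"),
                         "status": "beyond_spinodal"})
    return pd.DataFrame(rows, columns=["Pat_Pa", "Sigma", "status"])


_SWEEPABLE = ("K3", "R20", "sigma2", "f", "gas")


def sweep(parameter: str, values,
          droplet: interfaces.DropletConfig | None = None,
          tissue: interfaces.TissueConfig | None = None,
          f: float = 5e6, **kwargs) -> SweepTable:
    """Solve the threshold across one swept parameter.

    ``parameter`` is one of K3, R20, sigma2, f (SI values) or gas
    (booleans).  Failed rows carry an explicit status instead of aborting
    the sweep.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; "
                         f"choose from {_SWEEPABLE}")
    values = tuple(values)
    if not values:
        raise ValueError("sweep values must be nonempty")
    droplet = droplet or interfaces.DropletConfig()
    tissue = tissue or interfaces.TissueConfig()

    rows, results = [], []
    for v in values:
        d, t, fv, kw = droplet, tissue, f, dict(kwargs)
        if parameter == "K3":
            t = replace(tissue, K3=float(v))
        elif parameter == "R20":
            d = replace(droplet, R20=float(v))
        elif parameter == "sigma2":
            d = replace(droplet, sigma2=float(v))
        elif parameter == "f":
            fv = float(v)
        elif parameter == "gas":
            kw["include_gas"] = bool(v)
        try:
            res = solve_threshold(d, t, f=fv, **kw)
            results.append(res)
            rows.append({"swept_value": v, "P_INT_Pa": res.P_INT,
                         "P2_thr_Pa": res.P2_at_threshold,
                         "sigma1_Npm": res.sigma1_at_threshold,
                         "gamma": res.gamma_at_threshold, "status": "ok"})
        except (BeyondSpinodalError, SuperStabilizedError, ValueError) as exc:
            results.append(exc)
            rows.append({"swept_value": v, "P_INT_Pa": float("nan"),
                         "P2_thr_Pa": float("nan"), "sigma1_Npm": float("nan"),
                         "gamma": float("nan"),
                         "status": type(exc).__name__})
    table = pd.DataFrame(rows, columns=["swept_value", "P_INT_Pa", "P2_thr_Pa",
                                        "sigma1_Npm", "gamma", "status"])
    return SweepTable(parameter=parameter, values=values,
                      results=tuple(results), table=table)
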