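"""Nucleation-work landscape, critical radii, rate and probability.

The work to open a vapor embryo of radius R1 inside an elastically
confined droplet, scaled by the unconfined barrier W1wo and the unconfined
critical radius, is

    w(X; gamma) = 3 X^2 - 2 X^3 + gamma X^6,

where gamma = 8 sigma1^3 K / (R20^3 (P1 - P2wo)^4) measures the combined
droplet compressibility and tissue elasticity.  Stationary points solve
1 - X + gamma X^4 = 0: the smaller root is the critical radius (CR, local
maximum), the larger the stable critical radius (SCR, local minimum).
They coalesce at gamma = 27/256 (X = 4/3) and both vanish beyond it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from . import eos, interfaces
from .constants import K_BOLTZMANN, N_AVOGADRO
from .errors import NoNucleationDriveError, SuperStabilizedError

#: Coalescence value of the elasticity parameter (double stationary point).
GAMMA_LIMIT = 27.0 / 256.0
#: Elasticity parameter at which the SCR state has the same energy as the liquid.
GAMMA_EQUILIBRIUM = 1.0 / 16.0

REGIME_NO_ELASTICITY = "no_elasticity"
REGIME_BISTABLE = "bistable"
REGIME_DEGENERATE = "degenerate"
REGIME_SUPER_STABILIZED = "super_stabilized"


@dataclass(frozen=True)
class WorkCurveResult:
    """Dimensionless work landscape with its stationary points."""

    gamma: float
    X_grid: np.ndarray = field(repr=False)
    w_values: np.ndarray = field(repr=False)
    X_CR: float | None = None
    X_SCR: float | None = None
    barrier: float | None = None
    regime: str = REGIME_NO_ELASTICITY


@dataclass(frozen=True)
class NucleationState:
    """All intermediates of one nucleation-rate evaluation."""

    P2: float
    P1: float
    sigma1: float
    R1wo_star: float
    R1_star: float | None
    W1wo: float
    W_star: float
    gamma: float
    J0: float
    J: float
    regime: str


def dimensionless_work(X, gamma: float):
    """w(X; gamma) = 3X^2 - 2X^3 + gamma X^6."""
    X = np.asarray(X, dtype=float)
    w = 3.0 * X**2 - 2.0 * X**3 + gamma * X**6
    return float(w) if w.ndim == 0 else w


def stationary_points(gamma: float) -> tuple[float, float | None, str]:
    """Roots of 1 - X + gamma X^4 = 0 and the regime classification.

    Returns ``(X_CR, X_SCR, regime)``; ``X_SCR`` is ``None`` when no local
    minimum exists, and both are ``None`` in the super-stabilized regime.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if gamma == 0.0:
        return 1.0, None, REGIME_NO_ELASTICITY
    roots = np.roots([gamma, 0.0, 0.0, -1.0, 1.0])
    real = roots[np.abs(roots.imag) < 1e-9].real
    positive = np.sort(real[real > 0])
    if positive.size >= 2 and not math.isclose(gamma, GAMMA_LIMIT, rel_tol=1e-12):
        return float(positive[0]), float(positive[-1]), REGIME_BISTABLE
    if math.isclose(gamma, GAMMA_LIMIT, rel_tol=1e-12) or (
            positive.size == 1 and gamma <= GAMMA_LIMIT):
        X = 4.0 / 3.0 if math.isclose(gamma, GAMMA_LIMIT, rel_tol=1e-12) \
            else float(positive[0])
        return X, X, REGIME_DEGENERATE
    return None, None, REGIME_SUPER_STABILIZED


def work_curve(gamma: float, X_max: float = 3.0, n: int = 1001) -> WorkCurveResult:
    """Work landscape on [0, X_max] together with its stationary points."""
    X = np.linspace(0.0, X_max, n)
    w = dimensionless_work(X, gamma)
    X_CR, X_SCR, regime = stationary_points(gamma)
    barrier = dimensionless_work(X_CR, gamma) if X_CR is not None else None
    return WorkCurveResult(gamma=gamma, X_grid=X, w_values=w,
                           X_CR=X_CR, X_SCR=X_SCR, barrier=barrier, regime=regime)


def coalescence_point() -> tuple[float, float]:
    """Solve dw/dX = 0 and d2w/dX2 = 0 simultaneously: (gamma_l, X_l).

    Numerical solution of the 2x2 system; analytically 27/256 and 4/3.
    """
    def system(v):
        X, g = v
        return [1.0 - X + g * X**4, -1.0 + 4.0 * g * X**3]

    sol = root(system, x0=[1.2, 0.09], tol=1e-14)
    if not sol.success:
        raise RuntimeError(f"coalescence solve failed: {sol.message}")
    X, g = sol.x
    return float(g), float(X)


def equilibrium_point() -> tuple[float, float]:
    """Solve dw/dX = 0 and w = 0 simultaneously: (gamma_n, X_n).

    Numerical solution; analytically 1/16 and 2.
    """
    def system(v):
        X, g = v
        return [1.0 - X + g * X**4, 3.0 - 2.0 * X + g * X**4]

    sol = root(system, x0=[1.8, 0.05], tol=1e-14)
    if not sol.success:
        raise RuntimeError(f"equilibrium solve failed: {sol.message}")
    X, g = sol.x
    return float(g), float(X)


def gamma_parameter(sigma1: float, K: float, R20: float,
                    P1: float, P2wo: float) -> float:
    """Dimensionless elasticity parameter 8 sigma1^3 K / (R20^3 (P1-P2wo)^4)."""
    if P1 == P2wo:
        raise NoNucleationDriveError("P1 = P2wo: gamma diverges")
    return 8.0 * sigma1**3 * K / (R20**3 * (P1 - P2wo) ** 4)


def critical_radius_unconfined(sigma1: float, P1: float, P2wo: float) -> float:
    """Unconfined critical radius 2 sigma1 / (P1 - P2wo)."""
    if P1 <= P2wo:
        raise NoNucleationDriveError("no nucleation drive: P1 <= P2wo")
    return 2.0 * sigma1 / (P1 - P2wo)


def unconfined_barrier(sigma1: float, R1wo_star: float) -> float:
    """W1wo = (4 pi / 3) sigma1 R1wo*^2 — the gamma = 0 barrier."""
    return 4.0 * math.pi * sigma1 * R1wo_star**2 / 3.0


def critical_work(sigma1: float, P1: float, P2: float) -> float:
    """Unconfined critical work 16 pi sigma1^3 / (3 (P1 - P2)^2)."""
    if P1 <= P2:
        raise NoNucleationDriveError("no nucleation drive: P1 <= P2")
    return 16.0 * math.pi * sigma1**3 / (3.0 * (P1 - P2) ** 2)


def elastic_barrier(sigma1: float, K: float, R20: float,
                    P1: float, P2wo: float) -> tuple[float, float, float | None, str]:
    """Confined barrier W1wo * w(X_CR; gamma) and the landscape metadata.

    Returns ``(W_star, gamma, X_SCR, regime)``.  Raises
    :class:`SuperStabilizedError` when no barrier maximum exists.
    """
    gamma = gamma_parameter(sigma1, K, R20, P1, P2wo)
    R1wo = critical_radius_unconfined(sigma1, P1, P2wo)
    X_CR, X_SCR, regime = stationary_points(gamma)
    if X_CR is None:
        raise SuperStabilizedError(
            f"gamma = {gamma:.4g} >= 27/256: work curve has no stationary points")
    W_star = unconfined_barrier(sigma1, R1wo) * dimensionless_work(X_CR, gamma)
    return W_star, gamma, X_SCR, regime


def molecular_mass(fluid: eos.FluidProperties) -> float:
    """Mass of a single molecule, kg."""
    return fluid.molar_mass / N_AVOGADRO


def kinetic_prefactor(sigma1: float, T: float, fluid: eos.FluidProperties) -> float:
    """Kinetic pre-exponential factor (rho2/m) sqrt(2 sigma1 / (pi m))."""
    if sigma1 <= 0:
        raise ValueError("sigma1 must be positive")
    m = molecular_mass(fluid)
    rho2 = eos.liquid_density(T, fluid)
    return (rho2 / m) * math.sqrt(2.0 * sigma1 / (math.pi * m))


def nucleation_rate(P2: float, T: float, gases, fluid: eos.FluidProperties,
                    psat: float | None = None, pspin: float | None = None,
                    K: float = 0.0, R20: float | None = None,
                    include_elastic_barrier: bool = False,
                    ) -> tuple[float, NucleationState]:
    """Stationary homogeneous nucleation rate J = J0 exp(-W*/kB T).

    ``P2`` is the bubble-free liquid pressure.  When
    ``include_elastic_barrier`` is set (requires ``R20``), the barrier is
    the confined W1wo * w(X_CR; gamma); a super-stabilized landscape gives
    J = 0 rather than an error.
    """
    if psat is None:
        psat = fluid.Psat
    sigma1 = interfaces.effective_surface_tension(P2, T, fluid, psat=psat, pspin=pspin)
    Pg1 = interfaces.gas_partial_pressure(gases)
    P1 = psat + Pg1
    if P1 <= P2:
        raise NoNucleationDriveError("P1 <= P2: no tension across the interface")
    R1wo = critical_radius_unconfined(sigma1, P1, P2)
    W1wo = unconfined_barrier(sigma1, R1wo)
    gamma = 0.0
    X_SCR = None
    regime = REGIME_NO_ELASTICITY
    W_star = critical_work(sigma1, P1, P2)
    if include_elastic_barrier:
        if R20 is None:
            raise ValueError("R20 required for the elastic barrier")
        gamma = gamma_parameter(sigma1, K, R20, P1, P2)
        X_CR, X_SCR, regime = stationary_points(gamma)
        if X_CR is None:
            state = NucleationState(P2=P2, P1=P1, sigma1=sigma1, R1wo_star=R1wo,
                                    R1_star=None, W1wo=W1wo, W_star=math.inf,
                                    gamma=gamma, J0=0.0, J=0.0, regime=regime)
            return 0.0, state
        W_star = W1wo * dimensionless_work(X_CR, gamma)
    J0 = kinetic_prefactor(sigma1, T, fluid)
    J = J0 * math.exp(-W_star / (K_BOLTZMANN * T))
    R1_star = X_SCR * R1wo if X_SCR is not None else None
    state = NucleationState(P2=P2, P1=P1, sigma1=sigma1, R1wo_star=R1wo,
                            R1_star=R1_star, W1wo=W1wo, W_star=W_star,
                            gamma=gamma, J0=J0, J=J, regime=regime)
    return J, state


def nucleation_probability(J: float, V20: float, tau: float) -> float:
    """Probability 1 - exp(-J V20 tau) of nucleating at least one bubble."""
    if J < 0 or V20 < 0 or tau < 0:
        raise ValueError("J, V20 and tau must be non-negative")
    return -math.expm1(-J * V20 * tau)


def critical_rate(V20: float, tau: float, Nb: float = 1.0) -> float:
    """Rate Nb/(V20 tau) needed to form Nb bubbles in the time window."""
    if V20 <= 0 or tau <= 0:
        raise ValueError("V20 and tau must be positive")
    return Nb / (V20 * tau)
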